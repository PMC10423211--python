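"""End-to-end orchestration of the four-stage detection funnel.

Stage order: caller quality gate -> distinct-variant tally -> protein-
altering selection -> CH-in-TII VAF window -> cohort sample-fraction ->
population rarity -> hypermutable-gene exclusion -> deleteriousness
consensus -> immune-cell expression -> differential expression + pathway
tabulation.  Per-sample MAF rows collapse to one funnel unit per distinct
variant (keyed on chrom:pos:ref:alt) from the protein-altering stage
onward, so the funnel counts "different mutations" the way the per-stage
report does.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import candidate_filters, ch_detection, diff_expression, tii_expression, variant_io
from .candidate_filters import FilterConfig
from .ch_detection import ChCallConfig

logger = logging.getLogger("chtii")


@dataclass(frozen=True)
class PipelineConfig:
    """Every funnel threshold, with its conventional default."""

    min_lod: float = 4.0
    min_base_quality: float = 10.0
    vaf_lower: float = 0.02
    vaf_upper: float = 0.25
    ci_level: float = 0.95
    min_sample_fraction: float = 0.05
    max_population_freq: float = 0.0001
    fdr: float = 0.05

    def ch_config(self) -> ChCallConfig:
        return ChCallConfig(self.vaf_lower, self.vaf_upper, self.ci_level)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(self.min_sample_fraction, self.max_population_freq)

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def report_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-to-even to *decimals*."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class FunnelStage:
    name: str
    input_count: int
    output_count: int

    @property
    def percent_of_previous(self) -> float | None:
        return report_percent(self.output_count, self.input_count, 1) if self.input_count else None


@dataclass
class FunnelReport:
    """Ordered per-stage surviving counts of one pipeline run."""

    stages: list[FunnelStage] = field(default_factory=list)
    config_hash: str = ""

    def add(self, name: str, input_count: int, output_count: int) -> None:
        if output_count > input_count:
            raise ValueError(f"stage {name}: output exceeds input")
        stage = FunnelStage(name, int(input_count), int(output_count))
        self.stages.append(stage)
        logger.info("stage %-22s %8d -> %8d", name, input_count, output_count)

    def to_records(self) -> list[dict]:
        total = self.stages[0].input_count if self.stages else 0
        return [
            {
                "name": s.name,
                "input_count": s.input_count,
                "output_count": s.output_count,
                "percent_of_previous": s.percent_of_previous,
                "percent_of_total": report_percent(s.output_count, total, 1) if total else None,
            }
            for s in self.stages
        ]

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "stages": self.to_records()}, indent=1
        )


def format_candidate_row(summary: dict, annotation: dict, expression_summary: dict) -> str:
    """Render one candidate in the report layout.

    VAFs to 2 d.p. with +/- sample SD (suppressed for single-carrier
    candidates), sample fraction to 4 d.p., population frequency in
    scientific notation, expression as "P% (immune/total)".
    """

    def vaf(mean, sd):
        if sd is None:
            return f"{mean:.2f}"
        return f"{mean:.2f} ± {sd:.2f}"

    freq = annotation.get("population_freq", float("nan"))
    freq_str = "0" if freq == 0 else f"{freq:.0E}".replace("E-0", "E-")
    n_immune = expression_summary["n_immune_cells_expressing"]
    n_total = expression_summary["n_cells_expressing"]
    pct = report_percent(n_immune, n_total, 0) if n_total else 0.0
    expr_str = f"{pct:.0f}% ({n_immune:,}/{n_total:,})"
    return " | ".join(
        [
            vaf(summary["tumor_vaf_mean"], summary.get("tumor_vaf_sd")),
            vaf(summary["blood_vaf_mean"], summary.get("blood_vaf_sd")),
            f"{summary['sample_fraction']:.4f}",
            freq_str,
            expr_str,
        ]
    )


@dataclass
class PipelineResult:
    funnel: FunnelReport
    candidates: pd.DataFrame
    de_results: dict[str, pd.DataFrame]  # variant_id -> per-gene DE table
    pathway_counts: pd.DataFrame  # pathways x candidate variants
    expression_summaries: dict[str, dict]


def run_pipeline(
    maf: pd.DataFrame,
    annotations: pd.DataFrame,
    gene_meta: pd.DataFrame,
    cell_matrix: tii_expression.CellMatrix,
    bulk_expression: pd.DataFrame,
    pathway_map: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    n_cohort: int | None = None,
) -> PipelineResult:
    """Run the whole funnel on in-memory tables.

    *n_cohort* is the cohort size used for sample fractions; by default the
    number of distinct sample barcodes in the bulk expression table (the
    cohort), falling back to the MAF's distinct barcodes.
    """
    if n_cohort is None:
        n_cohort = (
            len(bulk_expression.columns)
            if len(bulk_expression.columns)
            else maf["Tumor_Sample_Barcode"].nunique()
        )
    funnel = FunnelReport(config_hash=config.hash())

    # stage 1a: caller quality gate (per observation row)
    gated = variant_io.quality_gate(maf, config.min_lod, config.min_base_quality)
    funnel.add("quality_gate_rows", len(maf), len(gated))

    # stage 1b: collapse to distinct variants
    n_distinct = gated["variant_id"].nunique()
    funnel.add("distinct_variants", n_distinct, n_distinct)

    # stage 1c: protein-altering consequences
    altering = variant_io.select_protein_altering(gated)
    funnel.add("protein_altering", n_distinct, altering["variant_id"].nunique())

    # stage 2: CH-in-TII dual VAF window, summarized per variant
    summaries = ch_detection.classify_table(altering, n_cohort, config.ch_config())
    ch_variants = summaries.loc[summaries["n_pass"] > 0]
    funnel.add("ch_in_tii", len(summaries), len(ch_variants))

    # stage 3: candidate filters, in report order
    fc = config.filter_config()
    frequent = candidate_filters.filter_sample_fraction(ch_variants, fc)
    funnel.add("sample_fraction", len(ch_variants), len(frequent))
    rare = candidate_filters.filter_rare(frequent, annotations, fc)
    funnel.add("population_rarity", len(frequent), len(rare))
    nonhyper = candidate_filters.filter_hypermutable(rare, gene_meta)
    funnel.add("hypermutable_exclusion", len(rare), len(nonhyper))
    deleterious = candidate_filters.filter_deleterious(nonhyper, annotations)
    funnel.add("deleterious_consensus", len(nonhyper), len(deleterious))

    expression_summaries = {
        gene: tii_expression.summarize_gene_expression(cell_matrix, gene)
        for gene in deleterious["gene"].unique()
    }
    expressed = tii_expression.filter_expressed_in_immune(expression_summaries, deleterious)
    funnel.add("immune_expression", len(deleterious), len(expressed))

    # stage 4 (computational part): differential expression per candidate
    de_results: dict[str, pd.DataFrame] = {}
    pathway_cols: dict[str, dict[str, int]] = {}
    calls_by_variant = {
        vid: grp for vid, grp in altering.groupby("variant_id", sort=False)
    }
    for _, cand in expressed.iterrows():
        vid = cand["variant_id"]
        grp = calls_by_variant[vid]
        ch_cfg = config.ch_config()
        carriers = {
            str(row["Tumor_Sample_Barcode"])
            for _, row in grp.iterrows()
            if ch_detection.classify_ch(row, ch_cfg).is_ch_in_tii
        }
        carriers &= set(bulk_expression.columns)
        if len(carriers) < 2 or len(bulk_expression.columns) - len(carriers) < 2:
            logger.info("skipping DE for %s: too few carriers with expression data", vid)
            continue
        de = diff_expression.run_de(bulk_expression, carriers, config.fdr)
        de_results[vid] = de
        sde_genes = de.loc[de["sde"], "gene"].tolist()
        pathway_cols[vid] = diff_expression.tabulate_pathways(sde_genes, pathway_map)
    pathway_counts = pd.DataFrame(pathway_cols).fillna(0).astype(int)
    pathway_counts.index.name = "pathway"

    candidates = expressed.copy().reset_index(drop=True)
    ann = annotations.set_index("variant_id")
    candidates["population_freq"] = candidates["variant_id"].map(ann["population_freq"])
    candidates["n_immune_cells_expressing"] = candidates["gene"].map(
        lambda g: expression_summaries[g]["n_immune_cells_expressing"]
    )
    candidates["n_cells_expressing"] = candidates["gene"].map(
        lambda g: expression_summaries[g]["n_cells_expressing"]
    )
    candidates["n_sde_genes"] = candidates["variant_id"].map(
        lambda v: int(de_results[v]["sde"].sum()) if v in de_results else 0
    )
    return PipelineResult(funnel, candidates, de_results, pathway_counts, expression_summaries)


def run_pipeline_from_paths(
    maf_path,
    annotations_path,
    gene_meta_path,
    scrna_dir,
    bulk_path,
    pathway_path,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """File-based front end of :func:`run_pipeline` (the bundle layout the
    synthetic generator writes)."""
    scrna_dir = Path(scrna_dir)
    maf = variant_io.read_maf(maf_path)
    annotations = pd.read_csv(annotations_path, sep="\t")
    gene_meta = pd.read_csv(gene_meta_path, sep="\t")
    cell_matrix = tii_expression.read_cell_matrix(
        scrna_dir / "matrix.mtx",
        scrna_dir / "barcodes.tsv",
        scrna_dir / "genes.tsv",
        scrna_dir / "celltypes.tsv",
    )
    bulk = pd.read_csv(bulk_path, sep="\t", index_col=0)
    pathway_map = pd.read_csv(pathway_path, sep="\t")
    return run_pipeline(maf, annotations, gene_meta, cell_matrix, bulk, pathway_map, config)


def run_pipeline_on_cohort(cohort, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the funnel directly on an in-memory simulated cohort."""
    return run_pipeline(
        cohort.annotated_maf(),
        cohort.annotations,
        cohort.gene_meta,
        cohort.cell_matrix(),
        cohort.bulk_expression,
        cohort.pathway_map,
        config,
        n_cohort=len(cohort.sample_ids),
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write funnel JSON, candidate TSV, DE TSVs and pathway-count TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "funnel.json").write_text(result.funnel.to_json())
    result.candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    result.pathway_counts.to_csv(out_dir / "pathway_counts.tsv", sep="\t")
    de_dir = out_dir / "de"
    de_dir.mkdir(exist_ok=True)
    for vid, de in result.de_results.items():
        safe = vid.replace(":", "_")
        de.to_csv(de_dir / f"{safe}.tsv", sep="\t", index=False)
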