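"""Self-contained synthetic cohort with planted ground truth.

Emulates the data a matched tumor/normal-blood variant study consumes — a
MAF-dialect call table, a variant-annotation table (population frequency,
SIFT/PolyPhen calls), gene metadata, a labeled single-cell count matrix,
bulk expression and a gene -> top-level-pathway map — so the whole
detection funnel is testable without any protected or external data.

Planted variant classes:

* ``planted_ch``      — true CH-in-TII variants: blood and tumor VAF drawn
                        inside the (2%, 25%) clonal window, carried by more
                        than 5% of samples, rare in the population,
                        deleterious, expressed in immune cells.  They pass
                        every downstream filter by construction.
* ``germline``        — heterozygous variants, true VAF 0.5 in both samples.
* ``noise``           — sub-clonal variants with true VAF < 2%; a
                        configurable fraction also fails the caller quality
                        gate (low LOD / base quality).
* ``passenger:<f>``   — passenger somatics each built to fail exactly one
                        named downstream filter (sample_fraction, gnomad,
                        hypermutable, deleterious, expression) and pass all
                        others.

Read depths are Poisson around ``depth_mean``, floored at 16 and capped at
725 (the observed exome depth range this generator emulates); alt reads are
Binomial(depth, true VAF).  Expression shifts of ``de_effect_size`` (in
units of the unit-variance log-expression noise) are added to a disjoint
set of affected genes in the carrier samples of each planted variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import variant_io

DEPTH_FLOOR = 16
DEPTH_CAP = 725

PASSENGER_FILTERS = ("sample_fraction", "gnomad", "hypermutable", "deleterious", "expression")

#: Cell-type proportions of the synthetic tumor microenvironment.
CELL_TYPE_PROPORTIONS = {
    "T-cell": 0.40,
    "myeloid": 0.25,
    "B-cell": 0.10,
    "NK": 0.05,
    "epithelial": 0.12,
    "stromal": 0.05,
    "endothelial": 0.03,
}

#: Per-cell expression probability, by cell type, for genes carrying planted
#: or passenger variants (detectable in immune cells)...
_EXPR_PROB_IMMUNE_GENE = {
    "T-cell": 0.50,
    "myeloid": 0.45,
    "B-cell": 0.20,
    "NK": 0.20,
    "epithelial": 0.15,
    "stromal": 0.15,
    "endothelial": 0.15,
}
#: ... for the passenger:expression gene (silent in every immune cell) ...
_EXPR_PROB_NONIMMUNE_GENE = {
    "T-cell": 0.0,
    "myeloid": 0.0,
    "B-cell": 0.0,
    "NK": 0.0,
    "epithelial": 0.50,
    "stromal": 0.30,
    "endothelial": 0.30,
}
#: ... and for background genes.
_EXPR_PROB_BACKGROUND = {t: 0.15 for t in CELL_TYPE_PROPORTIONS}

PATHWAY_VOCABULARY = [
    "Immune System",
    "Signal Transduction",
    "Metabolism",
    "Gene expression (Transcription)",
    "Metabolism of proteins",
    "Developmental Biology",
    "Disease",
    "Vesicle-mediated transport",
    "Cell Cycle",
    "Homeostasis",
]


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the study conditions the generator emulates: a cohort of
    1,064 patients, exome depth averaging 200x inside the observed 16-725x
    range, planted CH variants with blood/tumor VAF inside the clonal
    window, and recurrent carriers (6-12% of samples, above the 5%
    cohort-frequency threshold that planted variants must pass; the
    passenger:sample_fraction variant sits at 2%, so the cohort straddles
    the threshold).
    """

    n_samples: int = 1064
    n_genes: int = 120
    n_planted_ch: int = 8
    n_germline: int = 10
    n_noise: int = 10
    n_passenger_somatic: int = 5
    depth_mean: float = 200.0
    blood_vaf_range: tuple[float, float] = (0.05, 0.20)
    tumor_vaf_range: tuple[float, float] = (0.05, 0.20)
    carrier_fraction_range: tuple[float, float] = (0.06, 0.12)
    seed: int = 0
    de_effect_size: float = 1.0
    n_cells: int = 1500
    n_affected_genes: int = 5  # genes shifted per planted variant
    noise_lowqual_fraction: float = 0.5  # noise variants failing the quality gate

    def __post_init__(self):
        for name in (
            "n_samples",
            "n_genes",
            "n_planted_ch",
            "n_germline",
            "n_noise",
            "n_passenger_somatic",
            "n_cells",
            "n_affected_genes",
        ):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        for name in ("blood_vaf_range", "tumor_vaf_range", "carrier_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= 1):
                raise ConfigError(f"{name} must satisfy 0 <= low < high <= 1")
        for name in ("blood_vaf_range", "tumor_vaf_range"):
            lo, hi = getattr(self, name)
            if lo <= 0.02 or hi >= 0.25:
                raise ConfigError(f"{name} must lie strictly inside the (0.02, 0.25) window")
        if not (0 <= self.noise_lowqual_fraction <= 1):
            raise ConfigError("noise_lowqual_fraction must be in [0, 1]")
        n_variants = (
            self.n_planted_ch + self.n_germline + self.n_noise + self.n_passenger_somatic
        )
        if self.n_genes < n_variants + self.n_planted_ch * self.n_affected_genes:
            raise ConfigError(
                "n_genes too small: need one gene per variant plus "
                "n_planted_ch * n_affected_genes background genes"
            )


def well_separated_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration on which the funnel should recover planted variants
    exactly: VAFs centered at 0.12, carrier fraction 0.08, depth 500."""
    params = dict(
        blood_vaf_range=(0.10, 0.14),
        tumor_vaf_range=(0.10, 0.14),
        carrier_fraction_range=(0.07, 0.09),
        depth_mean=500.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort."""

    labels: dict[str, str]  # variant_id -> class label
    carriers: dict[str, list[str]]  # variant_id -> carrier sample ids
    true_vaf: dict[str, dict[str, float]]  # variant_id -> {blood, tumor}
    affected_genes: dict[str, list[str]]  # planted variant -> shifted genes
    immune_composition: dict[str, float]  # expected pooled immune composition

    def planted_ch_ids(self) -> set[str]:
        return {v for v, label in self.labels.items() if label == "planted_ch"}


@dataclass
class SimulatedCohort:
    """All tables a pipeline run consumes, plus the ground truth."""

    maf: pd.DataFrame
    annotations: pd.DataFrame
    gene_meta: pd.DataFrame
    cell_matrix_tables: dict  # mtx (sparse), barcodes, genes, celltypes (DataFrame)
    bulk_expression: pd.DataFrame
    pathway_map: pd.DataFrame
    ground_truth: GroundTruth
    sample_ids: list[str]

    def annotated_maf(self) -> pd.DataFrame:
        """MAF table with the derived per-call columns the pipeline expects."""
        return variant_io.annotate_maf(self.maf)

    def cell_matrix(self):
        """The single-cell tables as an in-memory :class:`~chtii.CellMatrix`."""
        from .tii_expression import CellMatrix

        tabs = self.cell_matrix_tables
        return CellMatrix(
            cells=tabs["barcodes"]["barcode"].tolist(),
            genes=tabs["genes"]["gene"].tolist(),
            counts=sparse.csc_matrix(tabs["mtx"]),
            cell_type=tabs["celltypes"]["cell_type"].tolist(),
            is_immune={t: t in ("T-cell", "myeloid", "B-cell", "NK") for t in CELL_TYPE_PROPORTIONS},
        )


def _expected_immune_composition(n_by_type: dict[str, int]) -> dict[str, float]:
    from .tii_expression import DEFAULT_IMMUNE_LABELS

    weights = {
        t: n_by_type[t] * _EXPR_PROB_IMMUNE_GENE[t]
        for t in n_by_type
        if DEFAULT_IMMUNE_LABELS[t]
    }
    total = sum(weights.values())
    return {t: w / total for t, w in weights.items()} if total else {}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full synthetic cohort for *config* (deterministic in seed)."""
    # Independent child streams so that sampling noise in one table does not
    # perturb another; the design stream fixes the shared cohort layout.
    ss = np.random.SeedSequence(config.seed)
    design_rng, maf_rng, scrna_rng, bulk_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    sample_ids = [f"SAMPLE_{i:04d}" for i in range(config.n_samples)]

    # --- variant design -------------------------------------------------
    specs = []  # per-variant design dicts
    n_variants = config.n_planted_ch + config.n_germline + config.n_noise
    n_variants += config.n_passenger_somatic

    labels = (
        ["planted_ch"] * config.n_planted_ch
        + ["germline"] * config.n_germline
        + ["noise"] * config.n_noise
        + [
            f"passenger:{PASSENGER_FILTERS[i % len(PASSENGER_FILTERS)]}"
            for i in range(config.n_passenger_somatic)
        ]
    )

    gene_names = []
    n_hyper = sum(1 for l in labels if l == "passenger:hypermutable")
    hyper_genes = [f"TRBV{i + 1}" for i in range(n_hyper)]
    background = [f"GENE{i:04d}" for i in range(config.n_genes - len(hyper_genes))]
    bg_iter = iter(background)
    hyper_iter = iter(hyper_genes)

    consequences = ["missense", "frameshift_del", "missense"]  # planted cycle
    chrom_cycle = [str(c) for c in range(1, 23)]

    for i, label in enumerate(labels):
        gene = next(hyper_iter) if label == "passenger:hypermutable" else next(bg_iter)
        gene_names.append(gene)
        if label == "planted_ch":
            consequence = consequences[i % len(consequences)]
        else:
            consequence = "missense"
        if label == "germline":
            blood_vaf = tumor_vaf = 0.5
        elif label == "noise":
            blood_vaf = float(design_rng.uniform(0.002, 0.015))
            tumor_vaf = float(design_rng.uniform(0.002, 0.015))
        else:
            blood_vaf = float(design_rng.uniform(*config.blood_vaf_range))
            tumor_vaf = float(design_rng.uniform(*config.tumor_vaf_range))
        if label == "passenger:sample_fraction":
            carrier_fraction = 0.02
        elif label == "germline":
            carrier_fraction = float(design_rng.uniform(0.10, 0.30))
        else:
            carrier_fraction = float(design_rng.uniform(*config.carrier_fraction_range))
        n_carriers = max(1, round(carrier_fraction * config.n_samples)) if config.n_samples else 0
        carriers = sorted(
            design_rng.choice(config.n_samples, size=min(n_carriers, config.n_samples), replace=False)
        ) if config.n_samples else []
        if label == "passenger:gnomad":
            population_freq = 0.05
        elif label == "germline":
            population_freq = float(design_rng.uniform(0.01, 0.5))
        else:
            # rare: absent from, or nearly absent from, the population reference
            population_freq = float(design_rng.choice([0.0, 2e-5, 4e-6, 9e-6]))
        if label == "passenger:deleterious":
            sift, polyphen = "tolerated", "benign"
        elif consequence == "missense":
            sift, polyphen = "deleterious", "probably_damaging"
        else:
            sift, polyphen = "unknown", "unknown"
        pos = 1000 + i * 10
        ref, alt = "A", "G"
        specs.append(
            dict(
                label=label,
                gene=gene,
                chrom=chrom_cycle[i % len(chrom_cycle)],
                pos=pos,
                ref=ref,
                alt=alt,
                variant_id=f"{chrom_cycle[i % len(chrom_cycle)]}:{pos}:{ref}:{alt}",
                consequence=consequence,
                protein_change=f"p.V{276 + i}G",
                blood_vaf=blood_vaf,
                tumor_vaf=tumor_vaf,
                carriers=[sample_ids[j] for j in carriers],
                population_freq=population_freq,
                sift=sift,
                polyphen=polyphen,
            )
        )

    # genes shifted in carriers of each planted variant (disjoint sets)
    affected_genes: dict[str, list[str]] = {}
    for spec in specs:
        if spec["label"] == "planted_ch":
            affected_genes[spec["variant_id"]] = [
                next(bg_iter) for _ in range(config.n_affected_genes)
            ]
    all_genes = gene_names + [g for gs in affected_genes.values() for g in gs]
    all_genes += list(bg_iter)  # remaining background genes
    all_genes += [g for g in hyper_genes if g not in gene_names]

    # --- MAF table ------------------------------------------------------
    _CONSEQ_TO_CLASS = {v: k for k, v in variant_io.CLASSIFICATION_TO_CONSEQUENCE.items()}
    maf_rows = []
    for spec in specs:
        is_noise = spec["label"] == "noise"
        lowqual = is_noise and maf_rng.random() < config.noise_lowqual_fraction
        for sample in spec["carriers"]:
            t_depth = int(np.clip(maf_rng.poisson(config.depth_mean), DEPTH_FLOOR, DEPTH_CAP))
            n_depth = int(np.clip(maf_rng.poisson(config.depth_mean), DEPTH_FLOOR, DEPTH_CAP))
            t_alt = int(maf_rng.binomial(t_depth, spec["tumor_vaf"]))
            n_alt = int(maf_rng.binomial(n_depth, spec["blood_vaf"]))
            if lowqual:
                lod = float(maf_rng.uniform(0.5, 3.9))
                bq = float(maf_rng.uniform(0.0, 9.9))
            else:
                lod = float(maf_rng.uniform(4.01, 75.10))
                bq = float(maf_rng.uniform(10.0, 40.0))
            maf_rows.append(
                {
                    "Hugo_Symbol": spec["gene"],
                    "Chromosome": spec["chrom"],
                    "Start_Position": spec["pos"],
                    "Reference_Allele": spec["ref"],
                    "Tumor_Seq_Allele2": spec["alt"],
                    "Variant_Classification": _CONSEQ_TO_CLASS[spec["consequence"]],
                    "Protein_Change": spec["protein_change"],
                    "Tumor_Sample_Barcode": sample,
                    "t_ref_count": t_depth - t_alt,
                    "t_alt_count": t_alt,
                    "n_ref_count": n_depth - n_alt,
                    "n_alt_count": n_alt,
                    "lod": round(lod, 2),
                    "base_quality": round(bq, 2),
                }
            )
    maf = pd.DataFrame(maf_rows, columns=variant_io.REQUIRED_COLUMNS)

    # --- annotations and gene metadata ---------------------------------
    annotations = pd.DataFrame(
        [
            {
                "variant_id": s["variant_id"],
                "population_freq": s["population_freq"],
                "sift": s["sift"],
                "polyphen": s["polyphen"],
            }
            for s in specs
        ],
        columns=["variant_id", "population_freq", "sift", "polyphen"],
    )
    gene_meta = pd.DataFrame(
        [{"gene": g, "hypermutable": g.startswith("TRBV")} for g in all_genes],
        columns=["gene", "hypermutable"],
    )

    # --- single-cell matrix --------------------------------------------
    type_order = list(CELL_TYPE_PROPORTIONS)
    n_by_type = {t: int(round(CELL_TYPE_PROPORTIONS[t] * config.n_cells)) for t in type_order}
    cell_types: list[str] = []
    for t in type_order:
        cell_types.extend([t] * n_by_type[t])
    cell_types = cell_types[: config.n_cells]
    while len(cell_types) < config.n_cells:
        cell_types.append(type_order[0])
    barcodes = [f"CELL_{i:05d}" for i in range(len(cell_types))]

    nonimmune_genes = {s["gene"] for s in specs if s["label"] == "passenger:expression"}
    variant_genes = {s["gene"] for s in specs} - nonimmune_genes

    rows_idx, cols_idx, data = [], [], []
    for j, gene in enumerate(all_genes):
        if gene in nonimmune_genes:
            probs = _EXPR_PROB_NONIMMUNE_GENE
        elif gene in variant_genes:
            probs = _EXPR_PROB_IMMUNE_GENE
        else:
            probs = _EXPR_PROB_BACKGROUND
        p = np.array([probs[t] for t in cell_types])
        expressing = scrna_rng.random(len(cell_types)) < p
        idx = np.nonzero(expressing)[0]
        counts = 1 + scrna_rng.poisson(1.0, size=idx.size)
        rows_idx.extend(idx.tolist())
        cols_idx.extend([j] * idx.size)
        data.extend(counts.tolist())
    mtx = sparse.coo_matrix(
        (data, (rows_idx, cols_idx)), shape=(len(cell_types), len(all_genes)), dtype=np.int64
    )
    cell_matrix_tables = {
        "mtx": mtx,
        "barcodes": pd.DataFrame({"barcode": barcodes}),
        "genes": pd.DataFrame({"gene": all_genes}),
        "celltypes": pd.DataFrame({"barcode": barcodes, "cell_type": cell_types}),
    }

    # --- bulk expression ------------------------------------------------
    baseline = bulk_rng.uniform(2.0, 10.0, size=len(all_genes))
    expr = baseline[:, None] + bulk_rng.normal(0.0, 1.0, size=(len(all_genes), config.n_samples))
    bulk = pd.DataFrame(expr, index=pd.Index(all_genes, name="gene"), columns=sample_ids)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    for spec in specs:
        if spec["label"] != "planted_ch":
            continue
        cols = [sample_pos[s] for s in spec["carriers"]]
        for g in affected_genes[spec["variant_id"]]:
            bulk.iloc[gene_pos[g], cols] += config.de_effect_size

    # --- pathway map ----------------------------------------------------
    pathway_rows = []
    unmapped = set(all_genes[-2:]) if len(all_genes) >= 2 else set()
    affected_set = {g for gs in affected_genes.values() for g in gs}
    for j, gene in enumerate(all_genes):
        if gene in unmapped:
            continue
        if gene in affected_set:
            pathway_rows.append({"gene": gene, "pathway": "Immune System"})
            if j % 2 == 0:  # exercise many-to-many mapping
                pathway_rows.append({"gene": gene, "pathway": "Signal Transduction"})
        else:
            pathway_rows.append(
                {"gene": gene, "pathway": PATHWAY_VOCABULARY[j % len(PATHWAY_VOCABULARY)]}
            )
    pathway_map = pd.DataFrame(pathway_rows, columns=["gene", "pathway"])

    ground_truth = GroundTruth(
        labels={s["variant_id"]: s["label"] for s in specs},
        carriers={s["variant_id"]: s["carriers"] for s in specs},
        true_vaf={
            s["variant_id"]: {"blood": s["blood_vaf"], "tumor": s["tumor_vaf"]} for s in specs
        },
        affected_genes=affected_genes,
        immune_composition=_expected_immune_composition(n_by_type),
    )
    return SimulatedCohort(
        maf=maf,
        annotations=annotations,
        gene_meta=gene_meta,
        cell_matrix_tables=cell_matrix_tables,
        bulk_expression=bulk,
        pathway_map=pathway_map,
        ground_truth=ground_truth,
        sample_ids=sample_ids,
    )


def write_fixture_bundle(cohort: SimulatedCohort, directory: str | Path) -> list[dict]:
    """Write every table of *cohort* under *directory*; return the manifest.

    Layout: variants.maf.tsv, annotations.tsv, gene_meta.tsv,
    scrna/{matrix.mtx,barcodes.tsv,genes.tsv,celltypes.tsv},
    bulk_expression.tsv, pathway_map.tsv, ground_truth.json, manifest.json.
    The manifest lists each file with its row (or cell/entry) count.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "scrna").mkdir(exist_ok=True)
    manifest: list[dict] = []

    def note(path: Path, rows: int):
        manifest.append({"path": str(path.relative_to(directory)), "rows": int(rows)})

    p = directory / "variants.maf.tsv"
    variant_io.write_maf(cohort.maf, p)
    note(p, len(cohort.maf))

    p = directory / "annotations.tsv"
    cohort.annotations.to_csv(p, sep="\t", index=False)
    note(p, len(cohort.annotations))

    p = directory / "gene_meta.tsv"
    cohort.gene_meta.to_csv(p, sep="\t", index=False)
    note(p, len(cohort.gene_meta))

    tabs = cohort.cell_matrix_tables
    p = directory / "scrna" / "matrix.mtx"
    spio.mmwrite(str(p), tabs["mtx"])
    note(p, tabs["mtx"].shape[0])
    p = directory / "scrna" / "barcodes.tsv"
    tabs["barcodes"].to_csv(p, sep="\t", index=False, header=False)
    note(p, len(tabs["barcodes"]))
    p = directory / "scrna" / "genes.tsv"
    tabs["genes"].to_csv(p, sep="\t", index=False, header=False)
    note(p, len(tabs["genes"]))
    p = directory / "scrna" / "celltypes.tsv"
    tabs["celltypes"].to_csv(p, sep="\t", index=False)
    note(p, len(tabs["celltypes"]))

    p = directory / "bulk_expression.tsv"
    cohort.bulk_expression.to_csv(p, sep="\t", float_format="%.6f")
    note(p, len(cohort.bulk_expression))

    p = directory / "pathway_map.tsv"
    cohort.pathway_map.to_csv(p, sep="\t", index=False)
    note(p, len(cohort.pathway_map))

    p = directory / "ground_truth.json"
    gt = cohort.ground_truth
    p.write_text(
        json.dumps(
            {
                "labels": gt.labels,
                "carriers": gt.carriers,
                "true_vaf": gt.true_vaf,
                "affected_genes": gt.affected_genes,
                "immune_composition": gt.immune_composition,
                "sample_ids": cohort.sample_ids,
            },
            indent=1,
        )
    )
    note(p, len(gt.labels))

    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_ground_truth(directory: str | Path) -> GroundTruth:
    """Read ground_truth.json written by :func:`write_fixture_bundle`."""
    data = json.loads((Path(directory) / "ground_truth.json").read_text())
    return GroundTruth(
        labels=data["labels"],
        carriers=data["carriers"],
        true_vaf=data["true_vaf"],
        affected_genes=data["affected_genes"],
        immune_composition=data["immune_composition"],
    )
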