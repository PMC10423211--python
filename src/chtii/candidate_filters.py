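"""Stage-3 candidate filters: cohort frequency, population rarity,
hypermutable-gene exclusion, and deleteriousness consensus.

These filters are designed to be exclusion-biased: they reduce the chance of
keeping passenger mutations even at the cost of discarding some genuine
candidates.  All of them are subset operations on the per-variant summary
table and commute with one another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("chtii")

#: Consequences treated as deleterious regardless of predictor calls:
#: truncating (nonsense), frame-shift and splice-site variants.
TRUNCATING = frozenset({"nonsense", "frameshift_ins", "frameshift_del", "splice_site"})

#: PolyPhen grades counted as "damaging".
DAMAGING_POLYPHEN = frozenset({"probably_damaging", "possibly_damaging"})

#: Gene-symbol prefixes of hypermutable / highly variable immune gene
#: families: immunoglobulin (IGH/IGK/IGL), T-cell receptor (TRA/TRB/TRG/TRD),
#: histocompatibility antigen (HLA) and Ig-like receptor (KIR/LILR) loci.
HYPERMUTABLE_PREFIXES = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRG", "TRD", "HLA", "KIR", "LILR")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the cohort-frequency and population-rarity filters."""

    min_sample_fraction: float = 0.05
    max_population_freq: float = 0.0001

    def __post_init__(self):
        for name in ("min_sample_fraction", "max_population_freq"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


def default_hypermutable(gene: str) -> bool:
    """Symbol-prefix heuristic for hypermutable immune gene families."""
    return gene.upper().startswith(HYPERMUTABLE_PREFIXES)


def filter_sample_fraction(
    summaries: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Retain variants that occur frequently in the cohort.

    A rare variant recurring in more than ``min_sample_fraction`` of the
    cohort's blood samples (strictly) is unlikely to be a passenger, since
    non-tumor immune cells are neither rapidly dividing nor repair-deficient.
    """
    keep = summaries["sample_fraction"] > config.min_sample_fraction
    return summaries.loc[keep]


def filter_rare(
    summaries: pd.DataFrame,
    annotations: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Retain variants rare in the population (frequency < max_population_freq).

    *annotations* has columns variant_id, population_freq (gnomAD-style
    allele fraction), sift, polyphen.  A variant absent from the population
    reference (frequency 0) is retained; a variant with no annotation row at
    all fails the filter (conservative) and is logged.
    """
    freq = annotations.set_index("variant_id")["population_freq"]
    missing = [v for v in summaries["variant_id"] if v not in freq.index]
    if missing:
        logger.info(
            "filter_rare: %d variant(s) without annotation treated as failing", len(missing)
        )
    mapped = summaries["variant_id"].map(freq)
    keep = mapped.notna() & (mapped < config.max_population_freq)
    return summaries.loc[keep]


def filter_hypermutable(summaries: pd.DataFrame, gene_meta: pd.DataFrame) -> pd.DataFrame:
    """Drop variants in hypermutable / highly variable immune gene families.

    *gene_meta* has columns gene, hypermutable (boolean) and must cover every
    gene present in *summaries*; a missing gene raises ``KeyError`` naming it.
    """
    flag = gene_meta.set_index("gene")["hypermutable"].astype(bool)
    for gene in summaries["gene"].unique():
        if gene not in flag.index:
            raise KeyError(f"gene missing from gene metadata: {gene!r}")
    keep = ~summaries["gene"].map(flag).astype(bool)
    return summaries.loc[keep]


def is_deleterious(consequence: str, sift: str, polyphen: str) -> bool:
    """Deleteriousness consensus rule.

    True iff the consequence is truncating / frame-shift / splice-site, or
    both predictors agree: SIFT calls it deleterious and PolyPhen calls it
    damaging (probably or possibly).
    """
    if consequence in TRUNCATING:
        return True
    return sift == "deleterious" and polyphen in DAMAGING_POLYPHEN


def filter_deleterious(summaries: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Retain variants passing the deleteriousness consensus.

    Variants without an annotation row get (unknown, unknown) predictor
    calls, so only truncating classes can pass for them.
    """
    ann = annotations.set_index("variant_id")
    keep = [
        is_deleterious(
            row["consequence"],
            ann["sift"].get(row["variant_id"], "unknown"),
            ann["polyphen"].get(row["variant_id"], "unknown"),
        )
        for _, row in summaries.iterrows()
    ]
    return summaries.loc[keep]
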