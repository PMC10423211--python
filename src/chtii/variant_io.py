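"""Read/write the MAF-dialect variant table and apply call-quality gates.

The dialect is a tab-delimited file with a named-column header carrying, per
sample-level variant observation, the tumor and matched-blood allele depths
plus caller quality fields (log-odds score and Phred base quality).  Variant
allele fraction (VAF) is computed from the two per-allele read counts, so it
is an exact rational of two integers.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path

import pandas as pd

logger = logging.getLogger("chtii")

#: Columns a MAF-dialect file must carry (bit-exact names).
REQUIRED_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Protein_Change",
    "Tumor_Sample_Barcode",
    "t_ref_count",
    "t_alt_count",
    "n_ref_count",
    "n_alt_count",
    "lod",
    "base_quality",
]

_INT_COLUMNS = ["Start_Position", "t_ref_count", "t_alt_count", "n_ref_count", "n_alt_count"]
_FLOAT_COLUMNS = ["lod", "base_quality"]

#: Map from MAF Variant_Classification strings to the internal consequence enum.
CLASSIFICATION_TO_CONSEQUENCE = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift_ins",
    "Frame_Shift_Del": "frameshift_del",
    "In_Frame_Ins": "inframe_ins",
    "In_Frame_Del": "inframe_del",
    "Splice_Site": "splice_site",
    "Silent": "synonymous",
    "Intron": "intron",
    "IGR": "intergenic",
    "3'UTR": "utr",
    "5'UTR": "utr",
    "3'Flank": "other",
    "5'Flank": "other",
    "RNA": "other",
    "Translation_Start_Site": "other",
    "Nonstop_Mutation": "other",
}

#: Consequence classes that alter the protein product: nonsense, missense,
#: insertions, deletions and splice-site variants.
PROTEIN_ALTERING = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_ins",
        "frameshift_del",
        "inframe_ins",
        "inframe_del",
        "splice_site",
    }
)


class MafFormatError(ValueError):
    """A MAF-dialect file violates the expected schema."""


def _variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF-dialect TSV into a per-observation variant-call table.

    One row per (variant, sample) observation.  Adds derived columns:
    ``variant_id`` (chrom:pos:ref:alt), ``consequence`` (enum; unknown
    classification strings map to ``other``), ``tumor_vaf`` and
    ``blood_vaf``.  Rows with zero total depth in either the tumor or the
    blood sample are dropped, with the drop count logged and stored in
    ``table.attrs["n_dropped_zero_depth"]``.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    MafFormatError
        If a required column is missing or a depth field is non-numeric
        (the error names the column / line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise MafFormatError(f"missing required column(s): {', '.join(missing)}")
    for col in _INT_COLUMNS + _FLOAT_COLUMNS:
        try:
            table[col] = pd.to_numeric(table[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(table[col], errors="coerce").isna()
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise MafFormatError(
                f"non-numeric value in column {col!r} at line {line}"
            ) from None
    for col in _INT_COLUMNS:
        table[col] = table[col].astype(int)
    if ((table[_INT_COLUMNS[1:]] < 0).any().any()) or (table["Start_Position"] < 1).any():
        raise MafFormatError("negative read count or non-positive position")

    zero_depth = (table["t_ref_count"] + table["t_alt_count"] == 0) | (
        table["n_ref_count"] + table["n_alt_count"] == 0
    )
    n_dropped = int(zero_depth.sum())
    if n_dropped:
        logger.info("read_maf: dropped %d row(s) with zero total depth", n_dropped)
    table = table.loc[~zero_depth].reset_index(drop=True)
    table = annotate_maf(table)
    table.attrs["n_dropped_zero_depth"] = n_dropped
    return table


def annotate_maf(table: pd.DataFrame) -> pd.DataFrame:
    """Add the derived columns ``variant_id``, ``consequence``, ``tumor_vaf``
    and ``blood_vaf`` to a raw MAF-dialect table (returns a copy)."""
    table = table.copy()
    table["variant_id"] = [
        _variant_id(c, p, r, a)
        for c, p, r, a in zip(
            table["Chromosome"],
            table["Start_Position"],
            table["Reference_Allele"],
            table["Tumor_Seq_Allele2"],
        )
    ]
    table["consequence"] = (
        table["Variant_Classification"].map(CLASSIFICATION_TO_CONSEQUENCE).fillna("other")
    )
    table["tumor_vaf"] = table["t_alt_count"] / (table["t_ref_count"] + table["t_alt_count"])
    table["blood_vaf"] = table["n_alt_count"] / (table["n_ref_count"] + table["n_alt_count"])
    return table


def write_maf(table: pd.DataFrame, path: str | Path) -> None:
    """Write a variant-call table back out in the same MAF dialect."""
    table[REQUIRED_COLUMNS].to_csv(path, sep="\t", index=False)


def compute_vaf(ref_count: int, alt_count: int) -> float:
    """Variant allele fraction: alt / (ref + alt), exact rational division.

    Raises ``ValueError`` on zero total depth or negative counts.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total == 0:
        raise ValueError("zero total depth: VAF undefined")
    return float(Fraction(alt_count, total))


def quality_gate(
    table: pd.DataFrame, min_lod: float = 4.0, min_base_quality: float = 10.0
) -> pd.DataFrame:
    """Retain calls with lod >= min_lod and base_quality >= min_base_quality.

    Thresholds are inclusive ("minimum" means the stated value passes).
    Row order is preserved.
    """
    if min_lod < 0 or min_base_quality < 0:
        raise ValueError("quality thresholds must be non-negative")
    keep = (table["lod"] >= min_lod) & (table["base_quality"] >= min_base_quality)
    return table.loc[keep].reset_index(drop=True)


def select_protein_altering(table: pd.DataFrame) -> pd.DataFrame:
    """Retain protein-altering calls (missense, nonsense, indel, splice site).

    Synonymous, intronic, intergenic, UTR and other non-coding classes are
    removed: they are far less likely to be pathogenic.
    """
    keep = table["consequence"].isin(PROTEIN_ALTERING)
    return table.loc[keep].reset_index(drop=True)
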