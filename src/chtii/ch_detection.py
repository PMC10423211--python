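"""Classify variants as clonally expanded somatic (CH) mutations in TII cells.

A somatic variant is called a clonal hematopoietic (CH) mutation present in
tumor-infiltrating immune (TII) cells when its variant allele fraction lies
strictly inside the (2%, 25%) window in *both* the blood and the tumor
sample.  The 2% floor is the accepted clonal-hematopoiesis detection
threshold (it also excludes circulating tumor / cell-free DNA); the 25%
ceiling excludes heterozygous germline variants (VAF ~ 50%).  Binomial
proportion confidence intervals quantify the sampling uncertainty of each
VAF given its read depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ChCallConfig:
    """Thresholds for the dual-sample VAF window.

    vaf_lower/vaf_upper bound the clonal window (strict inequalities);
    ci_level is the confidence level for binomial VAF intervals.
    """

    vaf_lower: float = 0.02
    vaf_upper: float = 0.25
    ci_level: float = 0.95
    ci_method: str = "wilson"

    def __post_init__(self):
        if not (0 <= self.vaf_lower < self.vaf_upper <= 1):
            raise ValueError("require 0 <= vaf_lower < vaf_upper <= 1")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class ChCall:
    """Per-sample classification of one variant observation."""

    sample_id: str
    variant_id: str
    tumor_vaf: float
    blood_vaf: float
    tumor_depth: int
    blood_depth: int
    tumor_ci: tuple[float, float]
    blood_ci: tuple[float, float]
    is_ch_in_tii: bool
    reason: str  # pass | below_lower_* | germline_range_*


def binomial_ci(
    alt_count: int, depth: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion alt_count/depth.

    Default is the Wilson score interval, which behaves sensibly at boundary
    counts (0 or depth alt reads); ``wald`` and ``clopper-pearson`` are also
    available.  The interval is a subset of [0, 1] and contains the point
    estimate.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0 <= alt_count <= depth):
        raise ValueError("alt_count must be in [0, depth]")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    p = alt_count / depth
    z = stats.norm.ppf(1 - (1 - level) / 2)
    if method == "wilson":
        denom = 1 + z * z / depth
        center = (p + z * z / (2 * depth)) / denom
        half = (z / denom) * math.sqrt(p * (1 - p) / depth + z * z / (4 * depth * depth))
        lo, hi = center - half, center + half
        # at boundary counts the Wilson bound is exactly the boundary
        if alt_count == 0:
            lo = 0.0
        if alt_count == depth:
            hi = 1.0
    elif method == "wald":
        half = z * math.sqrt(p * (1 - p) / depth)
        lo, hi = p - half, p + half
    elif method == "clopper-pearson":
        alpha = 1 - level
        lo = 0.0 if alt_count == 0 else stats.beta.ppf(alpha / 2, alt_count, depth - alt_count + 1)
        hi = (
            1.0
            if alt_count == depth
            else stats.beta.ppf(1 - alpha / 2, alt_count + 1, depth - alt_count)
        )
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return (max(0.0, lo), min(1.0, hi))


def classify_ch(call, config: ChCallConfig = ChCallConfig()) -> ChCall:
    """Classify one per-sample variant observation against the VAF window.

    *call* is a mapping (e.g. a DataFrame row) with t_ref_count, t_alt_count,
    n_ref_count, n_alt_count, sample id and variant id fields.  The call
    passes iff vaf_lower < VAF < vaf_upper in both samples (strict); a
    failing call carries the first applicable reason code among
    below_lower_blood, below_lower_tumor, germline_range_blood,
    germline_range_tumor.
    """
    t_depth = int(call["t_ref_count"]) + int(call["t_alt_count"])
    n_depth = int(call["n_ref_count"]) + int(call["n_alt_count"])
    if t_depth <= 0 or n_depth <= 0:
        raise ValueError("zero total depth in tumor or blood sample")
    tumor_vaf = int(call["t_alt_count"]) / t_depth
    blood_vaf = int(call["n_alt_count"]) / n_depth

    if blood_vaf <= config.vaf_lower:
        reason = "below_lower_blood"
    elif tumor_vaf <= config.vaf_lower:
        reason = "below_lower_tumor"
    elif blood_vaf >= config.vaf_upper:
        reason = "germline_range_blood"
    elif tumor_vaf >= config.vaf_upper:
        reason = "germline_range_tumor"
    else:
        reason = "pass"

    return ChCall(
        sample_id=str(call["Tumor_Sample_Barcode"]) if "Tumor_Sample_Barcode" in call else str(call["sample_id"]),
        variant_id=str(call["variant_id"]),
        tumor_vaf=tumor_vaf,
        blood_vaf=blood_vaf,
        tumor_depth=t_depth,
        blood_depth=n_depth,
        tumor_ci=binomial_ci(int(call["t_alt_count"]), t_depth, config.ci_level, config.ci_method),
        blood_ci=binomial_ci(int(call["n_alt_count"]), n_depth, config.ci_level, config.ci_method),
        is_ch_in_tii=reason == "pass",
        reason=reason,
    )


def summarize_variant(calls: list[ChCall], n_cohort: int) -> dict:
    """Cross-sample aggregate for one variant.

    sample_fraction is (number of samples whose call passes the window) /
    n_cohort.  VAF mean and sample standard deviation (n-1 denominator) are
    computed over the passing samples only — the samples in which the
    clonally expanded variant is actually detected; they are absent (None)
    when no sample passes.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    variant_ids = {c.variant_id for c in calls}
    if len(variant_ids) != 1:
        raise ValueError("calls span multiple variants")
    n_distinct = len({c.sample_id for c in calls})
    if n_cohort < n_distinct:
        raise ValueError("n_cohort smaller than number of distinct samples")
    passing = [c for c in calls if c.is_ch_in_tii]
    n_pass = len({c.sample_id for c in passing})
    out = {
        "variant_id": variant_ids.pop(),
        "n_obs": len(calls),
        "n_pass": n_pass,
        "sample_fraction": n_pass / n_cohort,
        "tumor_vaf_mean": None,
        "tumor_vaf_sd": None,
        "blood_vaf_mean": None,
        "blood_vaf_sd": None,
    }
    if passing:
        tv = np.array([c.tumor_vaf for c in passing])
        bv = np.array([c.blood_vaf for c in passing])
        out["tumor_vaf_mean"] = float(tv.mean())
        out["blood_vaf_mean"] = float(bv.mean())
        if len(passing) > 1:
            out["tumor_vaf_sd"] = float(tv.std(ddof=1))
            out["blood_vaf_sd"] = float(bv.std(ddof=1))
    return out


def classify_table(
    table: pd.DataFrame, n_cohort: int, config: ChCallConfig = ChCallConfig()
) -> pd.DataFrame:
    """Classify every observation in a variant-call table and summarize per variant.

    Returns one row per distinct variant with gene, protein change, passing
    counts, sample fraction and VAF moments over passing samples.
    """
    rows = []
    for variant_id, group in table.groupby("variant_id", sort=False):
        calls = [classify_ch(row, config) for _, row in group.iterrows()]
        summary = summarize_variant(calls, n_cohort)
        summary["gene"] = group["Hugo_Symbol"].iloc[0]
        summary["protein_change"] = group["Protein_Change"].iloc[0]
        summary["consequence"] = group["consequence"].iloc[0]
        rows.append(summary)
    columns = [
        "variant_id",
        "gene",
        "protein_change",
        "consequence",
        "n_obs",
        "n_pass",
        "sample_fraction",
        "tumor_vaf_mean",
        "tumor_vaf_sd",
        "blood_vaf_mean",
        "blood_vaf_sd",
    ]
    return pd.DataFrame(rows, columns=columns)
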