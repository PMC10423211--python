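"""Differential expression between mutation carriers and non-carriers.

Per gene, a two-sided Welch t test (unequal variances, Satterthwaite
degrees of freedom) compares bulk expression between the samples carrying a
candidate mutation and those not carrying it; p values are adjusted across
genes with the Benjamini-Hochberg step-up procedure, and genes with
adjusted q < 0.05 are flagged as significantly differentially expressed
(SDE).  SDE genes are then tabulated against a gene -> top-level-pathway map.

The t statistic and the BH adjustment are implemented here from their
defining formulas:

    t  = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny)
    df = (s2x/nx + s2y/ny)^2 / [ (s2x/nx)^2/(nx-1) + (s2y/ny)^2/(ny-1) ]

with a two-sided p value from Student's t with that df, and

    q(i) = min_{j : p(j) >= p(i)}  p(j) * m / rank(j)

computed by the usual cumulative-minimum pass over sorted p values.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("chtii")


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t test with Satterthwaite degrees of freedom.

    Returns (t_stat, df, two-sided p value).  Requires at least two
    observations per group and nonzero variance in at least one group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance")
    se2x, se2y = vx / nx, vy / ny
    se2 = se2x + se2y
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q values, in the input order.

    Standard step-up: sort ascending, q_(i) = p_(i) * m / i, then take the
    cumulative minimum from the largest rank down (so q is monotone in the p
    ranks and ties share one value), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_de(
    expr: pd.DataFrame, carriers, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-gene Welch t test of carriers vs non-carriers with BH adjustment.

    *expr* is a genes x samples table of finite expression values; *carriers*
    is the set of carrier sample ids (2 <= |carriers| <= n_samples - 2).
    Genes with zero variance in both groups are untestable: they are skipped,
    counted in ``result.attrs["n_skipped_zero_variance"]``, and excluded from
    the BH correction so they do not dilute it.  SDE iff q < fdr (strict).
    """
    carriers = set(carriers)
    samples = list(expr.columns)
    unknown = carriers - set(samples)
    if unknown:
        raise ValueError(f"carrier sample(s) not in expression table: {sorted(unknown)[:3]}")
    non_carriers = [s for s in samples if s not in carriers]
    if len(carriers) < 2 or len(non_carriers) < 2:
        raise ValueError("need at least 2 carriers and 2 non-carriers")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression values must be finite")

    carrier_cols = [s for s in samples if s in carriers]
    xmat = expr[carrier_cols].to_numpy(dtype=float)
    ymat = expr[non_carriers].to_numpy(dtype=float)

    rows, skipped = [], 0
    for i, gene in enumerate(expr.index):
        x, y = xmat[i], ymat[i]
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            skipped += 1
            continue
        t, df, p = welch_t(x, y)
        rows.append(
            {
                "gene": gene,
                "mean_carrier": float(x.mean()),
                "mean_noncarrier": float(y.mean()),
                "t_stat": t,
                "df": df,
                "p_value": p,
            }
        )
    if skipped:
        logger.info("run_de: skipped %d zero-variance gene(s)", skipped)
    result = pd.DataFrame(
        rows, columns=["gene", "mean_carrier", "mean_noncarrier", "t_stat", "df", "p_value"]
    )
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
        result["sde"] = result["q_value"] < fdr
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["sde"] = pd.Series(dtype=bool)
    result.attrs["n_skipped_zero_variance"] = skipped
    return result


def tabulate_pathways(sde_genes, pathway_map: pd.DataFrame) -> dict[str, int]:
    """Count SDE genes per top-level pathway.

    *pathway_map* is a two-column table (gene, pathway), many-to-many: a gene
    mapped to k pathways contributes 1 to each.  Genes with no mapping are
    counted under the explicit ``"unmapped"`` bucket.
    """
    gene_to_pathways: dict[str, list[str]] = {}
    for gene, pathway in zip(pathway_map["gene"], pathway_map["pathway"]):
        gene_to_pathways.setdefault(gene, []).append(pathway)
    counts: Counter[str] = Counter()
    for gene in sde_genes:
        pathways = gene_to_pathways.get(gene)
        if pathways:
            counts.update(set(pathways))
        else:
            counts["unmapped"] += 1
    return dict(counts)
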