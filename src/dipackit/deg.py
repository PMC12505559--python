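"""Normalization and differential expression.

Counts are normalized with median-of-ratios size factors. Differential
expression between two groups uses a negative-binomial moments model: per-gene
log2 fold change of normalized group means (with a pseudocount), a
method-of-moments dispersion moderated toward the genome-wide trimmed mean,
a delta-method standard error on the log2 scale, and a two-sided normal
p-value on the Wald statistic, followed by Benjamini-Hochberg adjustment.

The classifier downstream only consumes (log2fc, padj) pairs, so precomputed
tables from any external DE tool can be substituted as long as they carry the
``DegResult`` columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

__all__ = [
    "compute_size_factors",
    "normalized_counts",
    "test_differential_expression",
    "bh_adjust",
    "top_deg_table",
]

#: columns every DE result table carries, in order
DEG_COLUMNS = ["log2fc", "se", "pvalue", "padj", "mean_expr"]


def compute_size_factors(
    cm: CountMatrix, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene positive in every sample, the ratio of its count to its
    across-sample geometric mean is formed; the size factor of a sample is the
    median of these ratios. Genes with a zero anywhere are excluded from the
    reference; if none remain, ``allow_pseudo_reference=True`` falls back to
    geometric means computed over the positive entries only.
    """
    k = cm.counts.to_numpy(dtype=float)
    all_positive = (k > 0).all(axis=1)
    if all_positive.any():
        ref = k[all_positive]
        log_gm = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_gm[:, None]
    elif allow_pseudo_reference:
        any_positive = (k > 0).any(axis=1)
        if not any_positive.any():
            raise ValueError("count matrix is all zero")
        ref = k[any_positive]
        with np.errstate(divide="ignore"):
            logs = np.where(ref > 0, np.log(ref), np.nan)
        log_gm = np.nanmean(logs, axis=1)
        ratios = np.where(ref > 0, logs - log_gm[:, None], np.nan)
    else:
        raise ValueError(
            "no gene has positive counts in every sample; rerun with "
            "allow_pseudo_reference=True to use a positive-entry pseudo-reference"
        )
    log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=cm.sample_ids, name="size_factor")


def normalized_counts(cm: CountMatrix, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided per sample by the size factor."""
    if size_factors is None:
        size_factors = compute_size_factors(cm)
    return cm.counts / size_factors


def test_differential_expression(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
    dispersion_shrink: float = 0.9,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene contrast statistics for ``group_b`` over ``group_a``.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``se``,
    ``pvalue``, ``padj``, ``mean_expr``. ``log2fc`` is the log2 ratio of
    normalized group means after adding ``pseudocount`` to each mean, so zeros
    stay finite.

    Gene-wise dispersions alpha (raw-count variance = mu + alpha*mu^2) come
    from pooled within-group moments of the normalized counts, corrected for
    size-factor heterogeneity: for counts K_j ~ NB(s_j mu, alpha), the
    normalized within-group variance has expectation mu*mean(1/s_j) +
    alpha*mu^2, and the variance of the normalized group mean is
    (mu*mean(1/s_j) + alpha*mu^2)/n. With only a handful of replicates the
    per-gene moment estimate carries very few degrees of freedom, so it is
    shrunk ``dispersion_shrink`` (default 0.9) of the way toward the mean
    dispersion across expressed genes before entering the Wald standard
    error — heavy moderation is what keeps the normal-approximation p-values
    calibrated at n = 4 per group.
    """
    samples_a = cm.samples_in(group_a)
    samples_b = cm.samples_in(group_b)
    n_a, n_b = len(samples_a), len(samples_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need at least 2 samples")

    if size_factors is None:
        size_factors = compute_size_factors(cm)
    norm = cm.counts / size_factors
    a = norm[samples_a].to_numpy(dtype=float)
    b = norm[samples_b].to_numpy(dtype=float)
    inv_a = float((1.0 / size_factors[samples_a]).mean())
    inv_b = float((1.0 / size_factors[samples_b]).mean())

    m_a = a.mean(axis=1)
    m_b = b.mean(axis=1)
    log2fc = np.log2((m_b + pseudocount) / (m_a + pseudocount))

    # method-of-moments dispersion from pooled within-group variance
    v_a = a.var(axis=1, ddof=1)
    v_b = b.var(axis=1, ddof=1)
    v_pool = ((n_a - 1) * v_a + (n_b - 1) * v_b) / (n_a + n_b - 2)
    mu_pool = (n_a * m_a + n_b * m_b) / (n_a + n_b)
    c_pool = (n_a * inv_a + n_b * inv_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v_pool - mu_pool * c_pool) / mu_pool**2
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)
    expressed = mu_pool > 0
    alpha_prior = float(alpha[expressed].mean()) if expressed.any() else dispersion_floor
    alpha = (1.0 - dispersion_shrink) * alpha + dispersion_shrink * alpha_prior

    # delta method: Var(log2(mean + c)) ~= Var(mean) / ((mean + c) ln 2)^2
    ln2_sq = np.log(2.0) ** 2
    var_mean_a = (m_a * inv_a + alpha * m_a**2) / n_a
    var_mean_b = (m_b * inv_b + alpha * m_b**2) / n_b
    var_log = var_mean_a / ((m_a + pseudocount) ** 2 * ln2_sq) + var_mean_b / (
        (m_b + pseudocount) ** 2 * ln2_sq
    )
    se = np.sqrt(var_log)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": np.where(se > 0, se, np.inf),
            "pvalue": pvalue,
            "padj": padj,
            "mean_expr": norm.to_numpy()[:, :].mean(axis=1),
        },
        index=cm.gene_ids,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def top_deg_table(
    deg: pd.DataFrame, alpha: float = 0.001, k: int = 15
) -> pd.DataFrame:
    """The ``k`` most up- and ``k`` most downregulated significant genes.

    Genes with ``padj < alpha`` are ranked by log2 fold change; ties are broken
    by smaller ``padj``, then lexicographic gene id. The returned table carries
    a ``direction`` column (``up`` for the highest fold changes, ``down`` for
    the lowest) and may be empty.
    """
    sig = deg[deg["padj"] < alpha].copy()
    if sig.empty:
        out = deg.iloc[0:0].copy()
        out["direction"] = pd.Series(dtype=str)
        return out
    sig = sig.reset_index().rename(columns={sig.index.name or "index": "gene_id"})
    up = sig.sort_values(
        ["log2fc", "padj", "gene_id"], ascending=[False, True, True]
    ).head(k)
    down = sig.sort_values(
        ["log2fc", "padj", "gene_id"], ascending=[True, True, True]
    ).head(k)
    up = up.assign(direction="up")
    down = down.assign(direction="down")
    out = pd.concat([up, down], ignore_index=True).set_index("gene_id")
    return out
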