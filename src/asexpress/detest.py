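"""Negative-binomial two-group differential expression test.

A deliberately compact DESeq2-style analogue: median-of-ratios size
factors, per-gene method-of-moments dispersion shrunk toward a fitted
mean-dispersion trend, a Wald test on the log fold change of the two
group means, and Benjamini-Hochberg correction over tested genes.

Counts are modelled NB with Var = mu + alpha * mu^2. The Wald statistic is
referred to a moderated t distribution with 4*(n - 2) degrees of freedom
rather than the normal: the per-gene residual df is small and the trended
dispersion shrinkage adds borrowed information, so a t reference with
inflated df keeps the false discovery rate at its nominal level without
the overconfidence of the plain normal (same idea as limma's moderated t;
converges to the normal as samples grow). No Cox-Reid adjustment, no
outlier refitting, no independent filtering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 20.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes nonzero in all samples of
    count_gj / geometric_mean_g. Falls back to column-total ratios
    (normalized to geometric mean 1) when no gene is nonzero everywhere.
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if all_nonzero.any():
        sub = arr[all_nonzero]
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning("no gene nonzero in all samples; using column-total size factors")
        totals = arr.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _dispersion_trend(mu: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by non-negative least squares on genes
    with a positive raw estimate; evaluate at every gene's mean."""
    ok = (alpha_raw > 0) & (mu > 0) & np.isfinite(alpha_raw)
    if ok.sum() < 10:
        fallback = float(np.median(alpha_raw[ok])) if ok.any() else 0.01
        return np.full_like(mu, max(fallback, DISPERSION_FLOOR))
    design = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, _ = optimize.nnls(design, alpha_raw[ok])
    # one trimming pass: refit without gross outliers above 10x the trend
    fitted = design @ coef
    keep = alpha_raw[ok] < 10 * np.maximum(fitted, DISPERSION_FLOOR)
    if keep.sum() >= 10:
        coef, _ = optimize.nnls(design[keep], alpha_raw[ok][keep])
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(mu, 1e-12)
    return np.clip(trend, DISPERSION_FLOOR, DISPERSION_CEIL)


def estimate_dispersions(
    scaled: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Method-of-moments per-gene dispersion on size-factor-scaled counts,
    shrunk toward the fitted mean-dispersion trend.

    Returns (alpha_final, alpha_raw, alpha_trend). The shrinkage weight on
    the trend is n_eff / (n_eff + 4) with n_eff = n_samples - n_groups.
    """
    n = scaled.shape[1]
    n_groups = len(group_idx)
    n_eff = max(n - n_groups, 1)
    mu = scaled.mean(axis=1)
    # pooled within-group variance
    ss = np.zeros(scaled.shape[0])
    for idx in group_idx:
        sub = scaled[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var_within = ss / n_eff
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (var_within - mu) / mu**2
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, 0.0)
    alpha_trend = _dispersion_trend(mu, alpha_raw)
    w = n_eff / (n_eff + 4.0)
    alpha = w * alpha_trend + (1.0 - w) * alpha_raw
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)
    return alpha, alpha_raw, alpha_trend


def nb_de_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of group B over group A per gene.

    Returns a DataFrame indexed by gene with columns base_mean, log2fc,
    se_log2fc, wald_p, padj, tested. Genes with all-zero counts are
    untested (NaN statistics, tested=False).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    missing = (set(group_a) | set(group_b)) - set(counts.columns)
    if missing:
        raise ValueError(f"samples not in count matrix: {sorted(missing)}")
    sub = counts[group_a + group_b]
    if factors is None:
        factors = size_factors(sub)
    sf = factors.reindex(sub.columns).to_numpy(dtype=float)
    arr = sub.to_numpy(dtype=float)
    scaled = arr / sf[None, :]
    idx_a = np.arange(len(group_a))
    idx_b = np.arange(len(group_a), len(group_a) + len(group_b))

    tested = arr.sum(axis=1) > 0
    alpha, _, _ = estimate_dispersions(scaled, [idx_a, idx_b])

    mu_a = scaled[:, idx_a].mean(axis=1)
    mu_b = scaled[:, idx_b].mean(axis=1)
    # +0.5 pseudo-mean only when a group mean is exactly zero
    mu_a_t = np.where(mu_a == 0, 0.5, mu_a)
    mu_b_t = np.where(mu_b == 0, 0.5, mu_b)

    def var_log_mean(mu_t, idx):
        n_g = len(idx)
        inv_sf = (1.0 / sf[idx]).sum()
        var_mean = (mu_t * inv_sf + alpha * mu_t**2 * n_g) / n_g**2
        return var_mean / mu_t**2

    var_ln = var_log_mean(mu_a_t, idx_a) + var_log_mean(mu_b_t, idx_b)
    se_ln = np.sqrt(var_ln)
    log2fc = np.log2(mu_b_t / mu_a_t)
    se_log2fc = se_ln / np.log(2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.log(mu_b_t / mu_a_t) / se_ln
    n_eff = max(len(group_a) + len(group_b) - 2, 1)
    wald_p = 2.0 * stats.t.sf(np.abs(z), df=4 * n_eff)
    wald_p = np.clip(wald_p, 0.0, 1.0)

    padj = np.full(len(arr), np.nan)
    if tested.any():
        padj[tested] = multipletests(wald_p[tested], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "base_mean": scaled.mean(axis=1),
            "log2fc": log2fc,
            "se_log2fc": se_log2fc,
            "wald_p": wald_p,
            "padj": padj,
            "tested": tested,
        },
        index=sub.index,
    )
    out.loc[~tested, ["base_mean", "log2fc", "se_log2fc", "wald_p", "padj"]] = np.nan
    out.loc[~tested, "base_mean"] = 0.0
    return out


def call_de_sets(
    de: pd.DataFrame, alpha: float = 0.05, min_l2fc: float = 0.0
) -> tuple[set, set]:
    """Extract up- and downregulated gene sets at padj < alpha.

    min_l2fc (default 0) optionally requires |log2fc| > min_l2fc as well.
    alpha = 0 is allowed and yields empty sets (the cut is strict).
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    sig = de["tested"] & (de["padj"] < alpha) & (de["log2fc"].abs() > min_l2fc)
    up = set(de.index[sig & (de["log2fc"] > 0)])
    down = set(de.index[sig & (de["log2fc"] < 0)])
    return up, down
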