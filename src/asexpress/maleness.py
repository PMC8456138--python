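"""PCA-LDA maleness score.

A sex classifier trained on males and females of the sexual species:
log2(x+1) transform of normalized expression, per-gene centering, PCA on
the training samples, and a two-class Fisher discriminant on the retained
principal-component scores. The first discriminant (LD1) is oriented so
males score higher; projecting asexual females gives their "maleness
score" without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sexbias import MalenessComparison


@dataclass
class MalenessModel:
    gene_ids: list
    center: np.ndarray  # per-gene mean of log2(x+1) on training data
    loadings: np.ndarray  # genes x q principal axes
    variance_explained: np.ndarray
    w: np.ndarray  # discriminant axis over PC space (orientation folded in)
    ld1_train: pd.Series
    class_means: dict  # 'M'/'F' -> mean training LD1
    ld1_train_loo: pd.Series | None = None  # leave-one-out projected scores

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "center": self.center.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "w": self.w.tolist(),
            "ld1_train": self.ld1_train.to_dict(),
            "class_means": self.class_means,
            "ld1_train_loo": None if self.ld1_train_loo is None else self.ld1_train_loo.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MalenessModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gene_ids=d["gene_ids"],
            center=np.asarray(d["center"]),
            loadings=np.asarray(d["loadings"]),
            variance_explained=np.asarray(d["variance_explained"]),
            w=np.asarray(d["w"]),
            ld1_train=pd.Series(d["ld1_train"]),
            class_means=d["class_means"],
            ld1_train_loo=None
            if d.get("ld1_train_loo") is None
            else pd.Series(d["ld1_train_loo"]),
        )


def _log_transform(expr: pd.DataFrame) -> np.ndarray:
    arr = expr.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("expression must be non-negative (unnormalized input?)")
    return np.log2(arr + 1.0)


def fit_maleness_model(
    expr_train: pd.DataFrame,
    labels: pd.Series,
    pc_rule: float | int = 0.9,
    ridge: float = 1e-6,
    loo_scores: bool = True,
    loo_groups: pd.Series | None = None,
) -> MalenessModel:
    """Fit the PCA-LDA sex model on training samples (columns of expr_train).

    labels: per-sample 'M'/'F'. pc_rule: fraction of variance to retain
    (default 0.9) or an explicit integer PC count; always capped at
    n_train - 3 so the pooled covariance stays invertible. Genes are
    centered but not variance-scaled (input is already quantile-normalized
    and log-transformed internally).

    With loo_scores (default), each training sample is also projected from
    a model refit without it. In-sample LD1 scores are optimistically
    biased outward along the discriminant (a small-sample LDA always
    over-separates its own training classes), so comparisons of new
    samples against the training sexes must use these held-out scores to
    be apples-to-apples. When loo_groups is given (e.g. lineage x sex), the
    whole group of a sample is held out together: replicates left in
    training otherwise leak the group's profile into the refit, and the
    proper reference for scoring a lineage the model never saw is training
    samples scored by models that never saw their lineage either.
    """
    labels = labels.reindex(expr_train.columns)
    if labels.isna().any():
        raise ValueError("missing sex labels for training samples")
    n_m, n_f = (labels == "M").sum(), (labels == "F").sum()
    if n_m < 2 or n_f < 2:
        raise ValueError("need >= 2 training samples per sex")
    x = _log_transform(expr_train)  # genes x samples
    center = x.mean(axis=1)
    xc = (x - center[:, None]).T  # samples x genes
    n_train = xc.shape[0]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # fix PCA signs: largest-magnitude loading positive per axis
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s**2 / max(n_train - 1, 1)
    frac = var / var.sum()
    cap = max(n_train - 3, 1)
    if isinstance(pc_rule, int) and not isinstance(pc_rule, bool):
        q = pc_rule
    else:
        q = int(np.searchsorted(np.cumsum(frac), pc_rule) + 1)
    q = int(np.clip(q, 1, min(cap, len(s))))
    loadings = vt[:q].T  # genes x q
    scores = u[:, :q] * s[:q]  # samples x q

    is_m = (labels == "M").to_numpy()
    mu_m = scores[is_m].mean(axis=0)
    mu_f = scores[~is_m].mean(axis=0)
    resid_m = scores[is_m] - mu_m
    resid_f = scores[~is_m] - mu_f
    s_pooled = (resid_m.T @ resid_m + resid_f.T @ resid_f) / max(n_train - 2, 1)
    s_pooled = s_pooled + np.eye(q) * (ridge * np.trace(s_pooled) / q)
    w = np.linalg.solve(s_pooled, mu_m - mu_f)
    # unit norm in gene space (loadings are orthonormal) so LD1 is in
    # log2-expression units and comparable across refits (e.g. leave-one-out)
    w = w / np.linalg.norm(w)
    ld1 = scores @ w
    if ld1[is_m].mean() < ld1[~is_m].mean():
        w = -w
        ld1 = -ld1
    # zero LD1 at the midpoint between class means, not the overall mean:
    # with unbalanced classes the overall mean sits off-midpoint and would
    # bias projections of new samples. Fold the offset into the centering
    # vector so scoring needs no extra bookkeeping.
    mid = (ld1[is_m].mean() + ld1[~is_m].mean()) / 2.0
    ld1 = ld1 - mid
    center = center + mid * (loadings @ w)
    ld1_train = pd.Series(ld1, index=expr_train.columns, name="LD1")
    model = MalenessModel(
        gene_ids=list(expr_train.index),
        center=center,
        loadings=loadings,
        variance_explained=frac[:q],
        w=w,
        ld1_train=ld1_train,
        class_means={"M": float(ld1[is_m].mean()), "F": float(ld1[~is_m].mean())},
    )
    if loo_scores and n_m >= 3 and n_f >= 3:
        cols = list(expr_train.columns)
        if loo_groups is not None:
            grp = loo_groups.reindex(cols)
            folds = [list(grp.index[grp == g]) for g in grp.unique()]
        else:
            folds = [[c] for c in cols]
        loo = {}
        for held in folds:
            rest = [c for c in cols if c not in held]
            lab_rest = labels.reindex(rest)
            if (lab_rest == "M").sum() < 2 or (lab_rest == "F").sum() < 2:
                continue  # fold would leave too few samples; skip its scores
            sub = fit_maleness_model(
                expr_train[rest], lab_rest, pc_rule=pc_rule,
                ridge=ridge, loo_scores=False,
            )
            held_scores = maleness_scores(sub, expr_train[held])
            for sid, val in held_scores.items():
                loo[sid] = float(val)
        if loo:
            model.ld1_train_loo = pd.Series(loo, name="LD1_loo").reindex(expr_train.columns)
    return model


def maleness_scores(model: MalenessModel, expr_new: pd.DataFrame) -> pd.Series:
    """Project new samples onto LD1 using the stored centering and axes."""
    missing = set(model.gene_ids) - set(expr_new.index)
    if missing:
        raise ValueError(f"samples missing model genes: {sorted(missing)[:5]}")
    x = _log_transform(expr_new.loc[model.gene_ids])
    xc = (x - model.center[:, None]).T
    scores = xc @ model.loadings
    return pd.Series(scores @ model.w, index=expr_new.columns, name="LD1")


def score_comparison(
    asexual_scores: pd.Series,
    female_scores: pd.Series,
    male_scores: pd.Series,
    female_range: tuple[float, float] | None = None,
) -> MalenessComparison:
    """Rank-sum tests of asexual LD1 scores vs each training sex, plus the
    fraction of asexual scores inside the training-female range.

    female_range optionally widens the range used for the overlap fraction
    (e.g. the envelope of in-sample and held-out female projections, which
    bracket where a female-like sample can score); the rank-sum tests
    always use the score vectors as given.
    """
    for name, s in (("female", female_scores), ("male", male_scores)):
        if len(s) < 2:
            raise ValueError(f"empty/degenerate {name} score group")
    a = asexual_scores.to_numpy()
    f = female_scores.to_numpy()
    m = male_scores.to_numpy()
    if len(a) >= 2:
        p_f = float(stats.mannwhitneyu(a, f, alternative="two-sided").pvalue)
        p_m = float(stats.mannwhitneyu(a, m, alternative="two-sided").pvalue)
    else:
        p_f = p_m = np.nan
    lo, hi = (f.min(), f.max()) if female_range is None else female_range
    overlap = float(np.mean((a >= lo) & (a <= hi))) if len(a) else np.nan
    scores = pd.concat([female_scores, male_scores, asexual_scores])
    groups = pd.Series(
        ["train_F"] * len(f) + ["train_M"] * len(m) + ["asexual"] * len(a),
        index=scores.index,
    )
    return MalenessComparison(
        scores=scores,
        groups=groups,
        p_vs_female=p_f,
        p_vs_male=p_m,
        overlap_female_range=overlap,
        medians={
            "train_F": float(np.median(f)),
            "train_M": float(np.median(m)),
            "asexual": float(np.median(a)) if len(a) else np.nan,
        },
    )


def loo_accuracy(expr_train: pd.DataFrame, labels: pd.Series, pc_rule: float | int = 0.9) -> float:
    """Leave-one-out sex-classification accuracy (nearest class mean on LD1)."""
    hits = 0
    cols = list(expr_train.columns)
    for held in cols:
        rest = [c for c in cols if c != held]
        lab = labels.reindex(rest)
        if (lab == "M").sum() < 2 or (lab == "F").sum() < 2:
            raise ValueError("too few samples for LOO")
        model = fit_maleness_model(expr_train[rest], lab, pc_rule=pc_rule)
        score = maleness_scores(model, expr_train[[held]]).iloc[0]
        pred = "M" if abs(score - model.class_means["M"]) < abs(score - model.class_means["F"]) else "F"
        hits += pred == labels[held]
    return hits / len(cols)
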