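"""Expression quantification and normalization.

RPKM from raw counts, within-tissue quantile normalization across all
lineages (sexes pooled), and reference-transcript length filtering.
Expression matrices are pandas DataFrames with genes as rows and samples
as columns; sample metadata is a DataFrame indexed by sample id with
columns ``lineage``, ``sex``, ``tissue``, ``replicate``, ``mode``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("M", "F")
MODES = ("sexual", "asexual")


def validate_counts(counts: pd.DataFrame) -> None:
    """Check a count matrix: unique ids on both axes, non-negative integers."""
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")


def validate_meta(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Every count-matrix sample must have exactly one metadata row; asexual
    samples must be female."""
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    bad_sex = meta.loc[~meta["sex"].isin(SEXES)]
    if len(bad_sex):
        raise ValueError(f"unknown sex labels: {bad_sex['sex'].unique()}")
    asex_male = meta[(meta["mode"] == "asexual") & (meta["sex"] == "M")]
    if len(asex_male):
        raise ValueError(f"asexual samples with sex=M: {list(asex_male.index)}")


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[g, j] = count[g, j] / (length_kb[g] * column_total[j] / 1e6).
    Column totals are per-library (per-sample) mapped read totals.
    """
    validate_counts(counts)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing lengths for genes: {list(missing[:5])}")
    lens = lengths.reindex(counts.index).astype(float)
    if (lens <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"zero column total for samples: {zero}")
    rpkm = counts.to_numpy(dtype=float) / lens.to_numpy()[:, None] * 1e3
    rpkm = rpkm / totals.to_numpy()[None, :] * 1e6
    return pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)


def _quantile_normalize_group(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of one group in place of a copy.

    Each column's value at rank r is replaced by the mean over columns of
    their rank-r values; tied values receive the mean of the normalized
    values of their tied ranks (limma-style ties convention).
    """
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(n_samples):
        col = values[:, j]
        assigned = np.empty(n_genes)
        assigned[order[:, j]] = rank_means
        # average assigned values within blocks of tied input values
        srt = order[:, j]
        col_sorted = col[srt]
        block_start = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        block_id = np.cumsum(np.r_[True, col_sorted[1:] != col_sorted[:-1]]) - 1
        sums = np.add.reduceat(rank_means, block_start)
        sizes = np.add.reduceat(np.ones(n_genes), block_start)
        assigned[srt] = (sums / sizes)[block_id]
        out[:, j] = assigned
    return out


def quantile_normalize(expr: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Quantile-normalize within each sample group (typically one per tissue).

    groups maps group name -> list of sample ids. Groups with a single
    sample are returned unchanged with a warning. Samples not listed in any
    group are left untouched.
    """
    out = expr.copy().astype(float)
    for name, samples in groups.items():
        missing = set(samples) - set(expr.columns)
        if missing:
            raise ValueError(f"group {name!r}: unknown samples {sorted(missing)}")
        if len(samples) < 2:
            logger.warning("group %r has < 2 samples; left unnormalized", name)
            continue
        out.loc[:, samples] = _quantile_normalize_group(
            expr.loc[:, samples].to_numpy(dtype=float)
        )
    return out


def tissue_groups(meta: pd.DataFrame, samples: list[str] | None = None) -> dict[str, list[str]]:
    """Partition samples by tissue for within-tissue normalization."""
    sub = meta if samples is None else meta.loc[samples]
    return {t: list(idx) for t, idx in sub.groupby("tissue").groups.items()}


def filter_transcripts(lengths: pd.Series, min_len: int = 500) -> pd.Index:
    """Reference set: genes strictly longer than ``min_len`` bp."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    keep = lengths.index[lengths > min_len]
    return pd.Index(keep)


def average_replicates(
    expr: pd.DataFrame, meta: pd.DataFrame, by: tuple[str, ...] = ("lineage", "sex", "tissue")
) -> pd.DataFrame:
    """Arithmetic mean of normalized expression over biological replicates.

    Returns a DataFrame whose columns are tuples of the grouping keys.
    """
    meta_sub = meta.loc[expr.columns]
    grouped = {}
    for key, idx in meta_sub.groupby(list(by)).groups.items():
        grouped[key] = expr.loc[:, list(idx)].mean(axis=1)
    return pd.DataFrame(grouped)
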