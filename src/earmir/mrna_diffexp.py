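"""Transcript-layer differential expression.

Quantile normalization equalizes the empirical distribution of every array;
rows with no 'Present' call are removed; per-gene Welch two-sample t-tests
with Benjamini-Hochberg correction and a linear fold filter produce the
differential calls (defaults: fold >= 1.3, FDR < 0.1).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataIOError, ExpressionMatrix

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to the row-wise mean of the sorted columns.

    Ties within a column receive the average of the reference quantiles they
    span (rank method 'average'), so the transform is well defined and
    idempotent on tied data.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise DataIOError("quantile normalization needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    ranks = values.rank(method="average").to_numpy()  # 1-based, half-integer ties
    positions = np.arange(1, arr.shape[0] + 1, dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(ranks[:, j], positions, reference)
    normalized = pd.DataFrame(out, index=values.index, columns=values.columns)
    return ExpressionMatrix(normalized, dict(matrix.groups), matrix.flags)


def presence_filter(matrix: ExpressionMatrix, min_present: int = 1) -> ExpressionMatrix:
    """Drop rows with fewer than ``min_present`` 'P' presence calls."""
    if matrix.flags is None:
        raise DataIOError("presence filtering requires a flags matrix")
    n_present = (matrix.flags == "P").sum(axis=1)
    keep = n_present >= min_present
    n_removed = int((~keep).sum())
    logger.info("presence filter removed %d of %d rows", n_removed, len(keep))
    return ExpressionMatrix(
        matrix.values.loc[keep], dict(matrix.groups), matrix.flags.loc[keep]
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH q-values: q_i = min over rank >= rank_i of m*p/rank, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataIOError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test; degenerate rows handled explicitly."""
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        diff = a.mean(axis=1) - b.mean(axis=1)
        zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
        equal = zero_var & (diff == 0)
        unequal = zero_var & (diff != 0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        p = np.where(unequal, 0.0, p)
        t = np.where(unequal, np.sign(diff) * np.inf, t)
    return t, p


def diffexp_mrna(
    matrix: ExpressionMatrix,
    group_a: str = "A",
    group_b: str = "B",
    fold: float = 1.3,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-gene Welch t + BH + fold filter; direction = sign of A - B.

    Fold is computed on anti-logged group means of the log2 values and the
    boundary is inclusive.
    """
    samples_a = [s for s, g in matrix.groups.items() if g == group_a]
    samples_b = [s for s, g in matrix.groups.items() if g == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise DataIOError("each group needs at least 2 samples")
    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    t, p = _welch_rows(a, b)
    q = benjamini_hochberg(p)
    mean_log2_fold = a.mean(axis=1) - b.mean(axis=1)
    linear_fold = 2.0 ** np.abs(mean_log2_fold)
    passes = (linear_fold >= fold * (1.0 - 1e-12)) & (q < fdr)
    call = np.where(
        passes, np.where(mean_log2_fold > 0, "up_in_A", "up_in_B"), "not_de"
    )
    return pd.DataFrame(
        {
            "mean_log2_fold": mean_log2_fold,
            "t": t,
            "p": p,
            "q": q,
            "de_call": call,
        },
        index=matrix.values.index,
    )


def collapse_probes_to_genes(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse to gene level, keeping each gene's highest-mean probe.

    Probes absent from the map are dropped (count logged); gene ids are
    upper-cased to match the other platforms.
    """
    mapping = {p: g.upper() for p, g in probe_to_gene.items()}
    genes = pd.Series([mapping.get(p) for p in matrix.values.index],
                      index=matrix.values.index)
    n_unmapped = int(genes.isna().sum())
    if n_unmapped:
        logger.info("dropping %d unmapped probe(s)", n_unmapped)
    keep = genes.notna()
    values = matrix.values.loc[keep]
    genes = genes.loc[keep]
    means = values.mean(axis=1)
    best = (
        pd.DataFrame({"gene": genes, "mean": means})
        .reset_index(names="probe")
        .sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene")
        .set_index("probe")
    )
    collapsed = values.loc[best.index]
    collapsed.index = best["gene"]
    flags = None
    if matrix.flags is not None:
        flags = matrix.flags.loc[best.index]
        flags.index = best["gene"]
    return ExpressionMatrix(collapsed, dict(matrix.groups), flags)
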