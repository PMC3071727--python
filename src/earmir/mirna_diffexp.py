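"""Two-color miRNA array processing: detection and differential expression.

The workflow mirrors the original array analysis: foreground intensities are
rescaled so every labeled sample has the same mean; a probe is called
detected in a tissue if its (technical-replicate-averaged) spot intensity is
at least ``k_sd`` background standard deviations above the mean background in
at least ``min_samples`` biological replicates; dye-swap technical pairs are
averaged on the log2 ratio scale with the ratio oriented tissue A over
tissue B; a one-sample t-test against zero log-ratio and a fold filter
produce the differential calls; probe-level calls are then summarized per
miRNA family.
"""

from __future__ import annotations

import logging

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import TISSUES, DataIOError, TwoColorMirnaArray

logger = logging.getLogger(__name__)

# spots at (or below) zero after scaling cannot enter a log ratio; clamp to
# one intensity unit, far below any real signal
_INTENSITY_FLOOR = 1.0


def normalize_mean_scale(arrays: TwoColorMirnaArray) -> TwoColorMirnaArray:
    """Rescale foreground so every (hybridization, channel) mean is the grand mean.

    Each labeled RNA sample occupies one channel of one hybridization; its
    foreground intensities are multiplied by grand_mean / sample_mean.
    Background is left untouched.
    """
    df = arrays.records.copy()
    means = df.groupby(["sample_id", "channel"])["fg_intensity"].transform("mean")
    sample_means = df.groupby(["sample_id", "channel"])["fg_intensity"].mean()
    if (sample_means == 0).any():
        bad = sample_means[sample_means == 0].index.tolist()
        raise DataIOError(f"all-zero foreground in sample(s): {bad}")
    grand = sample_means.mean()
    df["fg_intensity"] = df["fg_intensity"] * (grand / means)
    return TwoColorMirnaArray(df)


def detection_call(
    arrays: TwoColorMirnaArray, k_sd: float = 2.0, min_samples: int = 2
) -> pd.DataFrame:
    """Per-probe, per-tissue detection calls.

    Background mean and SD are estimated per hybridization across probes.
    Technical replicates of a biological replicate are averaged first (both
    the spot intensity and the detection threshold); a probe is detected in a
    tissue if its averaged intensity clears bg_mean + k_sd * bg_sd in at
    least ``min_samples`` biological replicates of that tissue.
    """
    df = arrays.records
    n_reps = df["biological_replicate"].nunique()
    if n_reps < min_samples:
        raise DataIOError(
            f"detection requires >= {min_samples} biological replicates, have {n_reps}"
        )
    bg_stats = df.groupby("sample_id")["bg_intensity"].agg(["mean", "std"])
    thresholds = bg_stats["mean"] + k_sd * bg_stats["std"]
    work = df.assign(threshold=df["sample_id"].map(thresholds))
    per_rep = (
        work.groupby(["probe_id", "tissue", "biological_replicate"])[
            ["fg_intensity", "threshold"]
        ]
        .mean()
        .reset_index()
    )
    per_rep["pass"] = per_rep["fg_intensity"] >= per_rep["threshold"]
    counts = (
        per_rep.groupby(["probe_id", "tissue"])["pass"].sum().unstack("tissue")
    )
    detected = (counts >= min_samples).reindex(columns=list(TISSUES))
    detected.columns = [f"detected_in_{t}" for t in detected.columns]
    return detected


def average_dye_swaps(arrays: TwoColorMirnaArray) -> pd.DataFrame:
    """Per-probe, per-biological-replicate log2(A/B) ratios.

    Within each hybridization the ratio is oriented tissue A over tissue B
    regardless of which dye carries which tissue; the two technical log2
    ratios of a dye-swap pair are then averaged, which cancels any
    multiplicative dye bias exactly on the log scale.
    """
    df = arrays.records
    for pair_id, pair in df.groupby("dye_swap_pair_id"):
        orientations = pair.groupby("sample_id").apply(
            lambda h: frozenset(zip(h["tissue"], h["channel"])), include_groups=False
        )
        if len(orientations) != 2 or orientations.iloc[0] == orientations.iloc[1]:
            raise DataIOError(f"dye-swap pair {pair_id!r} is not a proper swap")
    fg = df.pivot_table(
        index=["probe_id", "biological_replicate", "sample_id"],
        columns="tissue",
        values="fg_intensity",
    )
    fg = fg.clip(lower=_INTENSITY_FLOOR)
    log_ratio = np.log2(fg["A"] / fg["B"])
    ratios = (
        log_ratio.groupby(level=["probe_id", "biological_replicate"])
        .mean()
        .unstack("biological_replicate")
    )
    return ratios


def one_sample_t(log_ratios: np.ndarray) -> tuple[float, float, bool]:
    """Classical one-sample t against mean zero; two-sided p.

    Returns (t, p, degenerate). Zero sample variance is degenerate: p = 0
    for a nonzero mean (infinitely strong evidence under the model), p = 1
    for an all-zero sample.
    """
    x = np.asarray(log_ratios, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise DataIOError("one-sample t-test needs at least 2 finite values")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, True
        return float(np.inf) * np.sign(mean), 0.0, True
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def probe_statistics(
    arrays: TwoColorMirnaArray, k_sd: float = 2.0, min_samples: int = 2
) -> pd.DataFrame:
    """Normalize, detect, average dye swaps and t-test every probe."""
    normalized = normalize_mean_scale(arrays)
    detected = detection_call(normalized, k_sd=k_sd, min_samples=min_samples)
    ratios = average_dye_swaps(normalized)
    rows = []
    for probe, values in ratios.iterrows():
        t, p, degenerate = one_sample_t(values.to_numpy())
        rows.append((probe, values.mean(), t, p, degenerate))
    out = pd.DataFrame(
        rows, columns=["probe_id", "mean_log2_ratio", "t", "p", "degenerate"]
    ).set_index("probe_id")
    return out.join(detected)


def call_de_mirnas(
    results: pd.DataFrame, fold_threshold: float = 1.25, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the fold / p-value / detection rule to probe statistics.

    A probe is differentially expressed if its linear fold 2**|mean log2
    ratio| is at least ``fold_threshold`` (boundary inclusive), p < alpha,
    and it is detected in at least one tissue. Direction follows the sign of
    the mean log2 ratio (positive = up in tissue A).
    """
    out = results.copy()
    fold = 2.0 ** out["mean_log2_ratio"].abs()
    # tolerate float round-trip at the inclusive boundary
    passes_fold = fold >= fold_threshold * (1.0 - 1e-12)
    detected_any = out["detected_in_A"] | out["detected_in_B"]
    de = passes_fold & (out["p"] < alpha) & detected_any
    out["de_call"] = np.where(
        de, np.where(out["mean_log2_ratio"] > 0, "up_in_A", "up_in_B"), "not_de"
    )
    return out


def mirna_de(
    arrays: TwoColorMirnaArray,
    fold_threshold: float = 1.25,
    alpha: float = 0.05,
    k_sd: float = 2.0,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Full probe-level differential-expression table from raw arrays."""
    return call_de_mirnas(
        probe_statistics(arrays, k_sd=k_sd, min_samples=min_samples),
        fold_threshold=fold_threshold,
        alpha=alpha,
    )


def map_to_families(
    results: pd.DataFrame,
    probe_to_family: Mapping[str, str] | pd.DataFrame,
    families: list[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Summarize probe-level DE results per miRNA family.

    The family log2 ratio is the mean over member probes; a family is flagged
    DE if any member probe is called DE (direction from the family mean).
    Returns the family summary and the number of families (from ``families``,
    e.g. all families with target predictions) that have no probe on the
    array and are therefore untestable.
    """
    if isinstance(probe_to_family, pd.DataFrame):
        pairs = probe_to_family[["probe_id", "family_id"]].drop_duplicates()
        dup = pairs["probe_id"].duplicated()
        if dup.any():
            bad = sorted(pairs.loc[dup, "probe_id"].unique())
            raise DataIOError(f"probe(s) mapped to multiple families: {bad}")
        mapping = dict(zip(pairs["probe_id"], pairs["family_id"]))
    else:
        mapping = dict(probe_to_family)
    work = results.copy()
    work["family_id"] = [mapping.get(p) for p in work.index]
    n_unmapped = int(work["family_id"].isna().sum())
    if n_unmapped:
        logger.info("%d probe(s) without family annotation excluded", n_unmapped)
    work = work.dropna(subset=["family_id"])
    summary = work.groupby("family_id").agg(
        mean_log2_ratio=("mean_log2_ratio", "mean"),
        n_probes=("mean_log2_ratio", "size"),
        any_de=("de_call", lambda c: bool((c != "not_de").any())),
        detected_in_A=("detected_in_A", "any"),
        detected_in_B=("detected_in_B", "any"),
    )
    summary["direction"] = np.where(
        ~summary["any_de"],
        "not_de",
        np.where(summary["mean_log2_ratio"] > 0, "up_in_A", "up_in_B"),
    )
    # a DE family whose mean ratio is exactly 0 has no usable direction
    summary.loc[
        summary["any_de"] & (summary["mean_log2_ratio"] == 0.0), "direction"
    ] = "not_de"
    n_without_probes = 0
    if families is not None:
        n_without_probes = len(set(families) - set(summary.index))
    return summary, n_without_probes
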