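"""iTRAQ reporter-ion quantification: peptides to per-protein tissue ratios.

Per MS/MS spectrum the share of tissue A's reporter in the summed 114 + 115
signal is r = I_A / (I_A + I_B); the equivalent odds t = r / (1 - r) is the
linear A/B fold for that peptide. Peptide odds are median-centered to 1
(removing global loading/labeling bias), aggregated per protein by the
median, and a protein is only considered valid with three or more peptides.
Differential abundance requires a linear fold of at least 1.3 in either
direction (boundary inclusive).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import DataIOError, PeptideQuantTable

logger = logging.getLogger(__name__)


def peptide_ratios(table: PeptideQuantTable, channel_of_a: int = 114) -> pd.DataFrame:
    """Per-peptide share r = I_A / (I_A + I_B) of the summed reporter signal.

    Rows with both channels zero are dropped (logged); rows where exactly one
    channel is zero yield r in {0, 1} and are flagged — they carry direction
    but no finite odds.
    """
    if channel_of_a not in (114, 115):
        raise DataIOError(f"channel_of_a must be 114 or 115, got {channel_of_a}")
    df = table.peptides.copy()
    total = df["intensity_114"] + df["intensity_115"]
    n_dropped = int((total == 0).sum())
    if n_dropped:
        logger.info("dropping %d peptide row(s) with zero total intensity", n_dropped)
    df = df.loc[total > 0].copy()
    i_a = df[f"intensity_{channel_of_a}"]
    df["r"] = i_a / (df["intensity_114"] + df["intensity_115"])
    df["flagged"] = (df["r"] == 0.0) | (df["r"] == 1.0)
    return df


def median_normalize(ratios: pd.DataFrame) -> pd.DataFrame:
    """Center peptide odds t = r/(1-r) so their median is exactly 1.

    Flagged rows (r in {0, 1}, infinite or zero odds) are excluded from both
    the median and the output; with no finite odds left the median is
    undefined and this is a hard error.
    """
    finite = ratios.loc[~ratios["flagged"]].copy()
    if finite.empty:
        raise DataIOError("no finite peptide odds to normalize")
    odds = finite["r"] / (1.0 - finite["r"])
    # median taken on the log scale: identical for odd counts, geometric
    # interpolation for even counts, which keeps channel swap an exact
    # inversion (log odds negate, so the centering negates with them)
    log_med = float(np.median(np.log(odds)))
    if not np.isfinite(log_med):
        raise DataIOError("undefined median of peptide odds")
    finite["odds"] = odds / np.exp(log_med)
    return finite


def aggregate_proteins(normalized: pd.DataFrame, min_peptides: int = 3) -> pd.DataFrame:
    """Protein ratio = median of its normalized peptide odds.

    Proteins with fewer than ``min_peptides`` retained peptides are kept in
    the table but marked invalid and excluded from differential calls.
    """
    grouped = normalized.groupby("protein_id")["odds"]
    out = pd.DataFrame(
        {
            "n_peptides": grouped.size(),
            # log-scale median, matching the normalization convention
            "ratio_a_over_b": np.exp(grouped.agg(lambda o: np.median(np.log(o)))),
        }
    )
    out["valid"] = out["n_peptides"] >= min_peptides
    out["abundance_call"] = "none"
    return out


def call_differential_proteins(proteins: pd.DataFrame, fold: float = 1.3) -> pd.DataFrame:
    """Fold-change calls on valid proteins; boundary inclusive both ways."""
    out = proteins.copy()
    tol = 1.0 - 1e-12
    up_a = out["valid"] & (out["ratio_a_over_b"] >= fold * tol)
    up_b = out["valid"] & (out["ratio_a_over_b"] <= (1.0 / fold) / tol)
    out["abundance_call"] = np.where(up_a, "up_in_A", np.where(up_b, "up_in_B", "none"))
    return out


def itraq_protein_table(
    table: PeptideQuantTable,
    channel_of_a: int = 114,
    min_peptides: int = 3,
    fold: float = 1.3,
) -> pd.DataFrame:
    """Full peptide-to-protein pipeline: ratios, normalization, calls."""
    ratios = peptide_ratios(table, channel_of_a=channel_of_a)
    normalized = median_normalize(ratios)
    proteins = aggregate_proteins(normalized, min_peptides=min_peptides)
    return call_differential_proteins(proteins, fold=fold)
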