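"""Steady-state translation metrics.

Percent of translating RNAs (smFISH-IF style, translation-site
intensity normalised by the median single mature-protein intensity),
fraction of time single RNAs spend translating in live traces, and the
two-sample equal-variance t-test on replicate means (the replicate, not
the cell, is the statistical unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .frameshift import call_bursts

__all__ = [
    "GroupComparison",
    "nascent_units",
    "percent_translating",
    "fraction_time_translating",
    "compare_groups",
]


@dataclass
class GroupComparison:
    means_a: np.ndarray
    means_b: np.ndarray
    t: float
    df: int
    p: float


def nascent_units(tls_intensity, median_single_protein: float, background: float = 0.0):
    """Translation-site intensity in mature-protein equivalents.

    Ratio of the background-subtracted integrated TLS intensity to the
    median single mature-protein intensity; negative values clip to 0.
    """
    if median_single_protein <= 0:
        raise ValueError("median_single_protein must be > 0")
    x = (np.asarray(tls_intensity, dtype=float) - background) / median_single_protein
    return np.maximum(x, 0.0)


def percent_translating(records: pd.DataFrame, min_units: float = 2.0):
    """Percent of actively translating RNAs per cell, replicate and group.

    ``records`` needs columns cell_id, nascent_units and optionally
    replicate (defaults to a single replicate).  An RNA is called
    translating when it carries at least ``min_units`` mature-protein
    equivalents of nascent signal.  The group summary is the mean +/- SD
    over replicate means.
    """
    df = records.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 0
    df["translating"] = df["nascent_units"] >= min_units

    per_cell = []
    for (rep, cell), g in df.groupby(["replicate", "cell_id"]):
        if len(g) == 0:
            warnings.warn(f"cell {cell} (replicate {rep}) has zero RNAs; skipped")
            continue
        per_cell.append((rep, cell, 100.0 * g["translating"].mean(), len(g)))
    per_cell = pd.DataFrame(per_cell, columns=["replicate", "cell_id", "percent", "n_rna"])
    per_rep = per_cell.groupby("replicate")["percent"].mean()
    summary = {
        "mean": float(per_rep.mean()),
        "sd": float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0,
        "min_units": min_units,
        "n_replicates": int(len(per_rep)),
    }
    return per_cell, per_rep, summary


def fraction_time_translating(
    signal: np.ndarray,
    on_threshold: float,
    min_on_frames: int = 3,
    min_off_frames: int = 2,
) -> float:
    """Fraction of a trace's frames in the called-ON translation state."""
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 6:
        raise ValueError("trace shorter than 6 frames excluded (track-length rule)")
    bursts = call_bursts(signal, on_threshold, min_on_frames, min_off_frames)
    return bursts.total_on_frames / len(signal)


def compare_groups(replicate_means_a, replicate_means_b) -> GroupComparison:
    """Two-tailed pooled-variance (equal variance) two-sample t-test."""
    a = np.asarray(replicate_means_a, dtype=float)
    b = np.asarray(replicate_means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        warnings.warn("zero pooled variance with equal means; p = 1 by convention")
        return GroupComparison(a, b, 0.0, df, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(a, b, float(t), df, float(p))
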