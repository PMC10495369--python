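"""Two-color frameshift classification.

A linked two-color trace carries the upstream-frame signal (channel 1,
e.g. HA) and the downstream-frame signal (channel 2, e.g. SunTag) of the
same mRNA.  Bursts are called per channel by hysteresis thresholding;
an mRNA showing bursts in both frames within the observation window
underwent a frameshift, channel-2-only signal indicates cap-independent
(RAN-style) initiation, channel-1-only is normal translation, and
neither is silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BurstSet", "FrameshiftSummary", "call_bursts", "classify_trace", "summarize_population"]

CLASSES = ("normal", "frameshift", "ran_only", "silent")


@dataclass
class BurstSet:
    """Disjoint, ordered ON intervals (start_frame, end_frame), inclusive."""

    intervals: list[tuple[int, int]] = field(default_factory=list)
    n_frames: int = 0

    def __len__(self) -> int:
        return len(self.intervals)

    def on_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_frames, dtype=bool)
        for a, b in self.intervals:
            mask[a : b + 1] = True
        return mask

    @property
    def total_on_frames(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)


@dataclass
class FrameshiftSummary:
    counts: dict
    percentages: dict
    time_fractions: dict
    n_cells: int
    n_traces: int
    denominator: str
    undefined: bool = False


def call_bursts(
    signal: np.ndarray,
    on_threshold: float,
    min_on_frames: int = 3,
    min_off_frames: int = 2,
) -> BurstSet:
    """Hysteresis burst calling.

    A burst starts once ``min_on_frames`` consecutive frames exceed the
    threshold and ends once ``min_off_frames`` consecutive frames fall
    below it; brief sub-threshold dips shorter than ``min_off_frames``
    do not terminate a burst.
    """
    if on_threshold <= 0:
        raise ValueError("on_threshold must be > 0")
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    above = signal > on_threshold
    intervals: list[tuple[int, int]] = []
    state_on = False
    run_above = 0
    run_below = 0
    start = 0
    last_above = -1
    for i in range(n):
        if above[i]:
            run_above += 1
            run_below = 0
            last_above = i
            if not state_on and run_above >= min_on_frames:
                state_on = True
                start = i - min_on_frames + 1
        else:
            run_below += 1
            run_above = 0
            if state_on and run_below >= min_off_frames:
                intervals.append((start, last_above))
                state_on = False
    if state_on:
        intervals.append((start, last_above))
    return BurstSet(intervals=intervals, n_frames=n)


def classify_trace(bursts_ch1: BurstSet, bursts_ch2: BurstSet) -> str:
    """normal / frameshift / ran_only / silent from per-channel bursts.

    Temporal overlap between the two channels is not required -- a
    downstream-frame burst after the upstream signal has decayed still
    marks a frameshifted ribosome from the same observation window.
    """
    has1, has2 = len(bursts_ch1) > 0, len(bursts_ch2) > 0
    if has1 and has2:
        return "frameshift"
    if has1:
        return "normal"
    if has2:
        return "ran_only"
    return "silent"


def summarize_population(
    results,
    denominator: str = "translating",
    n_cells: int | None = None,
) -> FrameshiftSummary:
    """Population class percentages and time-in-state fractions.

    ``results`` is an iterable of (class, bursts_ch1, bursts_ch2)
    triples (or a DataFrame with those columns).  Time-in-state
    fractions are computed over all frames in which at least one channel
    is ON, split into ch1-only / both / ch2-only.
    """
    if isinstance(results, pd.DataFrame):
        rows = list(results.itertuples(index=False))
        triples = [(r[0], r[1], r[2]) for r in rows]
    else:
        triples = list(results)
    if not triples:
        raise ValueError("need >= 1 trace")

    counts = {c: 0 for c in CLASSES}
    frames = {"ch1_only": 0, "both": 0, "ch2_only": 0}
    for cls, b1, b2 in triples:
        counts[cls] += 1
        m1, m2 = b1.on_mask(), b2.on_mask()
        n = max(len(m1), len(m2))
        m1 = np.pad(m1, (0, n - len(m1)))
        m2 = np.pad(m2, (0, n - len(m2)))
        frames["ch1_only"] += int(np.sum(m1 & ~m2))
        frames["both"] += int(np.sum(m1 & m2))
        frames["ch2_only"] += int(np.sum(~m1 & m2))

    n_traces = len(triples)
    if denominator == "translating":
        denom = n_traces - counts["silent"]
        classes = ("normal", "frameshift", "ran_only")
    elif denominator == "all":
        denom = n_traces
        classes = CLASSES
    else:
        raise ValueError("denominator must be 'translating' or 'all'")

    undefined = denom == 0
    percentages = {
        c: (np.nan if undefined else 100.0 * counts[c] / denom) for c in classes
    }
    total_on = sum(frames.values())
    time_fractions = {
        k: (np.nan if total_on == 0 else v / total_on) for k, v in frames.items()
    }
    return FrameshiftSummary(
        counts=counts,
        percentages=percentages,
        time_fractions=time_fractions,
        n_cells=0 if n_cells is None else n_cells,
        n_traces=n_traces,
        denominator=denominator,
        undefined=undefined,
    )
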