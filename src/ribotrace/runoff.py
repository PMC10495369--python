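"""Ribosome-runoff survival analysis and elongation-speed inversion.

After harringtonine blocks initiation, already-loaded ribosomes run off
the message; the translation-site signal decays and the time from drug
addition until it falls persistently below 10% of the trace maximum is
the runoff time t.  Runoff times over a cohort form a survival curve
(pooled Kaplan--Meier with plain Greenwood 95% bounds, or per-cell
averaged), and the median runoff time inverts to elongation speeds:

    t = t_I + t_0 = L_I / v_I + L_0 / v_0

so the speed fold of the insert relative to ordinary sequence is

    v_0 / v_I = (t - L_0/v_0) / (L_I/v_0)

which also equals the per-amino-acid residence-time fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracesim import IntensityTrace

__all__ = [
    "RunoffRecord",
    "SurvivalCurve",
    "ElongationEstimate",
    "extract_runoff_time",
    "km_survival",
    "per_cell_survival",
    "logrank_test",
    "estimate_v0",
    "elongation_fold",
    "fold_runoff_time",
    "frap_recovery",
]

EXCLUSIONS = ("none", "low_initial", "co_disappear", "short_track", "merge_split", "not_translating")


@dataclass
class RunoffRecord:
    cell_id: int
    rna_id: int
    runoff_time: float | None = None
    censor_time: float | None = None
    censored: bool = False
    exclusion: str = "none"

    def __post_init__(self):
        if self.exclusion not in EXCLUSIONS:
            raise ValueError(f"unknown exclusion code {self.exclusion!r}")
        if self.exclusion == "none":
            has_event = self.runoff_time is not None and not self.censored
            has_cens = self.censored and self.censor_time is not None
            if has_event == has_cens:
                raise ValueError("exactly one of runoff_time / censoring must be set")
            t = self.runoff_time if has_event else self.censor_time
            if t < 0:
                raise ValueError("times must be >= 0")

    @property
    def duration(self) -> float:
        return self.runoff_time if not self.censored else self.censor_time


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    mode: str = "pooled_km"
    median: float | None = None

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])


@dataclass
class ElongationEstimate:
    v0: float
    t_control: float
    t_target: float
    L_I: float
    L_0: float
    t_0: float
    t_I: float
    speed_fold: float
    per_aa_time_fold: float


def extract_runoff_time(
    trace: IntensityTrace,
    t_drug: float,
    threshold_frac: float = 0.10,
    init_frames: int = 4,
    persistence: int = 3,
    min_len: int = 6,
) -> RunoffRecord:
    """Apply the 10%-of-maximum runoff rule with the published exclusions.

    The trace maximum is taken over the raw, unsmoothed protein signal.
    Traces whose first ``init_frames`` frames average below the
    threshold were not visibly translating at drug addition and are
    discarded; traces whose RNA track vanishes within +/-2 frames of the
    protein signal's final fall are discarded as lost mRNAs.  A signal
    still above threshold at the end of the movie is right-censored.
    """
    signal = np.asarray(trace.ch1, dtype=float)
    time = np.asarray(trace.time, dtype=float)
    n = len(signal)
    if n == 0 or t_drug > time[-1]:
        raise ValueError("trace must cover t_drug onward")
    if n < min_len:
        return RunoffRecord(trace.cell_id, trace.rna_id, exclusion="short_track")
    if trace.merged or trace.split:
        return RunoffRecord(trace.cell_id, trace.rna_id, exclusion="merge_split")

    m = float(np.max(signal))
    if m <= 0:
        return RunoffRecord(trace.cell_id, trace.rna_id, exclusion="not_translating")
    thr = threshold_frac * m
    if float(np.mean(signal[:init_frames])) < thr:
        return RunoffRecord(trace.cell_id, trace.rna_id, exclusion="low_initial")

    below = signal < thr
    start = int(np.searchsorted(time, t_drug, side="left"))

    # final fall: last crossing from >=thr to <thr (for the co-disappearance check)
    fall_frame = None
    for i in range(n - 1, -1, -1):
        if below[i] and (i == 0 or not below[i - 1]):
            fall_frame = i
            break
    rna_finite = np.isfinite(np.asarray(trace.rna, dtype=float))
    rna_end = int(np.max(np.nonzero(rna_finite)[0])) if rna_finite.any() else -1
    if (
        fall_frame is not None
        and rna_end < n - 1  # RNA track actually terminates before the movie ends
        and abs(rna_end - fall_frame) <= 2
    ):
        return RunoffRecord(trace.cell_id, trace.rna_id, exclusion="co_disappear")

    # first frame at/after t_drug below threshold for >= persistence frames
    run = 0
    for i in range(start, n):
        run = run + 1 if below[i] else 0
        if run >= persistence:
            first = i - persistence + 1
            return RunoffRecord(
                trace.cell_id, trace.rna_id, runoff_time=float(time[first] - t_drug)
            )
    return RunoffRecord(
        trace.cell_id, trace.rna_id, censored=True, censor_time=float(time[-1] - t_drug)
    )


def _km_table(durations: np.ndarray, events: np.ndarray):
    order = np.argsort(durations, kind="stable")
    durations, events = durations[order], events[order]
    uniq = np.unique(durations[events])
    n_total = len(durations)
    rows = []
    for t in uniq:
        n_i = int(np.sum(durations >= t))
        d_i = int(np.sum((durations == t) & events))
        rows.append((float(t), n_i, d_i))
    return rows, n_total


def km_survival(records, alpha: float = 0.05) -> SurvivalCurve:
    """Pooled product-limit survival estimate with plain Greenwood bounds.

    Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i)); the CI is
    S +/- z * SE clipped to [0, 1].
    """
    recs = [r for r in records if r.exclusion == "none"]
    if not recs:
        raise ValueError("no eligible (non-excluded) records")
    durations = np.array([r.duration for r in recs], dtype=float)
    events = np.array([not r.censored for r in recs], dtype=bool)
    rows, n_total = _km_table(durations, events)

    z = stats.norm.ppf(1 - alpha / 2)
    times = [0.0]
    surv = [1.0]
    lo = [1.0]
    hi = [1.0]
    at_risk = [n_total]
    s = 1.0
    gw = 0.0
    for t, n_i, d_i in rows:
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            gw += d_i / (n_i * (n_i - d_i))
            se = s * math.sqrt(gw)
        else:
            se = 0.0  # S = 0; Greenwood term degenerate
        times.append(t)
        surv.append(s)
        lo.append(max(0.0, s - z * se))
        hi.append(min(1.0, s + z * se))
        at_risk.append(n_i)

    surv_a = np.asarray(surv)
    median = None
    reach = np.nonzero(surv_a <= 0.5)[0]
    if len(reach):
        median = float(times[reach[0]])
    return SurvivalCurve(
        times=np.asarray(times),
        survival=surv_a,
        ci_low=np.asarray(lo),
        ci_high=np.asarray(hi),
        n_at_risk=np.asarray(at_risk),
        mode="pooled_km",
        median=median,
    )


def per_cell_survival(records, alpha: float = 0.05, grid: np.ndarray | None = None) -> SurvivalCurve:
    """Mean-of-cells survival: per cell the fraction of its translating
    RNAs still above threshold at each time, averaged unweighted across
    cells (censored molecules count as surviving)."""
    by_cell: dict[int, list[RunoffRecord]] = {}
    for r in records:
        if r.exclusion == "none":
            by_cell.setdefault(r.cell_id, []).append(r)
    by_cell = {c: rs for c, rs in by_cell.items() if rs}
    if not by_cell:
        raise ValueError("no cell with eligible records")

    if grid is None:
        all_t = sorted(
            {0.0}
            | {r.runoff_time for rs in by_cell.values() for r in rs if not r.censored}
        )
        grid = np.asarray(all_t, dtype=float)
    curves = []
    for rs in by_cell.values():
        ev = np.array([r.runoff_time if not r.censored else np.inf for r in rs])
        curves.append((ev[None, :] > grid[:, None]).mean(axis=1))
    curves = np.vstack(curves)
    mean = curves.mean(axis=0)
    if len(curves) > 1:
        se = curves.std(axis=0, ddof=1) / math.sqrt(len(curves))
    else:
        se = np.zeros_like(mean)
    z = stats.norm.ppf(1 - alpha / 2)
    median = None
    reach = np.nonzero(mean <= 0.5)[0]
    if len(reach):
        median = float(grid[reach[0]])
    return SurvivalCurve(
        times=grid,
        survival=mean,
        ci_low=np.clip(mean - z * se, 0, 1),
        ci_high=np.clip(mean + z * se, 0, 1),
        n_at_risk=np.full(len(grid), len(curves)),
        mode="per_cell_mean",
        median=median,
    )


def logrank_test(records_a, records_b) -> tuple[float, float]:
    """Two-group log-rank (Mantel--Cox) test; returns (chi_square, p)."""
    from lifelines.statistics import logrank_test as _lr

    def arrays(recs):
        recs = [r for r in recs if r.exclusion == "none"]
        if not recs:
            raise ValueError("empty group")
        d = np.array([r.duration for r in recs], dtype=float)
        e = np.array([not r.censored for r in recs], dtype=bool)
        return d, e

    da, ea = arrays(records_a)
    db, eb = arrays(records_b)
    if not ea.any() or not eb.any():
        raise ValueError("log-rank statistic undefined: a group has zero events")
    res = _lr(da, db, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def estimate_v0(t_control_median: float, L_total_control: float) -> float:
    """Uniform-speed estimate v0 = L / t from the control median runoff time."""
    if t_control_median <= 0 or L_total_control <= 0:
        raise ValueError("inputs must be > 0")
    return L_total_control / t_control_median


def elongation_fold(
    t_target_median: float,
    v0: float,
    L_I: float,
    L_0: float,
    t_control_median: float | None = None,
) -> ElongationEstimate:
    """Invert the runoff-time decomposition to the insert speed fold.

    t_0 = L_0/v0 is the time through ordinary sequence, t_I the
    remainder; v0/vI = t_I / (L_I/v0) is both the speed fold and the
    per-amino-acid residence-time fold of the insert.
    """
    if L_I <= 0 or L_0 <= 0 or v0 <= 0:
        raise ValueError("lengths and v0 must be > 0")
    t_0 = L_0 / v0
    t_i = t_target_median - t_0
    if t_i <= 0:
        raise ValueError(
            f"degenerate inversion: t_target={t_target_median:.1f}s <= L_0/v0={t_0:.1f}s "
            "(negative insert time)"
        )
    fold = t_i / (L_I / v0)
    return ElongationEstimate(
        v0=v0,
        t_control=float("nan") if t_control_median is None else t_control_median,
        t_target=t_target_median,
        L_I=L_I,
        L_0=L_0,
        t_0=t_0,
        t_I=t_i,
        speed_fold=fold,
        per_aa_time_fold=fold,
    )


def fold_runoff_time(t_target_median: float, t_control_median: float) -> float:
    """Plain ratio of median runoff times, reported to one decimal."""
    if t_control_median <= 0:
        raise ValueError("control median must be > 0")
    return round(t_target_median / t_control_median, 1)


def frap_recovery(trace: IntensityTrace, t_bleach: float, plateau_frac: float = 0.10):
    """Normalised post-bleach recovery, its half-time and plateau.

    The signal is normalised to the mean pre-bleach intensity; the
    plateau is the mean of the final ``plateau_frac`` of frames and the
    half-time is the first post-bleach time at which the normalised
    signal reaches half the plateau.
    """
    time = np.asarray(trace.time, dtype=float)
    signal = np.asarray(trace.ch1, dtype=float)
    pre = signal[time < t_bleach]
    if len(pre) < 3:
        raise ValueError("need >= 3 pre-bleach frames")
    base = float(np.mean(pre))
    if base <= 0:
        raise ValueError("non-positive pre-bleach signal")
    post_mask = time >= t_bleach
    t_post = time[post_mask] - t_bleach
    norm = signal[post_mask] / base
    k = max(1, int(math.ceil(plateau_frac * len(norm))))
    plateau = float(np.mean(norm[-k:]))
    half_time = None
    half = plateau / 2.0
    hit = np.nonzero(norm >= half)[0]
    if len(hit):
        half_time = float(t_post[hit[0]])
    curve = pd.DataFrame({"time_s": t_post, "recovery": norm})
    return curve, half_time, plateau
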