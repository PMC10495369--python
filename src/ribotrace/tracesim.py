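"""Synthetic single-mRNA translation-site traces with ground truth.

The simulator emulates membrane-tethered reporter mRNAs imaged by TIRF:
bursty (telegraph-gated) initiation, codon-by-codon stochastic
elongation with region-specific speeds and steric exclusion, optional
frameshifting into a downstream reading frame, harringtonine shut-off of
initiation, photobleaching, and additive Gaussian measurement noise on
the integrated spot intensity.  The fluorescence of a translation site
is the number of completed, still-attached epitopes times
``unit_intensity`` -- nascent chains leave the site on termination.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import (
    poisson_times,
    simulate_rna_excluded,
    simulate_rna_free,
    telegraph_intervals,
)
from .kinetics import KineticParams, ParameterError
from .reporters import ReporterDesign, build_reporter

__all__ = [
    "TraceSet",
    "GroundTruth",
    "IntensityTrace",
    "simulate_traces",
    "sample_mature_proteins",
    "simulate_smfish_snapshot",
]

TRACE_COLUMNS = ["cell_id", "rna_id", "frame", "time_s", "rna_signal", "ch1_signal"]


@dataclass
class IntensityTrace:
    """One linked RNA/translation-site time series."""

    cell_id: int
    rna_id: int
    time: np.ndarray
    rna: np.ndarray
    ch1: np.ndarray
    ch2: np.ndarray | None = None
    dt: float = 10.0
    merged: bool = False
    split: bool = False

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TraceSet:
    traces: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def two_color(self) -> bool:
        return "ch2_signal" in self.traces.columns

    @property
    def dt(self) -> float:
        return float(self.metadata.get("dt", np.median(np.diff(np.unique(self.traces["time_s"])))))

    def iter_traces(self):
        has2 = self.two_color
        hasxy = "x_px" in self.traces.columns
        for (cid, rid), g in self.traces.groupby(["cell_id", "rna_id"], sort=True):
            g = g.sort_values("frame")
            yield IntensityTrace(
                cell_id=int(cid),
                rna_id=int(rid),
                time=g["time_s"].to_numpy(float),
                rna=g["rna_signal"].to_numpy(float),
                ch1=g["ch1_signal"].to_numpy(float),
                ch2=g["ch2_signal"].to_numpy(float) if has2 else None,
                dt=self.dt,
            )

    def n_traces(self) -> int:
        return self.traces.groupby(["cell_id", "rna_id"]).ngroups


@dataclass
class GroundTruth:
    ribosomes: pd.DataFrame   # cell_id, rna_id, init_time_s, is_ran, fs_flag, fs_codon, end_time_s
    rna_states: pd.DataFrame  # cell_id, rna_id, class, clearance_time_s
    on_intervals: pd.DataFrame  # cell_id, rna_id, start_s, end_s


def _rna_rng(seed: int, cell_id: int, rna_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(cell_id), int(rna_id)))
    )


def _signal_counts(records, frame_times: np.ndarray, chan: int, t_bleach: float | None) -> np.ndarray:
    """Number of visible completed epitopes per frame for one channel (5=ch1, 6=ch2... index)."""
    idx = 4 + chan  # record = (init, is_ran, fs_codon, end, ch1_times, ch2_times)
    ev_t, ev_v = [], []
    for rec in records:
        eps = rec[idx]
        if len(eps) == 0:
            continue
        end = rec[3]
        ev_t.append(eps)
        ev_v.append(np.ones(len(eps)))
        ev_t.append([end])
        ev_v.append([-float(len(eps))])
    if not ev_t:
        return np.zeros(len(frame_times))
    t = np.concatenate([np.asarray(a, dtype=float) for a in ev_t])
    v = np.concatenate([np.asarray(a, dtype=float) for a in ev_v])
    order = np.argsort(t, kind="stable")
    t, v = t[order], np.cumsum(v[order])
    pos = np.searchsorted(t, frame_times, side="right")
    counts = np.where(pos > 0, v[np.maximum(pos - 1, 0)], 0.0)
    if t_bleach is None:
        return counts
    # after the bleach only epitopes completed *after* t_bleach are visible
    ev_t, ev_v = [], []
    for rec in records:
        end = rec[3]
        if end <= t_bleach:
            continue
        eps = np.asarray(rec[idx], dtype=float)
        eps = eps[eps > t_bleach]
        if len(eps) == 0:
            continue
        ev_t.append(eps)
        ev_v.append(np.ones(len(eps)))
        ev_t.append([end])
        ev_v.append([-float(len(eps))])
    post = np.zeros(len(frame_times))
    if ev_t:
        t2 = np.concatenate([np.asarray(a, dtype=float) for a in ev_t])
        v2 = np.concatenate([np.asarray(a, dtype=float) for a in ev_v])
        order = np.argsort(t2, kind="stable")
        t2, v2 = t2[order], np.cumsum(v2[order])
        pos = np.searchsorted(t2, frame_times, side="right")
        post = np.where(pos > 0, v2[np.maximum(pos - 1, 0)], 0.0)
    return np.where(frame_times < t_bleach, counts, post)


def simulate_traces(
    design: ReporterDesign | str,
    params: KineticParams,
    n_rna: int,
    seed: int,
    n_cells: int = 1,
    positions: bool = False,
    fov: tuple[int, int] = (128, 128),
    diffusion_sd: float = 0.05,
    min_separation: float = 0.0,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate ``n_rna`` single-mRNA traces split evenly across ``n_cells``.

    Every source of randomness derives deterministically from ``seed``
    and the (cell, RNA) identifiers, so identical inputs give
    byte-identical outputs.
    """
    if seed is None:
        raise ParameterError("a seed is required (reproducibility contract)")
    if n_rna < 1:
        raise ParameterError("n_rna must be >= 1")
    design = build_reporter(design)
    if not isinstance(params, KineticParams):
        raise ParameterError("params must be a KineticParams")

    speeds = design.region_speed_map(params.v_flank, params.v_insert)
    ins = design.insert_region
    ins_start, ins_end = (ins.start, ins.end) if ins is not None else (0, -1)
    hazard = params.fs_codon_hazard(design.insert_length)
    ran_start = ins_start if ins is not None else 1
    deterministic = params.stepping == "deterministic"
    n_frames = params.n_frames
    burn = params.burn_in
    total = burn + params.duration
    frame_times = np.arange(n_frames) * params.dt          # recorded clock
    frame_times_abs = burn + frame_times                    # simulation clock
    t_init_max = burn + params.t_drug if params.t_drug is not None else total
    t_bleach_abs = None if params.t_bleach is None else burn + params.t_bleach

    trace_frames = []
    rib_rows, state_rows, on_rows = [], [], []
    margin = 8.0
    placed: list[tuple[float, float]] = []  # anchors, for min_separation

    for j in range(n_rna):
        cell_id = j % max(1, n_cells)
        rna_id = j
        rng = _rna_rng(seed, cell_id, rna_id)

        ons = telegraph_intervals(params.k_on, params.k_off, total, rng)
        on_windows = [(a, b) for a, b, s in ons if s]
        init_times = poisson_times(params.k_init, on_windows, rng, t_max=t_init_max)
        ran_times = (
            poisson_times(params.p_ran, [(0.0, t_init_max)], rng)
            if (params.p_ran > 0 and design.two_color)
            else np.empty(0)
        )

        args = (
            speeds,
            np.asarray(design.epitope_positions_ch1),
            np.asarray(design.epitope_positions_ch2),
            design.ch1_stop,
            design.total_length,
            ins_start,
            ins_end,
            hazard,
        )
        if params.exclusion:
            records = simulate_rna_excluded(
                *args, params.footprint, init_times, ran_times, ran_start, rng, deterministic
            )
        else:
            records = simulate_rna_free(
                *args, init_times, ran_times, ran_start, rng, deterministic
            )

        ch1 = _signal_counts(records, frame_times_abs, 0, t_bleach_abs) * params.unit_intensity
        ch1 = ch1 + params.background + params.noise_sd * rng.standard_normal(n_frames)
        rna = params.rna_intensity + params.noise_sd * rng.standard_normal(n_frames)
        cols = {
            "cell_id": cell_id,
            "rna_id": rna_id,
            "frame": np.arange(n_frames),
            "time_s": frame_times,
            "rna_signal": rna,
            "ch1_signal": ch1,
        }
        if design.two_color:
            ch2 = _signal_counts(records, frame_times_abs, 1, t_bleach_abs) * params.unit_intensity
            cols["ch2_signal"] = ch2 + params.background + params.noise_sd * rng.standard_normal(n_frames)
        if positions:
            for _ in range(1000):
                x0 = margin + rng.random() * (fov[1] - 2 * margin)
                y0 = margin + rng.random() * (fov[0] - 2 * margin)
                if min_separation <= 0 or all(
                    (x0 - px) ** 2 + (y0 - py) ** 2 >= min_separation**2
                    for px, py in placed
                ):
                    break
            placed.append((x0, y0))
            steps = diffusion_sd * rng.standard_normal((n_frames, 2))
            xy = np.cumsum(steps, axis=0) + [x0, y0]
            cols["x_px"], cols["y_px"] = xy[:, 0], xy[:, 1]
        trace_frames.append(pd.DataFrame(cols))

        for init_t, is_ran, fs_codon, end_t, _, e2 in records:
            rib_rows.append(
                (cell_id, rna_id, init_t - burn, bool(is_ran), fs_codon is not None,
                 np.nan if fs_codon is None else int(fs_codon), end_t - burn,
                 np.nan if len(e2) == 0 else float(np.min(e2)) - burn)
            )

        def _ch2_observable(rec):
            # downstream-frame epitopes visible at some recorded frame
            return (
                len(rec[5]) > 0
                and float(np.min(rec[5])) - burn <= params.duration
                and rec[3] - burn > 0
            )

        has_fs = any(r[2] is not None and _ch2_observable(r) for r in records)
        has_cap = any(not r[1] for r in records)
        has_ran = any(r[1] and _ch2_observable(r) for r in records)
        if has_fs:
            cls = "frameshift"
        elif has_ran and not has_cap:
            cls = "ran_only"
        elif has_cap:
            cls = "normal"
        else:
            cls = "silent"
        clearance = np.nan
        if params.t_drug is not None and records:
            clearance = max(r[3] for r in records) - burn - params.t_drug
        state_rows.append((cell_id, rna_id, cls, clearance))
        for a, b, s in ons:
            if s and b > burn:  # report ON windows on the recorded clock
                on_rows.append((cell_id, rna_id, max(a - burn, 0.0), b - burn))

    traces = pd.concat(trace_frames, ignore_index=True)
    meta = {
        "design": design.name,
        "dt": params.dt,
        "duration": params.duration,
        "seed": int(seed),
        "params_digest": params.digest(),
    }
    truth = GroundTruth(
        ribosomes=pd.DataFrame(
            rib_rows,
            columns=["cell_id", "rna_id", "init_time_s", "is_ran", "fs_flag",
                     "fs_codon", "end_time_s", "first_ch2_s"],
        ),
        rna_states=pd.DataFrame(
            state_rows, columns=["cell_id", "rna_id", "class", "clearance_time_s"]
        ),
        on_intervals=pd.DataFrame(on_rows, columns=["cell_id", "rna_id", "start_s", "end_s"]),
    )
    return TraceSet(traces=traces, metadata=meta), truth


def sample_mature_proteins(params: KineticParams, n: int, seed: int) -> np.ndarray:
    """Mature single-protein spot intensities (gamma, right-skewed).

    The distribution is parameterised by its median (``mature_median``,
    a noiseless mature protein carries all 24 epitopes) and coefficient
    of variation; ``mature_cv == 0`` collapses to the exact median.
    """
    if seed is None:
        raise ParameterError("a seed is required (reproducibility contract)")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if params.mature_cv < 0:
        raise ParameterError("mature_cv must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(997,)))
    if params.mature_cv == 0:
        return np.full(n, float(params.mature_median))
    shape = 1.0 / params.mature_cv**2
    from scipy.stats import gamma as _gamma

    median_unit = _gamma.ppf(0.5, shape)  # median of gamma(shape, scale=1)
    scale = params.mature_median / median_unit
    return rng.gamma(shape, scale, size=n)


def simulate_smfish_snapshot(
    design: ReporterDesign | str,
    params: KineticParams,
    n_cells: int,
    rnas_per_cell: int,
    seed: int,
    warmup: float | None = None,
):
    """Single-time-point (fixed-cell) translation-site intensities.

    Each RNA's instantaneous ribosome load is the end state of a
    steady-state trace simulation; the returned table holds one row per
    RNA with integrated TLS intensity, and the ground-truth flag says
    whether nascent epitope signal was truly present at the snapshot.
    """
    if n_cells < 1 or rnas_per_cell < 1:
        raise ParameterError("counts must be >= 1")
    design = build_reporter(design)
    if warmup is None:
        warmup = 2.0 * design.total_length / min(params.v_flank, max(params.v_insert, 1e-9))
        warmup = max(warmup, 3.0 / max(params.k_on + params.k_off, 1e-9))
    p = params.replace(duration=float(warmup), t_drug=None, t_bleach=None)
    ts, truth = simulate_traces(
        design, p, n_rna=n_cells * rnas_per_cell, seed=seed, n_cells=n_cells
    )
    # noiseless twin with identical dynamics (same per-RNA substreams; the
    # dynamics draws precede the noise draws, so trajectories are identical)
    ts0, _ = simulate_traces(
        design, p.replace(noise_sd=0.0, background=0.0),
        n_rna=n_cells * rnas_per_cell, seed=seed, n_cells=n_cells,
    )
    last = ts.traces.sort_values("frame").groupby(["cell_id", "rna_id"], sort=True).tail(1)
    last0 = ts0.traces.sort_values("frame").groupby(["cell_id", "rna_id"], sort=True).tail(1)
    t_snap = float(last["time_s"].max())

    rib = truth.ribosomes
    flags = {}
    for (cid, rid), g in rib.groupby(["cell_id", "rna_id"]):
        attached = g[(g["init_time_s"] <= t_snap) & (g["end_time_s"] > t_snap)]
        flags[(cid, rid)] = len(attached) > 0
    out = last[["cell_id", "rna_id"]].copy()
    out["rna_intensity"] = last["rna_signal"].to_numpy()
    out["tls_intensity"] = last["ch1_signal"].to_numpy()
    out["true_nascent_epitopes"] = last0["ch1_signal"].to_numpy() / max(p.unit_intensity, 1e-12)
    out["true_translating"] = [
        flags.get((c, r), False) for c, r in zip(out["cell_id"], out["rna_id"])
    ]
    return out.reset_index(drop=True), truth
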