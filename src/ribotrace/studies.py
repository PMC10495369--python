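"""Canonical simulation studies.

Each function simulates a complete in-silico experiment under the
package's reference conditions and runs the corresponding analysis
end-to-end, returning both the recovered quantities and the ground
truth.  These are the experiments behind the validation suite and the
reproduction script; they are ordinary library code and can be re-run
at any seed.

Reference conditions (see docs/methods.md for rationale):

* runoff cohorts -- constitutive AUG-driven initiation (one event per
  ~17 s), recording every 10 s for 30 min after harringtonine, 100
  mRNAs in 10 cells per cohort, 5-min steady-state burn-in.  Steric
  exclusion is off in these cohorts because the runoff inversion
  assumes the last ribosome's transit is unobstructed; with crowding
  enabled the assay measures queueing delay on top of elongation
  (demonstrated separately in the tests).
* the speed-fold estimator averages per-cell Kaplan--Meier medians
  (the per-cell mode of the survival analysis) and folds are averaged
  over independent replicate experiments, which also averages away the
  10-s frame quantisation of single-cohort medians.
"""

from __future__ import annotations

import numpy as np

from .frameshift import call_bursts, classify_trace
from .kinetics import KineticParams
from .quantify import fraction_time_translating
from .runoff import elongation_fold, estimate_v0, extract_runoff_time, km_survival
from .tracesim import simulate_traces

__all__ = [
    "RUNOFF_PARAMS",
    "runoff_cohort_median",
    "runoff_fold_recovery",
    "frameshift_recovery",
    "duty_cycle_recovery",
    "localization_benchmark",
    "pair_recovery_benchmark",
]

#: reference conditions of the simulated harringtonine runoff assay
RUNOFF_PARAMS = KineticParams(
    k_on=0.0,
    k_off=0.0,
    k_init=0.06,
    v_flank=3.5,
    v_insert=3.5,
    exclusion=False,
    burn_in=300.0,
    t_drug=0.0,
    dt=10.0,
    duration=1800.0,
)

CONTROL_DESIGN = "elongation_NLuc"
TARGET_DESIGN = "elongation_GGGGCC70"
L_CONTROL = 1034  # codons, control construct total
L_INSERT = 140    # codons, repeat insert
L_FLANK = 863     # codons, shared cassette + degron flank


def runoff_cohort_median(traceset, t_drug: float = 0.0) -> float:
    """Mean of per-cell Kaplan--Meier median runoff times (s)."""
    by_cell: dict[int, list] = {}
    for tr in traceset.iter_traces():
        rec = extract_runoff_time(tr, t_drug)
        if rec.exclusion == "none":
            by_cell.setdefault(rec.cell_id, []).append(rec)
    medians = []
    for recs in by_cell.values():
        m = km_survival(recs).median
        if m is not None:
            medians.append(m)
    if not medians:
        raise ValueError("no cell reached median runoff")
    return float(np.mean(medians))


def runoff_fold_recovery(
    factors=(1, 5, 10, 15),
    seed: int = 0,
    n_replicates: int = 3,
    n_rna: int = 100,
    n_cells: int = 10,
):
    """Simulated runoff assay at known insert slow-down factors.

    For each replicate experiment a control cohort fixes v0 and each
    target cohort's mean per-cell median inverts to a speed fold; folds
    are averaged over replicates.  Returns ``{factor: mean_fold}`` plus
    the per-replicate detail.
    """
    detail = {f: [] for f in factors}
    v0s = []
    for rep in range(n_replicates):
        s = int(seed) + 101 * rep
        ctrl, _ = simulate_traces(CONTROL_DESIGN, RUNOFF_PARAMS, n_rna=n_rna,
                                  seed=s, n_cells=n_cells)
        v0 = estimate_v0(runoff_cohort_median(ctrl), L_CONTROL)
        v0s.append(v0)
        for f in factors:
            p = RUNOFF_PARAMS.replace(v_insert=RUNOFF_PARAMS.v_flank / f)
            ts, _ = simulate_traces(TARGET_DESIGN, p, n_rna=n_rna, seed=s,
                                    n_cells=n_cells)
            est = elongation_fold(runoff_cohort_median(ts), v0, L_INSERT, L_FLANK)
            detail[f].append(est.speed_fold)
    means = {f: float(np.mean(v)) for f, v in detail.items()}
    return means, detail, v0s


#: reference conditions of the two-color frameshift observation
FRAMESHIFT_PARAMS = KineticParams(
    k_init=0.02,
    dt=10.0,
    duration=1800.0,
    noise_sd=0.2,
)


def frameshift_recovery(
    p_fs_values=(0.0, 0.02, 0.05, 0.10),
    seed: int = 0,
    n_traces: int = 500,
    k_sigma: float = 4.0,
):
    """Classify simulated two-color cohorts against ground truth.

    Returns per probability: recovered frameshift percent (classifier),
    true percent (ground-truth classes), number of translating traces,
    and the false-positive (frameshift + ran_only) percent.
    """
    out = {}
    thr = k_sigma * FRAMESHIFT_PARAMS.noise_sd + FRAMESHIFT_PARAMS.background
    for i, p_fs in enumerate(p_fs_values):
        p = FRAMESHIFT_PARAMS.replace(p_fs_traversal=float(p_fs))
        ts, truth = simulate_traces("frameshift_twocolor", p, n_rna=n_traces,
                                    seed=int(seed) + 7919 * i, n_cells=10)
        calls = {}
        for tr in ts.iter_traces():
            b1 = call_bursts(tr.ch1, thr)
            b2 = call_bursts(tr.ch2, thr)
            calls[(tr.cell_id, tr.rna_id)] = classify_trace(b1, b2)
        called = np.array(list(calls.values()))
        translating = called != "silent"
        n_tr = int(translating.sum())
        fs_pct = 100.0 * np.mean(called[translating] == "frameshift") if n_tr else np.nan
        fp_pct = 100.0 * np.mean(
            np.isin(called[translating], ["frameshift", "ran_only"])
        ) if n_tr else np.nan
        st = truth.rna_states
        true_translating = st["class"] != "silent"
        true_pct = 100.0 * np.mean(
            st.loc[true_translating, "class"] == "frameshift"
        )
        out[float(p_fs)] = {
            "recovered_pct": float(fs_pct),
            "true_pct": float(true_pct),
            "n_translating": n_tr,
            "fp_pct": float(fp_pct),
        }
    return out


def short_reporter():
    """Short one-color design (200 codons) for burst-kinetics studies.

    The nascent-signal tail after an OFF switch lasts one ribosome
    transit (~57 s here); a short ORF keeps that tail small relative to
    the telegraph periods so the called ON fraction tracks the true
    initiation duty cycle.
    """
    from .reporters import build_reporter

    return build_reporter({
        "name": "short_24x",
        "total_length": 200,
        "regions": [("cassette_ch1", 1, 180, "epitope_cassette"),
                    ("flank", 181, 200, "flank")],
        "epitope_positions_ch1": list(np.linspace(180 / 24, 180, 24).round().astype(int)),
    })


def duty_cycle_recovery(
    duty: float = 0.45,
    seed: int = 0,
    n_traces: int = 200,
    k_sigma: float = 4.0,
):
    """Recover the telegraph duty cycle as mean fraction of time translating.

    Slow switching (mean ON ~13 min) on the short reporter; returns
    (recovered mean fraction, true ON fraction from ground truth).
    """
    k_off = 1.0 / 800.0
    k_on = duty / (1.0 - duty) * k_off
    p = KineticParams(
        k_on=k_on,
        k_off=k_off,
        k_init=0.06,
        duration=1800.0,
        burn_in=300.0,
    )
    ts, truth = simulate_traces(short_reporter(), p, n_rna=n_traces, seed=seed, n_cells=10)
    thr = k_sigma * p.noise_sd + p.background
    fracs = [fraction_time_translating(tr.ch1, thr) for tr in ts.iter_traces()]
    on = truth.on_intervals
    true_frac = float((on["end_s"] - on["start_s"]).sum() / (n_traces * p.duration))
    return float(np.mean(fracs)), true_frac


def localization_benchmark(seed: int = 0, n: int = 100, snr: float = 10.0,
                           sigma: float = 1.3, background: float = 100.0) -> float:
    """RMS sub-pixel localization error over ``n`` single-spot renders.

    Peak amplitude is ``snr * sqrt(background)`` (Poisson shot noise),
    matching the detection module's working regime.
    """
    from .detection import detect_spots
    from .rendering import render_frame

    amp = snr * np.sqrt(background)
    errs = []
    for i in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(55, i))
        )
        x = 20.0 + 2.0 * rng.random()
        y = 20.0 + 2.0 * rng.random()
        img = render_frame(48, 48, [x], [y], [amp], sigma, background, rng)
        spots = detect_spots(img, sigma, 5.0)
        if len(spots) == 1:
            errs.append((spots[0].x - x) ** 2 + (spots[0].y - y) ** 2)
    if not errs:
        raise RuntimeError("no spots recovered in localization benchmark")
    return float(np.sqrt(np.mean(errs)))


def pair_recovery_benchmark(seed: int = 0, n_rna: int = 20, n_frames: int = 30):
    """End-to-end detect -> link -> pair on a rendered two-channel movie.

    Returns (fraction of true RNA--translation-site pairs recovered,
    number of RNAs).  RNA-channel brightness is set for spot SNR ~10.
    """
    from .detection import detect_movie, filter_tracks, link_rna_protein, link_spots
    from .rendering import Optics, render_movie

    p = KineticParams(
        k_on=0.0, k_off=0.0, k_init=0.06, burn_in=300.0,
        duration=(n_frames - 1) * 10.0, rna_intensity=100.0,
    )
    ts, _ = simulate_traces(CONTROL_DESIGN, p, n_rna=n_rna, seed=seed,
                            positions=True, fov=(128, 128), min_separation=8.0)
    stacks, _ = render_movie(ts, Optics(), seed=int(seed) + 1)
    rna_tracks, _ = filter_tracks(
        link_spots(detect_movie(stacks["rna"].astype(float)), channel="rna")
    )
    ch1_tracks, _ = filter_tracks(
        link_spots(detect_movie(stacks["ch1"].astype(float)), channel="ch1")
    )
    links, _ = link_rna_protein(rna_tracks, ch1_tracks)
    pos = ts.traces.groupby(["cell_id", "rna_id"])[["x_px", "y_px"]].mean()
    hit = set()
    for lt in links:
        if lt.ch1_track is None:
            continue
        s0 = lt.rna_track.spots[0]
        d = np.hypot(pos["x_px"] - s0.x, pos["y_px"] - s0.y)
        j = int(np.argmin(d.to_numpy()))
        if d.to_numpy()[j] < 2.0:
            hit.add(pos.index[j])
    return len(hit) / len(pos), len(pos)
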