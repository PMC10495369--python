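import numpy as np
import pandas as pd
import pytest

import ribotrace as rt
from ribotrace._engine import simulate_rna_excluded, simulate_rna_free, telegraph_intervals
from ribotrace.kinetics import ParameterError


def test_no_initiation_gives_zero_signal(nluc_design):
    p = rt.KineticParams(k_init=0.0, noise_sd=0.0, background=0.0, duration=300.0)
    ts, truth = rt.simulate_traces(nluc_design, p, n_rna=3, seed=1)
    assert np.all(ts.traces["ch1_signal"] == 0.0)
    assert len(truth.ribosomes) == 0
    assert set(truth.rna_states["class"]) == {"silent"}


def test_deterministic_single_ribosome_transit():
    # one ribosome over L=1003 codons at v=3.5 terminates at exactly L/v
    speeds = np.full(1003, 3.5)
    rec = simulate_rna_free(
        speeds, np.array([500]), np.array([], int), 1003, 1003, 0, -1, 0.0,
        np.array([0.0]), np.empty(0), 1, np.random.default_rng(0), deterministic=True,
    )
    assert rec[0][3] == pytest.approx(1003 / 3.5, rel=1e-9)


def test_steady_state_mean_signal_matches_littles_law(nluc_design):
    # E[signal]/unit = k_init * sum_i (L - p_i) / v  (no bursting, no exclusion)
    p = rt.KineticParams(k_off=0.0, k_init=0.02, exclusion=False, noise_sd=0.0,
                         background=0.0, duration=3600.0)
    ts, _ = rt.simulate_traces(nluc_design, p, n_rna=500, seed=3)
    eps = np.asarray(nluc_design.epitope_positions_ch1)
    expected = p.k_init * np.sum((nluc_design.total_length - eps) / p.v_flank)
    observed = ts.traces.loc[ts.traces.time_s >= 600, "ch1_signal"].mean()
    assert observed == pytest.approx(expected, rel=0.05)


def test_noiseless_signal_is_integer_multiple_of_unit(nluc_design):
    p = rt.KineticParams(noise_sd=0.0, background=0.0, unit_intensity=0.7, duration=600.0)
    ts, _ = rt.simulate_traces(nluc_design, p, n_rna=5, seed=4)
    units = ts.traces["ch1_signal"].to_numpy() / 0.7
    assert np.allclose(units, np.round(units), atol=1e-9)


def test_signal_decays_and_clears_after_drug(nluc_design):
    # after initiation stops, signal may transiently rise while loaded
    # ribosomes finish the epitope cassette, then decays monotonically
    # and reaches zero within one full transit
    p = rt.KineticParams(k_off=0.0, noise_sd=0.0, background=0.0, burn_in=600.0,
                         t_drug=0.0, duration=1800.0)
    ts, truth = rt.simulate_traces(nluc_design, p, n_rna=10, seed=5)
    cassette_end = max(nluc_design.epitope_positions_ch1)
    t_casette_clear = cassette_end / p.v_flank
    horizon = nluc_design.total_length / min(p.v_flank, p.v_insert)
    for tr in ts.iter_traces():
        tail = tr.ch1[tr.time > t_casette_clear]
        assert np.all(np.diff(tail) <= 1e-9)
        assert np.all(tr.ch1[tr.time > horizon] == 0.0)
    assert np.all(truth.rna_states["clearance_time_s"] <= horizon)


def test_steric_exclusion_keeps_footprint_distance(tiny_design):
    # epitope at every codon => completion times give the full trajectory;
    # a follower reaching codon c implies its leader had cleared c + footprint
    fp = 5
    speeds = np.full(30, 2.0)
    eps = np.arange(1, 31)
    init = np.arange(0.0, 100.0, 1.0)  # pressure: frequent initiation attempts
    rec = simulate_rna_excluded(
        speeds, eps, np.array([], int), 30, 30, 0, -1, 0.0, fp,
        init, np.empty(0), 1, np.random.default_rng(7),
    )
    rec.sort(key=lambda r: r[0])
    for lead, follow in zip(rec, rec[1:]):
        t_lead, t_follow = lead[4], follow[4]
        for c in range(1, 31 - fp):
            assert t_lead[c + fp - 1] <= t_follow[c - 1] + 1e-12


def test_frameshift_fraction_matches_per_traversal_probability(twocolor_design):
    p = rt.KineticParams(k_off=0.0, k_init=0.06, exclusion=False,
                         p_fs_traversal=0.05, duration=2000.0)
    ts, truth = rt.simulate_traces(twocolor_design, p, n_rna=100, seed=11)
    rib = truth.ribosomes[~truth.ribosomes["is_ran"]]
    n = len(rib)
    assert n > 10_000  # enough traversals for a tight binomial check
    frac = rib["fs_flag"].mean()
    se = np.sqrt(0.05 * 0.95 / n)
    assert abs(frac - 0.05) < 1.96 * se * 1.5
    # every frameshift codon lies inside the insert
    ins = twocolor_design.insert_region
    fs_codons = rib.loc[rib["fs_flag"], "fs_codon"]
    assert fs_codons.between(ins.start, ins.end).all()


def test_telegraph_duty_cycle_converges():
    rng = np.random.default_rng(0)
    ivs = telegraph_intervals(0.01, 0.012, 2_000_000.0, rng)
    on = sum(b - a for a, b, s in ivs if s)
    assert on / 2_000_000.0 == pytest.approx(0.01 / 0.022, abs=0.01)


def test_identical_seed_gives_identical_traceset(twocolor_design):
    p = rt.KineticParams(p_fs_traversal=0.02, duration=400.0)
    a, _ = rt.simulate_traces(twocolor_design, p, n_rna=8, seed=42, n_cells=2)
    b, _ = rt.simulate_traces(twocolor_design, p, n_rna=8, seed=42, n_cells=2)
    pd.testing.assert_frame_equal(a.traces, b.traces)
    c, _ = rt.simulate_traces(twocolor_design, p, n_rna=8, seed=43, n_cells=2)
    assert not a.traces["ch1_signal"].equals(c.traces["ch1_signal"])


def test_seed_is_mandatory(nluc_design):
    with pytest.raises(ParameterError, match="seed"):
        rt.simulate_traces(nluc_design, rt.KineticParams(), n_rna=1, seed=None)


def test_frames_are_consecutive_and_times_match_dt(nluc_design):
    p = rt.KineticParams(duration=200.0, dt=10.0)
    ts, _ = rt.simulate_traces(nluc_design, p, n_rna=3, seed=2)
    for tr in ts.iter_traces():
        assert np.allclose(np.diff(tr.time), 10.0)
        assert np.isfinite(tr.ch1).all() and np.isfinite(tr.rna).all()


def test_bleach_zeroes_accumulated_fluorescence(nluc_design):
    p = rt.KineticParams(k_off=0.0, k_init=0.06, noise_sd=0.0, background=0.0,
                         burn_in=600.0, t_bleach=100.0, duration=600.0, dt=5.0)
    ts, _ = rt.simulate_traces(nluc_design, p, n_rna=5, seed=6)
    for tr in ts.iter_traces():
        pre = tr.ch1[tr.time < 100.0]
        at_bleach = float(tr.ch1[tr.time == 100.0][0])
        assert pre.mean() > 20  # loaded site before the bleach
        assert at_bleach == 0.0  # all accumulated fluorescence zeroed
        assert tr.ch1[-1] > 5  # newly completed epitopes recover the signal


def test_on_off_intervals_cover_recorded_window(nluc_design):
    p = rt.KineticParams(duration=900.0)
    _, truth = rt.simulate_traces(nluc_design, p, n_rna=6, seed=9)
    for (_, _), g in truth.on_intervals.groupby(["cell_id", "rna_id"]):
        starts = g["start_s"].to_numpy()
        ends = g["end_s"].to_numpy()
        assert np.all(starts[1:] >= ends[:-1] - 1e-9)  # disjoint, ordered
        assert np.all(starts >= 0.0) and np.all(ends <= 900.0 + 1e-9)


class TestMatureProteins:
    def test_zero_cv_is_exactly_the_median(self):
        p = rt.KineticParams(mature_cv=0.0, mature_median=24.0)
        v = rt.sample_mature_proteins(p, 10, seed=0)
        assert np.all(v == 24.0)

    def test_large_sample_median(self):
        p = rt.KineticParams(mature_median=1000.0, mature_cv=0.3)
        v = rt.sample_mature_proteins(p, 100_000, seed=2)
        assert np.median(v) == pytest.approx(1000.0, rel=0.02)
        assert np.all(v > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            rt.sample_mature_proteins(rt.KineticParams(), 0, seed=0)
        with pytest.raises(ValueError):
            rt.KineticParams(mature_cv=-1.0)


class TestSnapshot:
    def test_silent_regime_background_only(self, nluc_design):
        p = rt.KineticParams(k_on=0.0, k_off=1.0, background=5.0, noise_sd=0.1)
        snap, _ = rt.simulate_smfish_snapshot(nluc_design, p, 3, 5, seed=1, warmup=200.0)
        assert snap["tls_intensity"].abs().max() < 6.0
        assert not snap["true_translating"].any()

    def test_loaded_site_outshines_single_mature_protein(self, nluc_design):
        p = rt.KineticParams(k_off=0.0, k_init=0.06)
        snap, _ = rt.simulate_smfish_snapshot(nluc_design, p, 2, 5, seed=3)
        mature = rt.sample_mature_proteins(p, 1000, seed=4)
        assert snap["tls_intensity"].median() > 3 * np.median(mature)
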