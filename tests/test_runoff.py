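import numpy as np
import pytest
from scipy import stats

import ribotrace as rt
from conftest import make_trace


class TestExtractRunoff:
    def test_worked_example_70s(self):
        tr = make_trace([50, 48, 45, 40, 30, 20, 10, 4, 3, 2], dt=10.0)
        rec = rt.extract_runoff_time(tr, t_drug=0.0)
        assert rec.exclusion == "none" and not rec.censored
        assert rec.runoff_time == 70.0

    def test_low_initial_signal_discarded(self):
        sig = [2, 3, 1, 2] + [50] * 10 + [1, 1, 1]
        rec = rt.extract_runoff_time(make_trace(sig), t_drug=0.0)
        assert rec.exclusion == "low_initial"

    def test_never_below_threshold_censors_at_movie_end(self):
        sig = np.full(181, 50.0)
        rec = rt.extract_runoff_time(make_trace(sig), t_drug=0.0)
        assert rec.censored and rec.censor_time == 1800.0

    def test_co_disappearance_excluded(self):
        sig = np.array([50.0] * 10 + [1.0] * 10)
        rna = np.array([10.0] * 11 + [np.nan] * 9)  # RNA vanishes with the protein
        rec = rt.extract_runoff_time(make_trace(sig, rna=rna), t_drug=0.0)
        assert rec.exclusion == "co_disappear"

    def test_brief_dip_does_not_trigger_runoff(self):
        # one sub-threshold frame then recovery: persistence of 3 guards it
        sig = [50, 48, 45, 40, 2, 40, 38, 2, 1, 1]
        rec = rt.extract_runoff_time(make_trace(sig), t_drug=0.0)
        assert rec.runoff_time == 70.0

    def test_short_track_excluded(self):
        rec = rt.extract_runoff_time(make_trace([50, 40, 30, 2, 1]), t_drug=0.0)
        assert rec.exclusion == "short_track"

    def test_drug_after_trace_end_rejected(self):
        with pytest.raises(ValueError):
            rt.extract_runoff_time(make_trace([50] * 10), t_drug=500.0)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = [2.0, 4.0, 6.0]
        recs = [rt.RunoffRecord(0, i, runoff_time=t) for i, t in enumerate(times)]
        c = rt.km_survival(recs)
        assert np.allclose(c.times, [0, 2, 4, 6])
        assert np.allclose(c.survival, [1, 2 / 3, 1 / 3, 0])
        assert c.median == 4.0

    def test_random_uncensored_km_is_empirical(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10.0, 40)
        recs = [rt.RunoffRecord(0, i, runoff_time=float(t)) for i, t in enumerate(times)]
        c = rt.km_survival(recs)
        for t in [1.0, 5.0, 12.0]:
            assert c.at(t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_greenwood_hand_example(self):
        # event at 1, censored at 2, event at 3, one more censored: after
        # t=1 (n=4, d=1) S=0.75 and SE = 0.75*sqrt(1/12)
        recs = [
            rt.RunoffRecord(0, 0, runoff_time=1.0),
            rt.RunoffRecord(0, 1, censored=True, censor_time=2.0),
            rt.RunoffRecord(0, 2, runoff_time=3.0),
            rt.RunoffRecord(0, 3, censored=True, censor_time=5.0),
        ]
        c = rt.km_survival(recs)
        i = list(c.times).index(1.0)
        se = 0.75 * np.sqrt(1.0 / 12.0)
        assert c.survival[i] == pytest.approx(0.75)
        assert c.ci_low[i] == pytest.approx(0.75 - 1.959964 * se, abs=1e-6)
        assert c.ci_high[i] == pytest.approx(min(1.0, 0.75 + 1.959964 * se), abs=1e-6)

    def test_against_lifelines_oracle(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        t = rng.exponential(5.0, 60)
        cens = rng.random(60) < 0.3
        obs_t = np.where(cens, t * rng.random(60), t)
        recs = [
            rt.RunoffRecord(0, i, runoff_time=float(x)) if not c
            else rt.RunoffRecord(0, i, censored=True, censor_time=float(x))
            for i, (x, c) in enumerate(zip(obs_t, cens))
        ]
        ours = rt.km_survival(recs)
        kmf = KaplanMeierFitter().fit(obs_t, ~cens)
        for q in [1.0, 3.0, 6.0, 10.0]:
            assert ours.at(q) == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0]), abs=1e-10
            )

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(3)
        recs = [rt.RunoffRecord(0, i, runoff_time=float(t))
                for i, t in enumerate(rng.gamma(3, 5, 30))]
        c = rt.km_survival(recs)
        assert c.survival[0] == 1.0 and c.times[0] == 0.0
        assert np.all(np.diff(c.survival) <= 0)
        assert np.all((c.ci_low <= c.survival + 1e-12) & (c.survival <= c.ci_high + 1e-12))
        assert np.all((c.survival >= 0) & (c.survival <= 1))

    def test_median_undefined_when_curve_stays_high(self):
        recs = [rt.RunoffRecord(0, 0, runoff_time=1.0)] + [
            rt.RunoffRecord(0, i, censored=True, censor_time=9.0) for i in range(1, 8)
        ]
        assert rt.km_survival(recs).median is None

    def test_all_excluded_raises(self):
        recs = [rt.RunoffRecord(0, 0, exclusion="low_initial")]
        with pytest.raises(ValueError):
            rt.km_survival(recs)


class TestPerCellSurvival:
    def test_single_cell_matches_empirical(self):
        recs = [rt.RunoffRecord(0, i, runoff_time=t) for i, t in enumerate([2.0, 4.0, 6.0])]
        c = rt.per_cell_survival(recs)
        pooled = rt.km_survival(recs)
        for t in [1.0, 3.0, 5.0, 7.0]:
            assert c.at(t) == pytest.approx(pooled.at(t))

    def test_two_cells_average(self):
        recs = [rt.RunoffRecord(0, 0, runoff_time=1.0),
                rt.RunoffRecord(1, 0, runoff_time=9.0)]
        c = rt.per_cell_survival(recs)
        assert c.at(5.0) == pytest.approx(0.5)  # one cell at 0, one at 1

    def test_agrees_with_pooled_on_homogeneous_cells(self):
        rng = np.random.default_rng(11)
        recs = []
        for cell in range(8):
            for i, t in enumerate(rng.exponential(300.0, 12)):
                recs.append(rt.RunoffRecord(cell, i, runoff_time=float(t)))
        pc = rt.per_cell_survival(recs)
        pooled = rt.km_survival(recs)
        for t in [100.0, 300.0, 600.0]:
            se = (pc.ci_high[np.searchsorted(pc.times, t) - 1]
                  - pc.ci_low[np.searchsorted(pc.times, t) - 1]) / 2
            assert abs(pc.at(t) - pooled.at(t)) <= max(se, 0.05)


class TestLogrank:
    def test_identical_groups_null(self):
        recs = [rt.RunoffRecord(0, i, runoff_time=t) for i, t in enumerate([1.0, 2.0, 5.0])]
        chi2, p = rt.logrank_test(recs, list(recs))
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_example(self):
        a = [rt.RunoffRecord(0, i, runoff_time=t) for i, t in enumerate([1.0, 2.0, 3.0])]
        b = [rt.RunoffRecord(0, i, runoff_time=t) for i, t in enumerate([4.0, 5.0, 6.0])]
        chi2, p = rt.logrank_test(a, b)
        assert chi2 == pytest.approx(5.05, abs=0.02)
        assert p == pytest.approx(0.025, abs=0.003)

    @staticmethod
    def _chi2_uncensored(xa, xb):
        # direct O-E / V evaluation of the log-rank statistic (all events)
        pooled = np.concatenate([xa, xb])
        labels = np.concatenate([np.ones(len(xa)), np.zeros(len(xb))])
        order = np.argsort(pooled)
        labels = labels[order]
        n = len(pooled)
        at_risk = np.arange(n, 0, -1, dtype=float)
        a_at_risk = len(xa) - np.concatenate([[0.0], np.cumsum(labels)[:-1]])
        e = a_at_risk / at_risk
        v = e * (1 - e)
        o_minus_e = labels.sum() - e.sum()
        return o_minus_e**2 / v.sum()

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        xa = rng.exponential(3.0, 8)
        xb = rng.exponential(6.0, 9)
        a = [rt.RunoffRecord(0, i, runoff_time=float(t)) for i, t in enumerate(xa)]
        b = [rt.RunoffRecord(0, i, runoff_time=float(t)) for i, t in enumerate(xb)]
        chi2, p = rt.logrank_test(a, b)
        # the direct evaluation agrees with the implementation
        assert self._chi2_uncensored(xa, xb) == pytest.approx(chi2, rel=1e-9)

        # permutation reference: resample group labels, recompute the statistic
        pooled = np.concatenate([xa, xb])
        n_a = len(xa)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if self._chi2_uncensored(perm[:n_a], perm[n_a:]) >= chi2 - 1e-12:
                count += 1
        p_perm = count / n_perm
        mc_se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(p - p_perm) < max(4 * mc_se, 0.02)

    def test_group_without_events_rejected(self):
        a = [rt.RunoffRecord(0, 0, runoff_time=1.0)]
        b = [rt.RunoffRecord(0, 0, censored=True, censor_time=2.0)]
        with pytest.raises(ValueError):
            rt.logrank_test(a, b)


class TestElongationAlgebra:
    def test_estimate_v0_direct(self):
        assert rt.estimate_v0(100.0, 100.0) == 1.0
        # NLuc construct: 863 + 171 codons over the printed 4 min 54 s median
        assert rt.estimate_v0(294.0, 1034.0) == pytest.approx(3.517, abs=0.01)
        with pytest.raises(ValueError):
            rt.estimate_v0(0.0, 100.0)

    def test_uniform_speed_identity(self):
        v0, L_I, L_0 = 3.5, 140.0, 863.0
        est = rt.elongation_fold((L_I + L_0) / v0, v0, L_I, L_0)
        assert est.speed_fold == pytest.approx(1.0, rel=1e-12)

    def test_decomposition_sums_to_total(self):
        est = rt.elongation_fold(672.0, 3.517, 140.0, 863.0)
        assert est.t_I + est.t_0 == pytest.approx(672.0, rel=1e-12)
        assert est.per_aa_time_fold == est.speed_fold

    def test_published_medians_give_published_fold_range(self):
        v0 = rt.estimate_v0(294.0, 1034.0)
        gp = rt.elongation_fold(672.0, v0, 140.0, 863.0)
        gr = rt.elongation_fold(810.0, v0, 140.0, 863.0)
        assert 9.0 <= gp.speed_fold <= 12.0
        assert 13.0 <= gr.speed_fold <= 16.0

    def test_degenerate_insert_time_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            rt.elongation_fold(100.0, 3.5, 140.0, 863.0)

    def test_fold_runoff_time(self):
        assert rt.fold_runoff_time(11.2, 4.9) == 2.3
        assert rt.fold_runoff_time(13.5, 4.9) == 2.8
        assert rt.fold_runoff_time(4.9, 4.9) == 1.0
        with pytest.raises(ValueError):
            rt.fold_runoff_time(1.0, 0.0)


class TestFrap:
    def test_instantaneous_recovery_has_small_half_time(self):
        sig = np.array([10.0, 10, 10, 0, 10, 10, 10, 10, 10, 10])
        tr = make_trace(sig, dt=5.0)
        _, half, plateau = rt.frap_recovery(tr, t_bleach=15.0)
        assert half is not None and half <= 5.0
        assert plateau == pytest.approx(1.0)

    def test_no_recovery_plateau_near_zero(self):
        sig = np.array([10.0] * 3 + [0.0] * 17)
        tr = make_trace(sig, dt=5.0)
        _, half, plateau = rt.frap_recovery(tr, t_bleach=15.0)
        assert plateau == pytest.approx(0.0, abs=1e-9)

    def test_needs_pre_bleach_frames(self):
        with pytest.raises(ValueError):
            rt.frap_recovery(make_trace([5.0] * 10, dt=5.0), t_bleach=0.0)

    def test_half_time_orders_with_insert_speed(self, repeat_design):
        # slower repeat translation -> slower translation-site recovery
        halves = []
        for v_i in (3.5, 0.35, 0.23):
            p = rt.KineticParams(
                k_off=0.0, k_init=0.06, v_insert=v_i, exclusion=False,
                burn_in=900.0, t_bleach=30.0, dt=5.0, duration=600.0,
            )
            ts, _ = rt.simulate_traces(repeat_design, p, n_rna=25, seed=77)
            hs = []
            for tr in ts.iter_traces():
                _, h, _ = rt.frap_recovery(tr, 30.0)
                if h is not None:
                    hs.append(h)
            halves.append(np.mean(hs))
        assert halves[0] < halves[1] < halves[2]


def test_greenwood_ci_coverage_on_exponential_data():
    # pointwise 95% CI coverage of S(t0)=exp(-t0) at t0 = true median,
    # n=50 per replicate; plain Greenwood should cover >= 90%
    rng = np.random.default_rng(2024)
    t0 = np.log(2.0)
    covered = 0
    n_rep = 500
    for _ in range(n_rep):
        x = rng.exponential(1.0, 50)
        recs = [rt.RunoffRecord(0, i, runoff_time=float(v)) for i, v in enumerate(x)]
        c = rt.km_survival(recs)
        i = np.searchsorted(c.times, t0, side="right") - 1
        if c.ci_low[i] <= 0.5 <= c.ci_high[i]:
            covered += 1
    assert covered / n_rep >= 0.90
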