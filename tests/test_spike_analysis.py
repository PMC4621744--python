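"""Z-scoring, response classification, PSTH/AUC, latency and population tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

import fearephys as fp
from fearephys import spike_analysis as sa
from fearephys.protocol import ValidationError
from fearephys.spike_analysis import (
    LatencyResult,
    ResponseLabel,
    UnclassifiableBaseline,
)


def _z_trace(values, bin_s=0.1, start=0.0, unit="u"):
    values = np.asarray(values, dtype=float)
    edges = start + bin_s * np.arange(values.size + 1)
    return sa.ZScoreTrace(edges, values, unit_id=unit, alignment="stimulus-locked")


class TestBinRates:
    def test_hand_counted_rates(self):
        train = fp.SpikeTrain("u", np.array([0.05, 0.15]))
        binned = sa.bin_rates(train, np.array([0.0, 0.1, 0.2]))
        np.testing.assert_allclose(binned.rates_hz, [10.0, 10.0])

    def test_empty_train_all_zero(self):
        binned = sa.bin_rates(fp.SpikeTrain("u", np.array([])), np.arange(0, 1.1, 0.1))
        assert np.all(binned.rates_hz == 0.0)

    def test_against_naive_counting_oracle(self, rng):
        spikes = np.sort(rng.uniform(0, 100, size=10_000))
        spikes = np.unique(spikes)
        edges = np.linspace(0, 100, 201)
        binned = sa.bin_rates(fp.SpikeTrain("u", spikes), edges)
        naive = np.array([
            np.sum((spikes >= lo) & (spikes < hi)) for lo, hi in zip(edges[:-1], edges[1:])
        ])
        np.testing.assert_array_equal(binned.rates_hz * np.diff(edges), naive)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValidationError):
            sa.bin_rates(fp.SpikeTrain("u", np.array([0.1])), np.array([0.0, 0.2, 0.1]))


class TestBaselineStats:
    def test_constant_baseline_flagged_degenerate(self):
        rates = sa.BinnedRates(np.arange(0, 1.1, 0.1), np.full(10, 5.0))
        stats = sa.baseline_stats(rates, (0.0, 1.0))
        assert stats.mean_rate_hz == 5.0
        assert stats.sd_rate_hz == 0.0
        assert stats.degenerate

    def test_sample_sd_ddof1(self):
        rates = sa.BinnedRates(np.array([0.0, 1.0, 2.0]), np.array([4.0, 6.0]))
        stats = sa.baseline_stats(rates, (0.0, 2.0))
        assert stats.mean_rate_hz == 5.0
        assert stats.sd_rate_hz == pytest.approx(math.sqrt(2.0))

    def test_window_outside_baseline_epoch_rejected(self, default_schedule):
        rates = sa.BinnedRates(np.arange(0, 700.0, 0.5), np.zeros(1399))
        with pytest.raises(ValidationError, match="BASELINE"):
            sa.baseline_stats(rates, (500.0, 650.0), default_schedule)


class TestZScore:
    def test_identity_and_unit_cases(self):
        rates = sa.BinnedRates(np.array([0.0, 1.0, 2.0, 3.0]), np.array([5.0, 7.0, 3.0]))
        stats = sa.BaselineStats(5.0, 2.0, 10, (0.0, 1.0))
        z = sa.zscore(rates, stats)
        np.testing.assert_allclose(z.z, [0.0, 1.0, -1.0])

    def test_elementwise_recomputation_oracle(self, rng):
        rates_v = rng.gamma(2.0, 3.0, size=500)
        stats = sa.BaselineStats(4.2, 1.7, 100, (0.0, 10.0))
        rates = sa.BinnedRates(np.arange(501.0), rates_v)
        z = sa.zscore(rates, stats)
        np.testing.assert_allclose(z.z, (rates_v - 4.2) / 1.7, atol=1e-12)

    def test_degenerate_baseline_raises(self):
        rates = sa.BinnedRates(np.array([0.0, 1.0]), np.array([5.0]))
        with pytest.raises(UnclassifiableBaseline):
            sa.zscore(rates, sa.BaselineStats(5.0, 0.0, 10, (0.0, 1.0)))

    def test_baseline_z_selfnormalizes(self, rng):
        """Z of the baseline bins under their own stats: mean 0, sd 1."""
        vals = rng.poisson(0.5, size=6000) / 0.1
        edges = 0.1 * np.arange(6001)
        rates = sa.BinnedRates(edges, vals)
        stats = sa.baseline_stats(rates, (0.0, 600.0))
        z = sa.zscore(rates, stats)
        assert np.mean(z.z) == pytest.approx(0.0, abs=1e-10)
        assert np.std(z.z, ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestClassifyUnit:
    def test_threshold_semantics(self):
        """Crossing +1 activates; crossing -0.5 (without +1) inhibits."""
        act = sa.classify_unit(_z_trace([0.0, 0.3, 1.2, 0.5, 0.1]))
        assert act.label is ResponseLabel.ACTIVATED
        assert act.peak_z == pytest.approx(1.2)
        assert act.latency_s == pytest.approx(0.2)

        inh = sa.classify_unit(_z_trace([0.0, -0.2, 0.4, 0.2, -0.6]))
        assert inh.label is ResponseLabel.INHIBITED
        assert inh.peak_z == pytest.approx(-0.6)
        assert inh.latency_s == pytest.approx(0.4)

        flat = sa.classify_unit(_z_trace([0.0] * 5))
        assert flat.label is ResponseLabel.NON_RESPONSIVE
        assert flat.latency_s is None

    def test_activation_has_priority_over_inhibition(self):
        both = sa.classify_unit(_z_trace([-0.8, 0.0, 1.5, 0.0, 0.0]))
        assert both.label is ResponseLabel.ACTIVATED

    def test_crossing_outside_window_ignored(self):
        z = _z_trace([0.0, 0.0, 0.0, 0.0, 0.0, 2.0], start=0.0)  # 2.0 at 0.5 s
        assert sa.classify_unit(z).label is ResponseLabel.NON_RESPONSIVE

    def test_window_coverage_required(self):
        with pytest.raises(ValidationError):
            sa.classify_unit(_z_trace([1.0, 1.0], start=0.0))  # only covers 0.2 s

    @given(
        st.lists(st.floats(-3, 3, allow_nan=False), min_size=5, max_size=5),
        st.floats(0.1, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, vals, c):
        """Multiplying rates and baseline stats by c > 0 preserves the label."""
        # values landing exactly on a threshold flip under float rounding
        assume(all(abs(v - 1.0) > 1e-6 and abs(v + 0.5) > 1e-6 for v in vals))
        mean, sd = 5.0, 2.0
        rates = np.array(vals) * sd + mean
        edges = 0.1 * np.arange(6)
        z1 = sa.zscore(sa.BinnedRates(edges, rates), sa.BaselineStats(mean, sd, 10, (0, 1)))
        z2 = sa.zscore(
            sa.BinnedRates(edges, rates * c), sa.BaselineStats(mean * c, sd * c, 10, (0, 1))
        )
        assert sa.classify_unit(z1).label is sa.classify_unit(z2).label

    def test_false_positive_rate_matches_monte_carlo_oracle(self):
        """Homogeneous 5 Hz units at 100 ms bins: pipeline FP rate vs oracle.

        Both routes run the same experiment (600 s baseline; 10-trial-averaged
        500 ms response window) on independent draws; the pipeline uses the
        package operators, the oracle is direct numpy recomputation.
        """
        n_units, n_base, n_trials, n_resp = 3000, 6000, 10, 5
        bw, rate = 0.1, 5.0

        def experiment(seed, pipeline: bool):
            r = np.random.default_rng(seed)
            base = r.poisson(rate * bw, size=(n_units, n_base)) / bw
            resp = r.poisson(rate * bw, size=(n_units, n_trials, n_resp)).mean(axis=1) / bw
            fps = 0
            edges = bw * np.arange(n_resp + 1)
            for i in range(n_units):
                mu, sd = base[i].mean(), base[i].std(ddof=1)
                if pipeline:
                    stats = sa.BaselineStats(mu, sd, n_base, (0, n_base * bw))
                    z = sa.zscore(sa.BinnedRates(edges, resp[i]), stats)
                    fps += sa.classify_unit(z).label is ResponseLabel.ACTIVATED
                else:
                    fps += np.any((resp[i] - mu) / sd > 1.0)
            return fps / n_units

        fp_pipe = experiment(1, pipeline=True)
        fp_mc = experiment(2, pipeline=False)
        p = (fp_pipe + fp_mc) / 2
        se = math.sqrt(max(p * (1 - p), 1e-6) * 2 / n_units)
        assert abs(fp_pipe - fp_mc) < 4 * se + 1e-3


class TestPeristimulusCurve:
    def _train_with_rate_step(self):
        # deterministic spikes: 1 per 10 ms during [onset, onset+1) of each trial
        trials = [fp.TrialWindow(i, fp.EpochLabel.CS_PLUS, 100.0 * (i + 1), 10.0) for i in range(4)]
        spikes = np.concatenate([t.onset_s + np.arange(0, 1, 0.01) for t in trials])
        return fp.SpikeTrain("u", np.sort(spikes)), trials

    def test_constant_z_rectangle_auc(self):
        """A flat Z = 1 over [0, 1] s integrates to AUC = 1 Z.s."""
        train, trials = self._train_with_rate_step()
        # baseline chosen so the in-response rate (100 Hz) maps to Z = 1
        stats = sa.BaselineStats(0.0, 100.0, 100, (0.0, 50.0))
        curve = sa.peristimulus_curve(train, trials, stats, pre_s=1.0, post_s=2.0, bin_s=0.05)
        in_resp = (curve.time_s > 0) & (curve.time_s < 1)
        np.testing.assert_allclose(curve.mean_z[in_resp], 1.0)
        assert curve.auc == pytest.approx(1.0, abs=0.06)  # edge bins straddle 0 and 1

    def test_triangular_peak_auc_closed_form(self):
        """Symmetric triangle of height 2 over [0, 1] has area 1 (geometry)."""
        t = np.linspace(0.0, 1.0, 41)  # includes the apex at 0.5
        tri = 2.0 * (1.0 - np.abs((t - 0.5) / 0.5))
        assert sa.auc_of_curve(t, tri, (0.0, 1.0)) == pytest.approx(1.0, abs=1e-12)

    def test_auc_matches_hand_trapezoid_oracle(self, rng):
        t = np.sort(rng.uniform(0, 2, size=300))
        v = rng.normal(0, 1, size=300)
        lo, hi = 0.2, 1.5
        m = (t >= lo) & (t <= hi)
        tm, vm = t[m], v[m]
        oracle = sum(
            0.5 * (vm[i] + vm[i + 1]) * (tm[i + 1] - tm[i]) for i in range(len(tm) - 1)
        )
        assert sa.auc_of_curve(t, v, (lo, hi)) == pytest.approx(oracle, abs=1e-9)

    def test_zero_gain_unit_curve_is_flat(self, default_schedule):
        prof = fp.UnitResponseProfile(baseline_rate_hz=10.0)
        train = fp.simulate_unit(prof, default_schedule, seed=5)
        rates = sa.bin_rates(train, np.arange(0, 600.05, 0.1))
        stats = sa.baseline_stats(rates, (0.0, 600.0))
        trials = fp.trials_from_schedule(default_schedule, fp.EpochLabel.CS_PLUS)
        curve = sa.peristimulus_curve(train, trials, stats)
        ok = np.abs(curve.mean_z) <= 3 * curve.sem_z + 1e-9
        assert ok.mean() > 0.9  # pointwise 3-sem band, allow a few excursions

    def test_mixed_stimuli_rejected(self):
        train = fp.SpikeTrain("u", np.array([1.0]))
        trials = [
            fp.TrialWindow(0, fp.EpochLabel.CS_PLUS, 10.0, 10.0),
            fp.TrialWindow(0, fp.EpochLabel.CS_MINUS, 30.0, 10.0),
        ]
        with pytest.raises(ValidationError, match="mix"):
            sa.peristimulus_curve(train, trials, sa.BaselineStats(1.0, 1.0, 10, (0, 5)))


class TestConcatenatedChange:
    def test_rate_equal_to_baseline_is_zero_percent(self):
        spikes = np.arange(0.05, 10.0, 0.1)  # 10 Hz everywhere
        train = fp.SpikeTrain("u", spikes)
        trials = [fp.TrialWindow(0, fp.EpochLabel.CS_PLUS, 2.0, 4.0, include_iti=True)]
        stats = sa.BaselineStats(10.0, 1.0, 20, (0.0, 2.0))
        assert sa.concatenated_change(train, trials, stats) == pytest.approx(0.0)

    def test_doubled_rate_is_plus_100_percent(self):
        spikes = np.sort(np.concatenate([np.arange(0.05, 2.0, 0.1), np.arange(2.025, 6.0, 0.05)]))
        train = fp.SpikeTrain("u", spikes)
        trials = [fp.TrialWindow(0, fp.EpochLabel.CS_PLUS, 2.0, 4.0, include_iti=True)]
        stats = sa.BaselineStats(10.0, 1.0, 20, (0.0, 2.0))
        assert sa.concatenated_change(train, trials, stats) == pytest.approx(100.0, abs=1.0)

    def test_quadrature_predicted_change_on_simulated_unit(self):
        """Percent change over trial+ITI spans vs the rate-integral prediction."""
        from fearephys.simulate import rate_function

        cfg = fp.ScheduleConfig(n_cs_plus=2, n_cs_minus=0, baseline_duration_s=120.0,
                                iti_duration_s=20.0)
        sched = fp.generate_schedule(cfg, seed=0)
        prof = fp.UnitResponseProfile(
            6.0, {fp.EpochLabel.CS_PLUS: fp.StimulusResponse(3.0, "excite", 0.05, 0.05, 1.0)}
        )
        spans = fp.trials_from_schedule(sched, fp.EpochLabel.CS_PLUS, include_iti=True)
        grid = np.linspace(spans[0].onset_s, spans[-1].end_s, 200001)
        lam = rate_function(prof, sched, grid)
        from scipy.integrate import trapezoid
        total_t = sum(s.duration_s for s in spans)
        expected = 100.0 * (trapezoid(lam, grid) / total_t - 6.0) / 6.0
        stats = sa.BaselineStats(6.0, 1.0, 100, (0.0, 120.0))
        changes = [
            sa.concatenated_change(fp.simulate_unit(prof, sched, seed=s), spans, stats)
            for s in range(200)
        ]
        mc, se = np.mean(changes), np.std(changes, ddof=1) / math.sqrt(200)
        assert abs(mc - expected) < 3.5 * se

    def test_zero_baseline_flagged(self):
        train = fp.SpikeTrain("u", np.array([1.0]))
        trials = [fp.TrialWindow(0, fp.EpochLabel.CS_PLUS, 0.0, 2.0, include_iti=True)]
        with pytest.raises(UnclassifiableBaseline):
            sa.concatenated_change(train, trials, sa.BaselineStats(0.0, 0.0, 10, (0, 1)))


class TestLatency:
    def test_first_bin_crossing_is_zero(self):
        res = sa.response_latency(_z_trace([2.0, 0.0, 0.0], bin_s=0.02), 1.0, 0.06)
        assert res.latency_s == 0.0 and not res.censored

    def test_no_crossing_is_censored(self):
        res = sa.response_latency(_z_trace([0.0] * 25, bin_s=0.02), 1.0, 0.5)
        assert res.censored and res.latency_s is None

    def test_negative_threshold_downward_crossing(self):
        res = sa.response_latency(_z_trace([0.0, -0.7, 0.0], bin_s=0.02), -0.5, 0.06)
        assert res.latency_s == pytest.approx(0.02)

    def test_latency_shift_recovered_between_cohorts(self):
        """A +100 ms kernel-latency shift moves the median latency by ~100 ms.

        Uses a threshold well above the fine-bin baseline noise (trial-averaged
        20 ms bins fluctuate at ~0.7 of the 100 ms-bin S.D., so threshold 1
        would trip on noise before the response; 2.5 does not).
        """
        cfg = fp.ScheduleConfig(n_cs_plus=10, n_cs_minus=0, baseline_duration_s=120.0,
                                iti_duration_s=10.0)
        sched = fp.generate_schedule(cfg, seed=0)
        trials = fp.trials_from_schedule(sched, fp.EpochLabel.CS_PLUS)

        def median_latency(lat_shift, seed0):
            lats = []
            for s in range(50):
                prof = fp.UnitResponseProfile(
                    10.0,
                    {fp.EpochLabel.CS_PLUS: fp.StimulusResponse(
                        8.0, "excite", 0.05 + lat_shift, 0.02, 0.2)},
                )
                tr = fp.simulate_unit(prof, sched, seed=seed0 + s)
                rates = sa.bin_rates(tr, np.arange(0, 120.05, 0.1))
                stats = sa.baseline_stats(rates, (0.0, 120.0))
                fine = sa.peristimulus_curve(tr, trials, stats, pre_s=0.0, post_s=0.5, bin_s=0.02)
                edges = np.arange(0.0, 0.5 + 0.01, 0.02)
                z = sa.ZScoreTrace(edges, fine.mean_z, alignment="stimulus-locked")
                res = sa.response_latency(z, 2.5, 0.5)
                if not res.censored:
                    lats.append(res.latency_s)
            return np.median(lats)

        shift = median_latency(0.1, 1000) - median_latency(0.0, 2000)
        assert abs(shift - 0.1) <= 0.02 + 1e-9  # within one latency bin


class TestLatencyCdf:
    def test_hand_ecdf(self):
        cdf = sa.latency_cdf([0.1, 0.2, 0.2, 0.4])
        np.testing.assert_allclose(cdf.support, [0.1, 0.2, 0.4])
        np.testing.assert_allclose(cdf.cumulative, [0.25, 0.75, 1.0])

    def test_single_value_steps_to_one(self):
        cdf = sa.latency_cdf([LatencyResult(0.3, False)])
        np.testing.assert_allclose(cdf.support, [0.3])
        np.testing.assert_allclose(cdf.cumulative, [1.0])

    def test_censored_counted_all_censored_rejected(self):
        cdf = sa.latency_cdf([LatencyResult(0.1, False), LatencyResult(None, True)])
        assert cdf.n_censored == 1 and cdf.n == 1
        with pytest.raises(ValidationError):
            sa.latency_cdf([LatencyResult(None, True)])

    def test_sort_count_oracle_on_random_values(self, rng):
        vals = rng.exponential(0.2, size=1000)
        cdf = sa.latency_cdf(list(vals))
        xs = rng.uniform(0, 1, size=200)
        oracle = np.array([(vals <= x).mean() for x in xs])
        np.testing.assert_allclose(cdf(xs), oracle, atol=1e-9)


class TestDiscriminationContrast:
    def _curves(self, csp_shift, seed, n_units=12):
        r = np.random.default_rng(seed)
        t = np.arange(-1.0, 2.0, 0.05) + 0.025
        csp, csm = [], []
        for i in range(n_units):
            base = r.normal(0, 1, size=(10, t.size))
            shift = np.where((t >= 0) & (t <= 1), csp_shift, 0.0)
            csp.append(sa.ResponseCurve(t, (base + shift).mean(0), base.std(0), 10, 0.0,
                                        (0, 1), base + shift, unit_id=f"u{i}"))
            base2 = r.normal(0, 1, size=(10, t.size))
            csm.append(sa.ResponseCurve(t, base2.mean(0), base2.std(0), 10, 0.0,
                                        (0, 1), base2, unit_id=f"u{i}"))
        return csp, csm

    def test_identical_curves_null(self):
        csp, _ = self._curves(0.0, 1)
        res = sa.discrimination_contrast(csp, csp, n_permutations=500, seed=0)
        assert res["mean_contrast"] == 0.0
        assert res["p_value"] > 0.99

    def test_shifted_curves_detected(self):
        csp, csm = self._curves(1.0, 2)
        res = sa.discrimination_contrast(csp, csm, n_permutations=1000, seed=0)
        assert res["mean_contrast"] > 0.5
        assert res["p_value"] < 0.05

    def test_no_matched_units_rejected(self):
        csp, csm = self._curves(0.0, 3, n_units=2)
        for c in csm:
            object.__setattr__(c, "unit_id", c.unit_id + "_other")
        with pytest.raises(ValidationError):
            sa.discrimination_contrast(csp, csm)


class TestPopulationSummary:
    def test_hand_tallied_proportions(self):
        rows = []
        labels = ["ACTIVATED"] * 5 + ["INHIBITED"] * 3 + ["NON_RESPONSIVE"] * 4
        for i, lab in enumerate(labels):
            rows.append({"unit_id": f"u{i}", "genotype": "CONTROL", "day": 1,
                         "stimulus": "US", "label": lab})
        out = sa.population_summary(pd.DataFrame(rows))
        assert len(out) == 1
        r = out.iloc[0]
        assert r["n_units"] == 12
        assert r["prop_activated"] == pytest.approx(5 / 12)
        assert r["prop_inhibited"] == pytest.approx(3 / 12)
        assert r["prop_non_responsive"] == pytest.approx(4 / 12)

    def test_counts_conserved_and_proportions_sum_to_one(self, three_day_schedules):
        spec = fp.CohortSpec(n_units=20, seed=9)
        trains, _ = fp.simulate_cohort(spec, three_day_schedules[:1])
        df = fp.analyze_cohort(trains, three_day_schedules[:1])
        out = sa.population_summary(df[["unit_id", "genotype", "day", "stimulus", "label"]])
        prop_cols = [c for c in out.columns if c.startswith("prop_")]
        n_cols = [c for c in out.columns if c.startswith("n_") and c != "n_units"]
        np.testing.assert_allclose(out[prop_cols].sum(axis=1), 1.0)
        assert (out[n_cols].sum(axis=1) == out["n_units"]).all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            sa.population_summary(pd.DataFrame())
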