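"""Resampling inference: permutation tests, bootstrap, t test, pooling."""

import numpy as np
import pytest

import ofr
from conftest import make_noise_traces
from ofr.kinematics import default_grid
from ofr.stats import invert_for_pooling


def labelled(rng, n_per, levels):
    labels = [{"delay_ms": lev} for lev in levels for _ in range(n_per)]
    return make_noise_traces(rng, labels)


class TestRandomizationSlopeTest:
    def test_reproducible_null(self):
        rng = np.random.default_rng(0)
        traces = labelled(rng, 5, [10, 50, 100])
        kw = dict(response="window_speed", n_shuffles=99, seed=7, window_start=60.0)
        a = ofr.randomization_slope_test(traces, "delay_ms", **kw)
        b = ofr.randomization_slope_test(traces, "delay_ms", **kw)
        assert np.array_equal(a.null_values, b.null_values)
        assert a.p_value == b.p_value
        assert 0 < a.p_value <= 1

    def test_identical_condition_means_slope_zero(self):
        """Responses constructed identical across levels: empirical slope 0
        and p ~ 1."""
        grid = default_grid()
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, len(grid))
        traces = []
        for tid, lev in enumerate([10, 50, 100, 300] * 4):
            v = base.copy()
            traces.append(
                ofr.VelocityTrace(tid, grid, v, v, v, np.ones(len(grid), bool),
                                  {"delay_ms": lev})
            )
        res = ofr.randomization_slope_test(
            traces, "delay_ms", response="window_speed", n_shuffles=99, seed=0,
            window_start=60.0,
        )
        assert res.empirical_value == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_type_i_error_calibrated(self):
        """Pure-noise responses: rejection rate at alpha = 0.05 in [0.03, 0.07]."""
        rng = np.random.default_rng(42)
        rej = 0
        n_datasets = 400
        for i in range(n_datasets):
            traces = labelled(rng, 5, [10, 30, 50, 100, 200, 300])
            res = ofr.randomization_slope_test(
                traces, "delay_ms", response="window_speed", n_shuffles=199,
                seed=1000 + i, window_start=60.0,
            )
            rej += res.p_value <= 0.05
        assert 0.03 <= rej / n_datasets <= 0.07

    def test_detects_planted_slope(self):
        grid = default_grid()
        rng = np.random.default_rng(3)
        traces = []
        for tid in range(120):
            lev = [10, 30, 50, 100, 200, 300][tid % 6]
            v = rng.normal(0, 0.3, len(grid)) + 0.01 * lev
            traces.append(
                ofr.VelocityTrace(tid, grid, v, v, v, np.ones(len(grid), bool),
                                  {"delay_ms": lev})
            )
        res = ofr.randomization_slope_test(
            traces, "delay_ms", response="window_speed", n_shuffles=199, seed=1,
            window_start=60.0,
        )
        assert res.empirical_value == pytest.approx(0.01, abs=0.002)
        assert res.p_value == pytest.approx(1 / 200)

    def test_latency_response_on_synthetic_ramps(self):
        """Latency slope test recovers a planted latency-delay dependence."""
        grid = default_grid()
        rng = np.random.default_rng(4)
        traces = []
        for tid in range(90):
            lev = [10.0, 100.0, 300.0][tid % 3]
            c = 50.0 + 0.05 * lev
            v = 0.06 * np.maximum(grid - c, 0.0) + rng.normal(0, 0.5, len(grid))
            traces.append(
                ofr.VelocityTrace(tid, grid, v, v, v, np.ones(len(grid), bool),
                                  {"delay_ms": lev})
            )
        res = ofr.randomization_slope_test(
            traces, "delay_ms", response="latency", n_shuffles=99, seed=2
        )
        assert res.empirical_value == pytest.approx(0.05, abs=0.02)
        assert res.p_value <= 0.05

    def test_preconditions(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="2 condition levels"):
            ofr.randomization_slope_test(labelled(rng, 4, [10]), "delay_ms",
                                         response="window_speed", window_start=60.0)
        with pytest.raises(ValueError, match="2 trials per"):
            ofr.randomization_slope_test(labelled(rng, 1, [10, 50]), "delay_ms",
                                         response="window_speed", window_start=60.0)
        with pytest.raises(ValueError, match="unknown response"):
            ofr.randomization_slope_test(labelled(rng, 3, [10, 50]), "delay_ms",
                                         response="gain")


class TestLatencyDifferenceTest:
    def test_same_trials_zero_difference(self):
        grid = default_grid()
        rng = np.random.default_rng(5)
        v0 = 0.06 * np.maximum(grid - 60.0, 0.0)
        traces = []
        for tid in range(20):
            v = v0 + rng.normal(0, 0.2, len(grid))
            traces.append(
                ofr.VelocityTrace(tid, grid, v, v, v, np.ones(len(grid), bool), {})
            )
        # duplicate the same trials into both groups
        both = traces + traces
        in_a = np.array([True] * 20 + [False] * 20)
        res = ofr.randomization_latency_difference_test(both, in_a, n_shuffles=49,
                                                        seed=0)
        assert res.empirical_value == pytest.approx(0.0, abs=1e-9)

    def test_p_uniform_under_null(self):
        """Groups drawn from one population: p values roughly uniform."""
        grid = default_grid()
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(60):
            traces = []
            for tid in range(24):
                v = 0.06 * np.maximum(grid - 60.0, 0.0) + rng.normal(0, 0.4, len(grid))
                traces.append(
                    ofr.VelocityTrace(tid, grid, v, v, v,
                                      np.ones(len(grid), bool), {})
                )
            in_a = np.arange(24) < 12
            res = ofr.randomization_latency_difference_test(
                traces, in_a, n_shuffles=39, seed=rep
            )
            ps.append(res.p_value)
        ps = np.array(ps)
        # coarse uniformity: mean near 0.5 and no pile-up below 0.05
        assert 0.35 <= ps.mean() <= 0.65
        assert np.mean(ps <= 0.05) <= 0.12

    def test_group_validation(self):
        grid = default_grid()
        tr = ofr.VelocityTrace(0, grid, grid * 0, grid * 0, grid * 0,
                               np.ones(len(grid), bool), {})
        with pytest.raises(ValueError, match="non-empty"):
            ofr.randomization_latency_difference_test([tr, tr], [True, True])


class TestBootstrap:
    def test_identical_values_zero(self):
        assert ofr.bootstrap_sd_of_mean([2.0] * 20, seed=0) == 0.0

    def test_matches_analytic_se(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10_000)
        sd = ofr.bootstrap_sd_of_mean(x, n_boot=1000, seed=1)
        analytic = x.std(ddof=1) / np.sqrt(len(x))
        assert sd == pytest.approx(analytic, rel=0.10)

    def test_converges_with_many_resamples(self):
        """At n_boot = 1e5 the bootstrap SD matches s/sqrt(n) within 2%."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3, 400)
        sd = ofr.bootstrap_sd_of_mean(x, n_boot=100_000, seed=3)
        assert sd == pytest.approx(x.std(ddof=1) / 20.0, rel=0.02)

    def test_needs_two_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            ofr.bootstrap_sd_of_mean([1.0])


class TestTwoSampleT:
    def test_identical_samples(self):
        out = ofr.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0 and out["p"] == 1.0
        assert out["df"] == 4

    def test_df_definition(self):
        rng = np.random.default_rng(0)
        out = ofr.two_sample_t(rng.normal(size=32), rng.normal(size=32))
        assert out["df"] == 62

    def test_power_at_one_sd_separation(self):
        """n = 32 per group, 1-SD mean separation: power exceeds 95% at
        alpha = 0.05 (closed-form noncentral-t check)."""
        from scipy import stats as sps
        n = 32
        ncp = 1.0 / np.sqrt(2.0 / n)
        crit = sps.t.ppf(0.975, 2 * n - 2)
        power = sps.nct.sf(crit, 2 * n - 2, ncp) + sps.nct.cdf(-crit, 2 * n - 2, ncp)
        assert power > 0.95
        # empirical agreement
        rng = np.random.default_rng(1)
        rej = sum(
            ofr.two_sample_t(rng.normal(1, 1, n), rng.normal(0, 1, n))["p"] < 0.05
            for _ in range(300)
        )
        assert rej / 300 == pytest.approx(power, abs=0.06)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            ofr.two_sample_t([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="at least 2"):
            ofr.two_sample_t([1.0], [1.0, 2.0])


class TestPoolDirections:
    def _trace(self, sacc, stim, vx=0.0, vy=0.0, tid=0):
        grid = default_grid()
        z = np.zeros(len(grid))
        return ofr.VelocityTrace(
            tid, grid, z + vx, z + vy, z, np.ones(len(grid), bool),
            {"saccade_dir_deg": sacc, "stim_dir_deg": stim},
        )

    def test_sign_inversion_180(self):
        tr = self._trace(180.0, 180.0, vx=-4.0)
        out = invert_for_pooling(tr)
        assert np.allclose(out.vx, 4.0)
        assert np.allclose(out.vy, tr.vy)

    def test_involution(self):
        tr = self._trace(270.0, 270.0, vx=1.0, vy=-2.0)
        twice = invert_for_pooling(invert_for_pooling(tr))
        assert np.array_equal(twice.vx, tr.vx) and np.array_equal(twice.vy, tr.vy)

    def test_collapses_to_two_groups_per_axis(self):
        trials = []
        tid = 0
        for sacc in (0.0, 90.0, 180.0, 270.0):
            for rel in ("identical", "opposite"):
                stim = sacc if rel == "identical" else (sacc + 180.0) % 360.0
                for _ in range(3):
                    trials.append(self._trace(sacc, stim, tid=tid))
                    tid += 1
        pooled = ofr.pool_directions(trials)
        for axis in ("horizontal", "vertical"):
            assert len(pooled[axis]["identical"]) == 6
            assert len(pooled[axis]["opposite"]) == 6

    def test_congruence_gain_recovered_from_generator(self):
        """Pooling a noiseless congruence session: identical-group mean speed
        equals congruence_factor times the opposite-group mean."""
        truth = ofr.GroundTruth(noise_sd=0.0, congruence_factor=1.3)
        design = ofr.make_design("direction", 1, seed=0)
        traces = [ofr.savgol_velocity(t) for t in ofr.simulate_session(design, truth, 0)]
        pooled = ofr.pool_directions(traces)
        for axis, comp in (("horizontal", "horizontal"), ("vertical", "vertical")):
            m = {
                rel: np.mean([
                    ofr.window_mean_speed(tr, 100.0, 40.0, component=comp)
                    for tr in pooled[axis][rel]
                ])
                for rel in ("identical", "opposite")
            }
            assert m["identical"] / m["opposite"] == pytest.approx(1.3, rel=1e-6)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ofr.pool_directions([self._trace(0.0, 45.0)])
        with pytest.raises(ValueError, match="different axes"):
            ofr.pool_directions([self._trace(90.0, 0.0)])
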