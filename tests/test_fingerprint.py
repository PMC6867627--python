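"""Motility parameters: dwell-time fits, v_run, P_run, q, comparisons."""

import numpy as np
import pandas as pd
import pytest

import ringlane as rl
from ringlane.fingerprint import DwellTimeSample, fit_tau_from_sample
from ringlane.segmentation import REST, RUN

from conftest import make_segments


class TestRunVelocity:
    def vel(self, v):
        v = np.asarray(v, dtype=float)
        return rl.VelocitySeries("c", np.arange(len(v)) / 6.0, v)

    def segs_all_run(self, n):
        seg = rl.StateSegment(RUN, 0.0, n / 6.0, 1, 0, n - 1, True, True)
        return [seg]

    def test_constant_velocity(self):
        assert rl.run_velocity(self.vel(np.full(10, 20.0)), self.segs_all_run(10)) == 20.0

    def test_sign_invariance(self):
        v = np.tile([20.0, -20.0], 5)
        assert rl.run_velocity(self.vel(v), self.segs_all_run(10)) == 20.0

    def test_no_run_frames_undefined(self):
        seg = rl.StateSegment(REST, 0.0, 1.0, 0, 0, 9, True, True)
        assert np.isnan(rl.run_velocity(self.vel(np.zeros(10)), [seg]))

    def test_population_estimate_tracks_true_speeds(self):
        params = rl.ctrl_like(n_cells=200, immobile_fraction_true=0.0, seed=5)
        coll, truth = rl.simulate_population(params)
        result = rl.fingerprint(coll)
        true_mean = np.mean(
            [
                np.mean(
                    np.abs(coll.geometry.radius * np.diff(t.phi) / params.dt)[
                        truth.cells[t.cell_id].frame_is_run[:-1]
                    ]
                )
                for t in coll
            ]
        )
        assert result.fingerprint.v_run == pytest.approx(true_mean, rel=0.10)


class TestCollectDwellTimes:
    def test_start_rule(self):
        # 48 h track; RUN segments starting at 1, 20 and 35 h
        segs = make_segments(
            [
                (REST, 1.0, 0), (RUN, 7.0, 1), (REST, 12.0, 0),
                (RUN, 8.0, 1), (REST, 7.0, 0), (RUN, 5.0, 1), (REST, 8.0, 0),
            ]
        )
        sample = rl.collect_dwell_times({"c": segs}, censor_horizon=16.0)
        assert sample[RUN].n == 2  # 48 - 35 = 13 < 16 excludes the third
        assert sample[RUN].durations == pytest.approx([7.0, 8.0])

    def test_short_track_yields_nothing(self):
        segs = make_segments([(REST, 5.0, 0), (RUN, 7.0, 1)])
        sample = rl.collect_dwell_times({"c": segs}, censor_horizon=16.0)
        assert sample[RUN].n == 0 and sample[REST].n == 0

    def test_ongoing_state_censored(self):
        segs = make_segments([(RUN, 30.0, 1), (REST, 18.0, 0)])
        sample = rl.collect_dwell_times({"c": segs})
        assert sample[RUN].censored.tolist() == [False]
        assert sample[REST].censored.tolist() == [True]

    def test_censored_sample_matches_exponential_survival(self):
        # true dwell durations from the simulator, censor rule applied,
        # compared against the exponential the simulator draws from
        params = rl.ctrl_like(n_cells=300, immobile_fraction_true=0.0, seed=3)
        coll, truth = rl.simulate_population(params)
        by_cell = {}
        for cid, gt in truth.cells.items():
            spans = [
                (lab, dur, 1 if lab == RUN else 0)
                for lab, dur in zip(gt.segment_labels, gt.segment_durations)
            ]
            by_cell[cid] = make_segments(spans)
        sample = rl.collect_dwell_times(by_cell)[RUN]
        t, s = rl.survival_function(sample, dt=params.dt)
        expected = np.exp(-t / params.tau_run)
        n = sample.n
        binom_3sd = 3.0 * np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(s - expected) <= binom_3sd + 3.0 / n)


class TestSurvivalFunction:
    def test_counting(self):
        sample = DwellTimeSample(RUN, np.array([1.0, 2.0, 3.0]), np.zeros(3, bool))
        t, s = rl.survival_function(sample, dt=0.5, horizon=4.0)
        lookup = dict(zip(t.round(3), s))
        assert lookup[0.0] == 1.0
        assert lookup[1.5] == pytest.approx(2 / 3)
        assert lookup[2.5] == pytest.approx(1 / 3)
        assert lookup[3.5] == 0.0

    def test_equal_durations_step(self):
        sample = DwellTimeSample(RUN, np.full(7, 5.0), np.zeros(7, bool))
        t, s = rl.survival_function(sample, dt=1.0, horizon=8.0)
        assert np.all(s[t < 5.0] == 1.0)
        assert np.all(s[t >= 5.0] == 0.0)

    def test_glivenko_cantelli(self, rng):
        draws = rng.exponential(3.0, 5000)
        sample = DwellTimeSample(RUN, draws, np.zeros(5000, bool))
        t, s = rl.survival_function(sample, dt=1.0 / 6.0)
        assert np.max(np.abs(s - np.exp(-t / 3.0))) < 0.02

    def test_empty_sample_rejected(self):
        sample = DwellTimeSample(RUN, np.array([]), np.array([], bool))
        with pytest.raises(rl.EstimationError):
            rl.survival_function(sample, dt=0.5)


class TestFitTau:
    @pytest.mark.parametrize("tau", [1.0, 4.0, 10.0])
    @pytest.mark.parametrize("offset", [1.0, 0.8])
    def test_exact_exponential_recovered(self, tau, offset):
        t = np.arange(0.0, 16.01, 1.0 / 6.0)
        fit = rl.fit_tau(t, offset * np.exp(-t / tau))
        assert fit.tau == pytest.approx(tau, rel=1e-9)
        assert fit.intercept == pytest.approx(np.log(offset), abs=1e-9)
        assert fit.ci99_low <= fit.tau <= fit.ci99_high

    def test_monte_carlo_pipeline(self, rng):
        draws = rng.exponential(3.0, 5000)
        sample = DwellTimeSample(RUN, draws, np.zeros(5000, bool))
        fit = fit_tau_from_sample(sample, dt=1.0 / 6.0)
        assert 2.8 <= fit.tau <= 3.2

    def test_bootstrap_ci_brackets_replicate_spread(self):
        # the CI should have the scale of the estimator's sampling spread
        estimates = []
        for seed in range(12):
            d = np.random.default_rng(seed).exponential(3.0, 800)
            s = DwellTimeSample(RUN, d, np.zeros(800, bool))
            estimates.append(fit_tau_from_sample(s, dt=1.0 / 6.0).tau)
        spread = np.std(estimates)
        d = np.random.default_rng(99).exponential(3.0, 800)
        fit = fit_tau_from_sample(DwellTimeSample(RUN, d, np.zeros(800, bool)), dt=1.0 / 6.0)
        half_width = (fit.ci99_high - fit.ci99_low) / 2.0
        assert 1.0 * spread < half_width < 6.0 * spread

    def test_too_few_points(self):
        t = np.array([0.0, 2.0, 3.0])
        with pytest.raises(rl.FitError):
            rl.fit_tau(t, np.array([1.0, 0.5, 0.0]))

    def test_non_decaying_rejected(self):
        t = np.arange(0.0, 16.01, 1.0)
        with pytest.raises(rl.DegenerateFitError):
            rl.fit_tau(t, np.full(len(t), 0.5))


class TestRunFraction:
    def test_three_quarters(self):
        segs = make_segments([(RUN, 6.0, 1), (REST, 2.0, 0)])
        assert rl.run_fraction(segs) == pytest.approx(0.75)

    def test_all_rest(self):
        segs = make_segments([(REST, 10.0, 0)])
        assert rl.run_fraction(segs) == 0.0


class TestPersistenceQ:
    def traj(self, phi):
        phi = np.asarray(phi, dtype=float)
        return rl.Trajectory("c", np.arange(len(phi)) / 6.0, phi)

    def test_monotone_is_one(self):
        assert rl.persistence_q(self.traj(np.linspace(0, 3, 40))) == pytest.approx(1.0, abs=1e-15)

    def test_out_and_back_is_half(self):
        phi = np.concatenate([np.linspace(0, 2, 20), np.linspace(2, 0, 20)[1:]])
        assert rl.persistence_q(self.traj(phi)) == pytest.approx(0.5)

    def test_zero_path_undefined(self):
        assert np.isnan(rl.persistence_q(self.traj(np.zeros(5))))

    def test_matches_brute_force_on_random_walks(self, rng):
        for _ in range(50):
            steps = rng.choice([-0.01, 0.01], size=1000)
            phi = np.concatenate([[0.0], np.cumsum(steps)])
            q = rl.persistence_q(self.traj(phi))
            rng_len = max(phi) - min(phi)
            path = sum(abs(phi[i + 1] - phi[i]) for i in range(len(phi) - 1))
            assert q == pytest.approx(rng_len / path, abs=1e-12)
            assert 0.0 <= q <= 1.0


class TestImmobileFraction:
    def test_counts_single_rest_cells(self):
        by_cell = {f"m{i}": make_segments([(RUN, 5.0, 1), (REST, 3.0, 0)]) for i in range(7)}
        for i in range(3):
            by_cell[f"s{i}"] = make_segments([(REST, 8.0, 0)])
        assert rl.immobile_fraction(by_cell) == pytest.approx(0.3)

    def test_zero_when_everyone_runs(self):
        by_cell = {f"m{i}": make_segments([(REST, 1.0, 0), (RUN, 5.0, 1)]) for i in range(4)}
        assert rl.immobile_fraction(by_cell) == 0.0

    def test_recovered_from_simulation(self):
        params = rl.ctrl_like(n_cells=300, immobile_fraction_true=0.2, seed=21)
        coll, truth = rl.simulate_population(params)
        result = rl.fingerprint(coll)
        assert result.fingerprint.immobile_fraction == pytest.approx(0.2, abs=0.05)


class TestFingerprint:
    def test_single_cell_rejected(self, geometry):
        t = rl.Trajectory("a", np.arange(10) / 6.0, np.linspace(0, 1, 10))
        coll = rl.TrajectoryCollection([t], geometry)
        with pytest.raises(rl.EstimationError):
            rl.fingerprint(coll)

    def test_p_run_and_rest_fraction_sum_to_one(self, small_population):
        coll, _ = small_population
        result = rl.fingerprint(coll)
        for cell_id, segs in result.segments.items():
            total = segs[-1].end - segs[0].start
            rest_time = sum(s.duration for s in segs if s.label == REST)
            p_run = result.per_cell.set_index("cell_id").loc[cell_id, "p_run"]
            assert p_run + rest_time / total == pytest.approx(1.0)

    def test_disjoint_halves_agree(self):
        params = rl.ctrl_like(n_cells=200, seed=8)
        coll, _ = rl.simulate_population(params)
        half = len(coll) // 2
        geo = coll.geometry
        a = rl.fingerprint(rl.TrajectoryCollection(coll.trajectories[:half], geo))
        b = rl.fingerprint(rl.TrajectoryCollection(coll.trajectories[half:], geo))
        for param, se in [("v_run", "v_run_se"), ("p_run", "p_run_se"), ("q", "q_se")]:
            fa, fb = a.fingerprint, b.fingerprint
            combined = np.hypot(getattr(fa, se), getattr(fb, se))
            assert abs(getattr(fa, param) - getattr(fb, param)) < 2.0 * combined

    def test_mirror_invariance_of_estimators(self, small_population):
        coll, _ = small_population
        mirrored = rl.TrajectoryCollection(
            [rl.Trajectory(t.cell_id, t.times, -t.phi) for t in coll], coll.geometry
        )
        a = rl.fingerprint(coll).fingerprint
        b = rl.fingerprint(mirrored).fingerprint
        assert a.v_run == pytest.approx(b.v_run)
        assert a.p_run == pytest.approx(b.p_run)
        assert a.q == pytest.approx(b.q)

    def test_to_dict_shape(self, small_population):
        coll, _ = small_population
        d = rl.fingerprint(coll).fingerprint.to_dict()
        for key in ("v_run", "tau_run", "tau_rest", "p_run", "q", "immobile_fraction"):
            assert {"value", "error_low", "error_high", "n"} <= set(d[key])


class TestCompare:
    def per_cell(self, rng, n=40, shift=0.0):
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "v_run": rng.normal(30 + shift, 5, n),
                "p_run": np.clip(rng.normal(0.5 + shift / 100, 0.1, n), 0, 1),
                "q": np.clip(rng.normal(0.5, 0.1, n), 0, 1),
            }
        )

    def test_identical_groups(self, rng):
        a = self.per_cell(rng)
        res = rl.compare_fingerprints(a, a.copy())
        for param in ("v_run", "p_run", "q"):
            assert res[param].diff == 0.0
            assert res[param].pvalue == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        a = pd.DataFrame({"v_run": [1.0] * 5, "p_run": [0.5] * 5, "q": [0.5] * 5})
        with pytest.raises(rl.EstimationError):
            rl.compare_fingerprints(a, a.copy())

    def test_shifted_groups_detected(self, rng):
        a = self.per_cell(rng, n=100)
        b = self.per_cell(rng, n=100, shift=-10.0)
        res = rl.compare_fingerprints(a, b)
        assert res["v_run"].pvalue < 0.05 and res["v_run"].diff > 0


class TestSpiderTable:
    def test_reference_normalizes_to_one(self, small_population):
        coll, _ = small_population
        fp = rl.fingerprint(coll).fingerprint
        table = rl.spider_table({"ctrl": fp, "other": fp}, reference="ctrl")
        ref_rows = table[table.condition == "ctrl"]
        assert np.allclose(ref_rows.normalized, 1.0)
        assert set(table.parameter) == {"v_run", "tau_run", "tau_rest", "p_run", "q"}
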