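import dataclasses
import math

import numpy as np
import pytest

import cleftsim.simulate as sim_mod
from cleftsim import (
    AnalyticFPT,
    WallParams,
    em_step,
    make_cleft_params,
    occupancy_below,
    sample_trajectory,
    simulate_fpt,
    simulate_paired,
)
from cleftsim.params import SimConfig


class TestEmStep:
    def test_no_noise_no_force_is_identity(self, cleft, wall_off):
        p = make_cleft_params(d=cleft.d, D=cleft.D, V=0.0, T=cleft.T)
        assert em_step(5e-9, p, wall_off, 1e-8, 0.0) == 5e-9

    def test_deterministic_part_is_drift(self, cleft, wall_off):
        # one 10 ns step advances by v_drift * dt ~ 2.47e-11 m
        x1 = em_step(5e-9, cleft, wall_off, 1e-8, 0.0)
        assert x1 - 5e-9 == pytest.approx(cleft.v_drift * 1e-8, rel=1e-12)
        assert x1 - 5e-9 == pytest.approx(2.47e-11, rel=1e-3)

    def test_noise_variance_is_2Ddt(self, cleft, wall_off):
        p = make_cleft_params(d=cleft.d, D=cleft.D, V=0.0, T=cleft.T)
        rng = np.random.default_rng(2)
        z = rng.standard_normal(1_000_000)
        dx = em_step(0.0, p, wall_off, 1e-8, z)
        assert np.var(dx) == pytest.approx(2 * p.D * 1e-8, rel=1e-2)


class TestSimulateFPT:
    def test_bit_identical_reruns(self, cleft, wall):
        cfg = SimConfig(n_runs=300, seed=99)
        s1 = simulate_fpt(cleft, wall, cfg)
        s2 = simulate_fpt(cleft, wall, cfg)
        np.testing.assert_array_equal(s1.times_by_run, s2.times_by_run)
        assert s1.params_fingerprint == s2.params_fingerprint

    def test_results_independent_of_chunk_size(self, cleft, wall, monkeypatch):
        cfg = SimConfig(n_runs=300, seed=99)
        ref = simulate_fpt(cleft, wall, cfg)
        monkeypatch.setattr(sim_mod, "_RUN_CHUNK", 37)
        monkeypatch.setattr(sim_mod, "_NOISE_BLOCK", 11)
        alt = simulate_fpt(cleft, wall, cfg)
        np.testing.assert_array_equal(ref.times_by_run, alt.times_by_run)

    def test_sample_bookkeeping(self, cleft, wall):
        cfg = SimConfig(n_runs=400, seed=5)
        s = simulate_fpt(cleft, wall, cfg)
        assert len(s.times) + s.n_censored == cfg.n_runs
        assert np.all(s.times >= cfg.dt) and np.all(s.times <= cfg.t_max)

    def test_censoring_counted_and_warned(self, cleft, wall, caplog):
        # a horizon of a few steps censors nearly everything
        cfg = SimConfig(n_runs=50, seed=5, t_max=5e-8)
        with caplog.at_level("WARNING"):
            s = simulate_fpt(cleft, wall, cfg)
        assert s.n_censored > 25
        assert any("t_max" in r.message for r in caplog.records)

    def test_faster_diffusion_shortens_passage(self, cleft, wall):
        cfg = SimConfig(n_runs=400, seed=8)
        fast = make_cleft_params(d=cleft.d, D=100 * cleft.D, V=cleft.V, T=cleft.T)
        s_def = simulate_fpt(cleft, wall, cfg)
        s_fast = simulate_fpt(fast, wall, cfg)
        assert s_fast.mean < s_def.mean

    def test_wall_free_mean_matches_quadrature_oracle(self, cleft, wall_off):
        # oracle: quadrature mean of the closed-form law, d/v; a finer
        # step keeps the boundary-overshoot bias inside the tolerance
        from cleftsim.analytic import fpt_moments

        cfg = SimConfig(n_runs=4000, seed=21, dt=2e-9, interpolate_crossing=True)
        s = simulate_fpt(cleft, wall_off, cfg)
        _, mean_oracle, _ = fpt_moments(AnalyticFPT.from_cleft(cleft))
        assert s.n_censored == 0
        assert s.mean == pytest.approx(mean_oracle, rel=0.15)

    def test_interpolated_times_bounded_by_step_end(self, cleft, wall_off):
        cfg = SimConfig(n_runs=200, seed=33, interpolate_crossing=True)
        cfg_plain = dataclasses.replace(cfg, interpolate_crossing=False)
        ti = simulate_fpt(cleft, wall_off, cfg).times_by_run
        te = simulate_fpt(cleft, wall_off, cfg_plain).times_by_run
        ok = np.isfinite(ti) & np.isfinite(te)
        assert np.all(ti[ok] <= te[ok])
        assert np.all(te[ok] - ti[ok] < cfg.dt)


class TestSimulatePaired:
    def test_shared_noise_hook_gives_zero_deltas(self, cleft, wall):
        cfg = SimConfig(n_runs=200, seed=13)
        res = simulate_paired(cleft, cleft, wall, wall, cfg, shared_noise=True)
        assert np.all(res.delta_times == 0.0)

    def test_symmetric_null_mean(self, cleft, wall):
        cfg = SimConfig(n_runs=3000, seed=17, dt=2e-9)
        res = simulate_paired(cleft, cleft, wall, wall, cfg)
        mean, std, _ = res.summary
        assert abs(mean) < 3 * std / math.sqrt(len(res.delta_times))

    def test_slower_cleft_arrives_later_on_average(self, cleft, wall_off):
        slow = make_cleft_params(d=cleft.d, D=cleft.D / 10, V=cleft.V, T=cleft.T)
        cfg = SimConfig(n_runs=800, seed=5)
        res = simulate_paired(slow, cleft, wall_off, wall_off, cfg)
        # cleft 1 slower (smaller D) => t1 - t2 > 0; sign cross-checked
        # against the closed-form means d/v: 81 us vs 8.1 us
        mu1 = AnalyticFPT.from_cleft(slow).mu
        mu2 = AnalyticFPT.from_cleft(cleft).mu
        assert mu1 > mu2
        assert np.mean(res.delta_times) > 0

    def test_exchangeability_mirrors_distribution(self, cleft, wall_off):
        slow = make_cleft_params(d=cleft.d, D=cleft.D / 3, V=cleft.V, T=cleft.T)
        cfg = SimConfig(n_runs=2000, seed=29)
        fwd = simulate_paired(slow, cleft, wall_off, wall_off, cfg)
        rev = simulate_paired(cleft, slow, wall_off, wall_off, cfg)
        m_f, s_f, _ = fwd.summary
        m_r, s_r, _ = rev.summary
        se = math.hypot(s_f / math.sqrt(len(fwd.delta_times)),
                        s_r / math.sqrt(len(rev.delta_times)))
        assert abs(m_f + m_r) < 4 * se
        assert s_f / s_r == pytest.approx(1.0, rel=0.2)

    def test_censored_pairs_excluded_and_counted(self, cleft, wall):
        cfg = SimConfig(n_runs=100, seed=3, t_max=2e-7)
        res = simulate_paired(cleft, cleft, wall, wall, cfg)
        assert len(res.delta_times) + res.n_pairs_censored == cfg.n_runs
        assert res.n_pairs_censored > 0


class TestTrajectoriesAndConfinement:
    def test_single_trajectory_reaches_boundary(self, cleft, wall):
        cfg = SimConfig(n_runs=1, seed=41)
        t, x = sample_trajectory(cleft, wall, cfg)
        assert x[0] == cfg.x_start
        assert x[-1] >= cleft.d
        assert len(t) == len(x)
        # the recorded batch time for the same run matches the path length
        s = simulate_fpt(cleft, wall, cfg)
        assert s.times_by_run[0] == pytest.approx((len(x) - 1) * cfg.dt)

    def test_wall_confines_particle_to_cleft(self, cleft, wall, wall_off):
        # in the wall-resolved regime the time fraction spent behind the
        # wall (x < -2 x0) is < 1e-3, against ~0.9 for the free walk
        cfg = SimConfig(n_runs=400, seed=17, dt=1e-9)
        frac_on = occupancy_below(cleft, wall, cfg, threshold=-2 * wall.x0)
        assert frac_on < 1e-3
        cfg_free = SimConfig(n_runs=150, seed=17, dt=1e-9)
        frac_off = occupancy_below(cleft, wall_off, cfg_free, threshold=-2 * wall.x0)
        assert frac_off > 0.5
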