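import math

import numpy as np
import pytest

import larvaforage as lf
from larvaforage.simulator import CRAWL, PAUSE, TURN


def _params(mean_v=0.84, sd_v=0.13, pt=0.044, pp=0.0083):
    return lf.SubstrateParams(mean_v=mean_v, sd_v=sd_v, p_turn_per_s=pt, p_pause_per_s=pp)


def _homog_config(params, **kw):
    layout = lf.PatchLayout(outside_substrate="agar")
    defaults = dict(
        layout=layout,
        params_by_substrate={"agar": params},
        turn_model=lf.TurnAngleModel(mu=0.0, kappa=1.0),
        start_point=(120.0, 120.0),
        n_steps=1000,
    )
    defaults.update(kw)
    return lf.SimConfig(**defaults)


class TestStepState:
    def test_all_crawl(self, rng):
        p = _params(pt=0.0, pp=0.0)
        assert all(lf.step_state(p, 0.5, rng) == "crawl" for _ in range(100))

    def test_certain_pause(self, rng):
        p = _params(pt=0.0, pp=2.0)  # 2/s * 0.5 s = probability 1
        assert all(lf.step_state(p, 0.5, rng) == "pause" for _ in range(100))

    def test_overflow_rejected(self, rng):
        p = _params(pt=1.5, pp=1.0)
        with pytest.raises(lf.ConfigurationError):
            lf.step_state(p, 0.5, rng)

    def test_turn_frequency_matches_binomial(self, rng):
        p = _params()  # rover-agar
        n = 200_000
        turns = sum(lf.step_state(p, 0.5, rng) == "turn" for _ in range(n))
        expected = 0.044 * 0.5
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(turns / n - expected) < 3 * se


class TestSampleSpeed:
    def test_degenerate_sd(self, rng):
        p = _params(sd_v=0.0)
        assert lf.sample_speed(p, rng) == 0.84

    def test_always_positive(self):
        rng = np.random.default_rng(0)
        p = _params(mean_v=0.1, sd_v=0.5)  # heavy truncation regime
        assert all(lf.sample_speed(p, rng) > 0 for _ in range(2000))

    def test_mean_recovered(self, rng):
        p = _params()  # mean/sd = 6.5: truncation shift < 1e-3
        n = 100_000
        xs = np.array([lf.sample_speed(p, rng) for _ in range(n)])
        se = 0.13 / math.sqrt(n)
        assert abs(xs.mean() - 0.84) < 3 * se + 1e-3


class TestSampleTurnAngle:
    def test_degenerate_concentration(self, rng):
        m = lf.TurnAngleModel(mu=0.7, kappa=1e6)
        xs = [lf.sample_turn_angle(m, rng) for _ in range(500)]
        assert np.allclose(xs, 0.7, atol=0.01)

    def test_range(self, rng):
        m = lf.TurnAngleModel(mu=2.5, kappa=0.3)
        xs = np.array([lf.sample_turn_angle(m, rng) for _ in range(5000)])
        assert np.all(xs >= -math.pi) and np.all(xs <= math.pi)

    def test_kappa_zero_is_circular_uniform(self, rng):
        n = 10_000
        xs = np.array([lf.sample_turn_angle(lf.TurnAngleModel(0.0, 0.0), rng) for _ in range(n)])
        # Rayleigh test: z = n * Rbar^2; under uniformity P(z > 3) ~ 5%
        rbar = math.hypot(np.cos(xs).mean(), np.sin(xs).mean())
        z = n * rbar**2
        assert z < 5.0  # fails to reject uniformity

    def test_circular_mean(self, rng):
        n = 100_000
        m = lf.TurnAngleModel(mu=0.5, kappa=2.0)
        xs = np.array([lf.sample_turn_angle(m, rng) for _ in range(n)])
        mean_dir = math.atan2(np.sin(xs).mean(), np.cos(xs).mean())
        rbar = math.hypot(np.cos(xs).mean(), np.sin(xs).mean())
        se = 1.0 / math.sqrt(n * rbar * 2.0)  # circular SE with kappa = 2
        assert abs(mean_dir - 0.5) < 3 * se


class TestChooseTurnDirection:
    def test_forced_inward(self, two_patches):
        rng = np.random.default_rng(1)
        bias = lf.BiasProfile(bin_edges=(0.0, 60.0), p_bias=(1.0,))
        # larva east of the first patch centre, heading north; a pi/2 turn
        # can point it west (toward the centre) or east (away)
        pos, heading = (100.0, 120.0), (0.0, 1.0)
        u = (60.0 - pos[0], 0.0)
        for _ in range(50):
            ang = lf.choose_turn_direction(math.pi / 2, pos, heading, two_patches, bias, rng)
            ca, sa = math.cos(ang), math.sin(ang)
            h = (ca * heading[0] - sa * heading[1], sa * heading[0] + ca * heading[1])
            assert h[0] * u[0] + h[1] * u[1] > 0  # points into the centre half-plane

    def test_zero_bias_is_identity(self, two_patches, rng):
        bias = lf.BiasProfile.zero()
        for _ in range(100):
            mag = rng.uniform(-math.pi, math.pi)
            got = lf.choose_turn_direction(mag, (90.0, 130.0), (0.0, 1.0), two_patches, bias, rng)
            assert got == mag

    def test_beyond_cutoff_unchanged(self, two_patches, rng):
        bias = lf.BiasProfile(bin_edges=(0.0, 60.0), p_bias=(1.0,), cutoff=60.0)
        # (120, 20): 100+ mm from either centre
        got = lf.choose_turn_direction(-1.0, (120.0, 20.0), (1.0, 0.0), two_patches, bias, rng)
        assert got == -1.0

    def test_inward_fraction_matches_pbias(self, two_patches):
        rng = np.random.default_rng(7)
        p = 0.8
        bias = lf.BiasProfile(bin_edges=(0.0, 60.0), p_bias=(p,))
        pos = (95.0, 120.0)  # 35 mm from the first centre
        u = (60.0 - pos[0], 0.0)
        n, inward = 10_000, 0
        for _ in range(n):
            heading = (0.0, 1.0)
            ang = lf.choose_turn_direction(1.0, pos, heading, two_patches, bias, rng)
            ca, sa = math.cos(ang), math.sin(ang)
            h = (ca * heading[0] - sa * heading[1], sa * heading[0] + ca * heading[1])
            alt = (ca * heading[0] + sa * heading[1], -sa * heading[0] + ca * heading[1])
            if h[0] * u[0] + h[1] * u[1] > alt[0] * u[0] + alt[1] * u[1]:
                inward += 1
        se = math.sqrt(p * (1 - p) / n)
        assert abs(inward / n - p) < 3 * se


class TestBiasProfileScaling:
    def test_identity(self):
        b = lf.BiasProfile(bin_edges=(0, 10, 20, 30), p_bias=(0.9, 0.8, 0.7))
        s = lf.scale_bias_profile(b, 25.0, 25.0)
        assert s.bin_edges == b.bin_edges and s.cutoff == b.cutoff

    def test_eight_patch_halving(self):
        b = lf.BiasProfile(bin_edges=(0, 10, 20, 30), p_bias=(0.9, 0.8, 0.7), cutoff=60.0)
        s = lf.scale_bias_profile(b, 12.5, 25.0)
        assert s.bin_edges == (0.0, 5.0, 10.0, 15.0)
        assert s.cutoff == 30.0
        assert s.p_bias == b.p_bias  # probabilities unchanged

    def test_lookup_half_open_and_cutoff(self):
        b = lf.BiasProfile(bin_edges=(0, 10, 20), p_bias=(0.9, 0.5), cutoff=20.0)
        assert b.pbias_at(0.0) == 0.9
        assert b.pbias_at(10.0) == 0.5
        assert b.pbias_at(19.999) == 0.5
        assert b.pbias_at(25.0) == 0.0

    def test_validation(self):
        with pytest.raises(lf.ConfigurationError):
            lf.BiasProfile(bin_edges=(0, 10), p_bias=(1.5,))
        with pytest.raises(lf.ConfigurationError):
            lf.BiasProfile(bin_edges=(10, 0), p_bias=(0.5,))


class TestSimulate:
    def test_pure_crawl_is_ballistic(self):
        cfg = _homog_config(_params(mean_v=0.8, sd_v=0.0, pt=0.0, pp=0.0), n_steps=100)
        res = lf.simulate(cfg)
        disp = np.linalg.norm(res.trajectory.positions[-1] - res.trajectory.positions[0])
        assert disp == pytest.approx(0.8 * 0.5 * 100, abs=1e-9)
        assert np.all(res.state_log == CRAWL)

    def test_pause_only_is_frozen(self):
        cfg = _homog_config(_params(pt=0.0, pp=2.0), n_steps=200)
        res = lf.simulate(cfg)
        assert np.all(res.state_log == PAUSE)
        assert np.all(res.trajectory.positions == res.trajectory.positions[0])
        assert res.state_fractions()["pause"] == 1.0

    def test_seed_determinism(self, two_patches):
        params = {
            "yeast": lf.load_substrate_params("rover", "yeast"),
            "agar": lf.load_substrate_params("rover", "agar"),
        }
        def run():
            cfg = lf.SimConfig(
                layout=two_patches, params_by_substrate=params,
                turn_model=lf.TurnAngleModel(0.1, 1.0), n_steps=2000, seed=33,
            )
            return lf.simulate(cfg)
        a, b = run(), run()
        assert np.array_equal(a.trajectory.positions, b.trajectory.positions)
        assert np.array_equal(a.state_log, b.state_log)
        assert [(e.vertex_index, e.angle) for e in a.turn_log] == [
            (e.vertex_index, e.angle) for e in b.turn_log
        ]

    def test_stays_inside_arena(self):
        # fast larva started near a corner: many wall contacts
        cfg = _homog_config(
            _params(mean_v=3.0, sd_v=0.5, pt=0.02, pp=0.0),
            n_steps=5000, start_point=(2.0, 2.0), seed=5,
        )
        res = lf.simulate(cfg)
        pos = res.trajectory.positions
        assert np.all(pos[:, 0] >= 0) and np.all(pos[:, 0] <= 240)
        assert np.all(pos[:, 1] >= 0) and np.all(pos[:, 1] <= 240)

    def test_state_fractions_converge(self):
        p = _params()  # rover-agar: pt*dt = 0.022, pp*dt = 0.00415
        n = 100_000
        cfg = _homog_config(p, n_steps=n, seed=2)
        res = lf.simulate(cfg)
        for state, prob in [(TURN, 0.022), (PAUSE, 0.00415)]:
            frac = float(np.mean(res.state_log == state))
            se = math.sqrt(prob * (1 - prob) / n)
            assert abs(frac - prob) < 3 * se

    def test_turns_per_minute_matches_rate(self):
        # ground-truth turns/min = 60 * P_turn/s
        cfg = _homog_config(_params(), n_steps=60_000, seed=8)
        res = lf.simulate(cfg)
        minutes = 60_000 * 0.5 / 60.0
        rate = len(res.turn_log) / minutes
        se = math.sqrt(0.022 * (1 - 0.022) / 60_000) * 120  # per-minute scale
        assert abs(rate - 60 * 0.044) < 3 * se

    def test_crawl_speed_mean(self):
        cfg = _homog_config(_params(), n_steps=20_000, seed=4)
        res = lf.simulate(cfg)
        pos = res.trajectory.positions
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        crawl_speeds = steps[res.state_log == CRAWL] / 0.5
        # exclude truncated wall steps
        crawl_speeds = crawl_speeds[crawl_speeds > 0.1]
        assert crawl_speeds.mean() == pytest.approx(0.84, abs=0.01)

    def test_turn_steps_carry_no_translation(self):
        cfg = _homog_config(_params(pt=0.2, pp=0.1), n_steps=3000, seed=6)
        res = lf.simulate(cfg)
        pos = res.trajectory.positions
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.all(steps[res.state_log == TURN] == 0)
        assert np.all(steps[res.state_log == PAUSE] == 0)

    def test_missing_substrate_params_rejected(self, two_patches):
        cfg = lf.SimConfig(
            layout=two_patches,
            params_by_substrate={"agar": _params()},  # no yeast entry
        )
        with pytest.raises(lf.ConfigurationError):
            lf.simulate(cfg)

    def test_start_inside_patch(self, two_patches):
        params = {"yeast": _params(), "agar": _params()}
        for seed in range(10):
            cfg = lf.SimConfig(
                layout=two_patches, params_by_substrate=params, n_steps=1, seed=seed
            )
            res = lf.simulate(cfg)
            start = res.trajectory.positions[0]
            assert any(p.contains(start) for p in two_patches.patches)

    def test_bias_increases_residence(self):
        """Elevated near-border inward bias strictly increases time inside,
        on paired seeds (small-scale version of the core model property)."""
        yeast = lf.load_substrate_params("rover", "yeast")
        agar = lf.load_substrate_params("rover", "agar")
        bias = lf.BiasProfile(bin_edges=(0, 20, 30, 40, 60), p_bias=(0.5, 0.9, 0.9, 0.7))
        f0 = lf.residence_ensemble(yeast, agar, n_larvae=8, n_runs=5, seed=21, bias=None)
        f1 = lf.residence_ensemble(yeast, agar, n_larvae=8, n_runs=5, seed=21, bias=bias)
        assert f1.mean() > f0.mean()


class TestParameterTables:
    def test_homogeneous_values(self):
        p = lf.load_substrate_params("rover", "agar")
        assert (p.mean_v, p.sd_v, p.p_turn_per_s, p.p_pause_per_s) == (0.84, 0.13, 0.044, 0.0083)
        p = lf.load_substrate_params("sitter", "yeast")
        assert (p.mean_v, p.p_pause_per_s) == (0.31, 0.25)

    def test_corrected_values(self):
        inside, outside = lf.load_corrected_params("sitter", "yeast")
        assert inside.mean_v == 0.26 and outside.mean_v == 0.36
        assert inside.p_pause_per_s == 0.32

    def test_unknown_combination(self):
        with pytest.raises(lf.ConfigurationError):
            lf.load_substrate_params("rover", "banana")

    def test_example_bias_profile_loads(self):
        b = lf.example_bias_profile()
        assert b.cutoff == 60.0
        assert all(0 <= p <= 1 for p in b.p_bias)

    def test_bias_profile_file_round_trip(self, tmp_path):
        path = tmp_path / "bias.yaml"
        path.write_text("bin_edges: [0, 30, 60]\np_bias: [0.9, 0.6]\ncutoff_mm: 60\n")
        b = lf.load_bias_profile(path)
        assert b.pbias_at(10.0) == 0.9 and b.pbias_at(45.0) == 0.6
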