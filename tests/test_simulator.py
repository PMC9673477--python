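"""Phenotype simulator: calibration of variance components and the config grid."""

import numpy as np
import pytest

from gsbench.simulate import (SimulationConfig, builtin_configs, draw_noise,
                              effect_size, get_config, noise_variance,
                              realized_variance_components, sample_background,
                              read_truth_sidecar, simulate, write_truth_sidecar)


def skewness(x):
    x = np.asarray(x, dtype=float)
    return float(np.mean((x - x.mean()) ** 3) / np.std(x) ** 3)


class TestBackground:
    def test_default_background_size_and_disjointness(self, sim_panel):
        sp = simulate(get_config("C", 0.95), sim_panel, seed=1)
        t = sp.truth
        assert len(np.unique(t.background_indices)) == 1000
        assert len(t.gamma) == 1000
        assert not set(t.background_indices) & set(t.causal_indices)

    def test_zero_sd_gives_zero_polygenic_value(self, small_panel):
        rng = np.random.default_rng(0)
        _, gamma, u = sample_background(small_panel, 50, 0.0, rng)
        assert np.allclose(gamma, 0) and np.allclose(u, 0)

    def test_pooled_gamma_sd_matches_prior(self, sim_panel):
        pooled = np.concatenate([
            simulate(get_config("C", 0.95), sim_panel, seed=s).truth.gamma
            for s in range(1, 11)
        ])
        sd = pooled.std(ddof=1)
        se = 0.1 / np.sqrt(2 * pooled.size)
        assert abs(sd - 0.1) < 3 * se

    def test_too_many_background_markers(self, small_panel):
        with pytest.raises(ValueError, match="exceeds marker count"):
            sample_background(small_panel, 10**6, 0.1, np.random.default_rng(0))


class TestNoise:
    @pytest.mark.parametrize("h,var_u,expected", [
        (0.5, 2.0, 2.0),
        (0.95, 1.0, 1.0 / 19.0),
        (0.7, 7.0, 3.0),
    ])
    def test_noise_variance_formula(self, h, var_u, expected):
        assert noise_variance(h, var_u) == pytest.approx(expected)

    def test_noise_variance_rejects_degenerate_h(self):
        for h in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                noise_variance(h, 1.0)

    def test_gaussian_moments(self):
        rng = np.random.default_rng(0)
        eps = draw_noise("gaussian", 4.0, 4.0, 10**5, rng)
        assert abs(eps.mean()) < 3 * 2.0 / np.sqrt(10**5)
        assert np.var(eps) == pytest.approx(4.0, rel=0.05)

    def test_gamma_centered_with_target_variance_and_skew(self):
        rng = np.random.default_rng(1)
        weak = draw_noise("gamma", 2.0, 4.0, 10**5, rng)
        strong = draw_noise("gamma", 2.0, 1.0, 10**5, rng)
        for eps in (weak, strong):
            assert abs(eps.mean()) < 0.05
            assert np.var(eps) == pytest.approx(2.0, rel=0.05)
        assert skewness(strong) > skewness(weak) > 0

    def test_invalid_sigma2(self):
        with pytest.raises(ValueError):
            draw_noise("gaussian", 0.0, 4.0, 10, np.random.default_rng(0))


class TestEffectSize:
    def test_unit_case(self):
        assert effect_size(0.5, 1.0, 1.0) == pytest.approx(1.0)

    def test_closed_form(self):
        assert effect_size(0.3, 1.0, 1.0) == pytest.approx(np.sqrt(3 / 7), abs=1e-6)
        assert effect_size(0.3, 4.0, 1.0) == pytest.approx(2 * np.sqrt(3 / 7), abs=1e-4)

    def test_realized_fraction_oracle(self):
        # direct simulation: beta*x should explain ~c of total variance
        rng = np.random.default_rng(2)
        c = 0.3
        bg = rng.normal(0, 1.3, size=20000)
        x = rng.choice([0.0, 2.0], size=20000)
        beta = effect_size(c, float(np.var(bg, ddof=1)), float(np.var(x, ddof=1)))
        y = beta * x + bg
        realized = np.var(beta * x, ddof=1) / np.var(y, ddof=1)
        assert realized == pytest.approx(c, abs=0.02)

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            effect_size(0.3, 1.0, 0.0)


class TestSimulate:
    def test_config_c_calibration(self, sim_panel):
        fracs, ratios = [], []
        for s in range(1, 4):
            sp = simulate(get_config("C", 0.95), sim_panel, seed=s)
            t = sp.truth
            vu, ve = np.var(t.u, ddof=1), np.var(t.epsilon, ddof=1)
            ratios.append(vu / (vu + ve))
            fracs.append(sp.realized_fractions["causal_0"])
        assert np.mean(ratios) == pytest.approx(0.95, abs=0.02)
        assert np.mean(fracs) == pytest.approx(0.30, abs=0.05)

    def test_no_fixed_effects_reduces_to_background_plus_noise(self, small_panel):
        cfg = SimulationConfig(name="null", n_samples=200, n_causal=0,
                               heritability=0.8, n_background=100)
        sp = simulate(cfg, small_panel, seed=3)
        assert np.allclose(sp.y, sp.truth.u + sp.truth.epsilon)

    def test_config_e_interaction_fraction(self, sim_panel):
        fracs = [simulate(get_config("E", 0.95), sim_panel, seed=s)
                 .realized_fractions["interaction"] for s in range(1, 4)]
        assert np.mean(fracs) == pytest.approx(0.20, abs=0.05)

    def test_skewed_configs_are_right_skewed(self, sim_panel):
        weak = [skewness(simulate(get_config("G", 0.95), sim_panel, seed=s).truth.epsilon)
                for s in range(1, 4)]
        strong = [skewness(simulate(get_config("H", 0.95), sim_panel, seed=s).truth.epsilon)
                  for s in range(1, 4)]
        assert min(weak) > 0 and min(strong) > 0
        assert np.mean(strong) > np.mean(weak)

    def test_bit_identical_for_equal_seed(self, sim_panel):
        a = simulate(get_config("C", 0.85), sim_panel, seed=11)
        b = simulate(get_config("C", 0.85), sim_panel, seed=11)
        assert (a.y == b.y).all()
        assert (a.truth.background_indices == b.truth.background_indices).all()
        assert (a.truth.beta == b.truth.beta).all()

    def test_fraction_components_sum_to_one(self, sim_panel):
        # holds for purely additive configs whose terms are near-orthogonal
        for name in ("C", "I"):
            sp = simulate(get_config(name, 0.95), sim_panel, seed=5)
            assert sum(sp.realized_fractions.values()) == pytest.approx(1.0, abs=0.05)
        # the Hadamard term covaries positively with its marginals, so the
        # component shares of config E undershoot 1 by the covariance mass
        sp = simulate(get_config("E", 0.95), sim_panel, seed=5)
        assert 0.8 < sum(sp.realized_fractions.values()) < 1.0

    def test_causal_total_tracks_target_for_additive_series(self, sim_panel):
        for name in ("I", "K"):
            sp = simulate(get_config(name, 0.95), sim_panel, seed=9)
            total = sum(v for k, v in sp.realized_fractions.items() if k.startswith("causal"))
            assert total == pytest.approx(0.30, abs=0.05)

    def test_truth_sidecar_round_trip(self, sim_panel, tmp_path):
        sp = simulate(get_config("E", 0.7), sim_panel, seed=2)
        path = tmp_path / "truth.json"
        write_truth_sidecar(sp, path)
        d = read_truth_sidecar(path)
        assert d["causal_indices"] == sp.truth.causal_indices.tolist()
        assert d["beta"] == pytest.approx(sp.truth.beta.tolist())
        assert d["config"]["name"] == "E"


class TestBuiltinGrid:
    def test_grid_size_and_rows(self):
        configs = builtin_configs()
        assert len(configs) == 36
        a = get_config("A", 0.7)
        assert a.n_samples == 100 and a.n_causal == 1
        assert get_config("D", 0.95).n_samples == 2000
        assert get_config("H", 0.85).gamma_shape == 1.0

    def test_sampled_fraction_rule_for_config_l(self):
        from gsbench.simulate import _draw_fractions
        cfg = get_config("L", 0.95)
        rng = np.random.default_rng(0)
        draws = np.array([_draw_fractions(cfg, rng).sum() for _ in range(100)])
        assert (draws > 0).all()
        assert draws.mean() == pytest.approx(0.30, abs=0.02)
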