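import numpy as np
import pytest

from axonmap import (DecayModel, SphericalMeanDecay, aicc, compare_models,
                     fit_model, stick_beta, tangent_intercept,
                     truncated_powerlaw)
from axonmap.fitting import MODEL_IDS, model_predict


def decay_from(model_id, params, b_values, sigma=0.0, noise=None):
    y = model_predict(model_id, params, b_values)
    if noise is not None:
        y = y + noise
    return SphericalMeanDecay(np.asarray(b_values, float), y, sigma=sigma)


CONNECTOM_HIGH_B = np.array([7, 9, 11, 12.1, 13.5, 15, 16.9, 19.1, 21.7, 25.0])


class TestAicc:
    def test_direct_value(self):
        assert aicc(1e-4, 10, 2) == pytest.approx(-109.415, abs=1e-3)

    def test_penalty_monotone_in_k(self):
        assert aicc(1e-3, 12, 3) > aicc(1e-3, 12, 2) > aicc(1e-3, 12, 1)

    def test_zero_rss_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            val = aicc(0.0, 10, 2)
        assert np.isfinite(val)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(1e-3, 3, 2)


class TestFitModel:
    def test_exact_recovery_of_own_model(self):
        truth = {"beta": 0.35, "Da_perp": 8.6e-4}
        decay = decay_from("vii", truth, CONNECTOM_HIGH_B)
        res = fit_model(decay, "vii", b_min=6.0)
        assert res.params["beta"] == pytest.approx(0.35, abs=1e-6)
        assert res.params["Da_perp"] == pytest.approx(8.6e-4, abs=1e-6)
        assert res.converged and res.plausible

    def test_negative_intercept_hallmark(self):
        """Free-intercept power law on truncated-power-law data: gamma < 0."""
        decay = decay_from("vii", {"beta": 0.35, "Da_perp": 3e-3}, CONNECTOM_HIGH_B)
        res = fit_model(decay, "ii", b_min=6.0)
        assert res.params["f_im"] < 0

    def test_nested_model_alpha_recovery(self):
        decay = decay_from("vi", {"beta": 0.4}, CONNECTOM_HIGH_B)
        res = fit_model(decay, "v", b_min=6.0)
        assert res.params["alpha"] == pytest.approx(0.5, abs=1e-4)

    def test_nested_rss_ordering(self, rng):
        noise = rng.normal(0, 2e-3, CONNECTOM_HIGH_B.size)
        decay = decay_from("vii", {"beta": 0.35, "Da_perp": 2e-3},
                           CONNECTOM_HIGH_B, noise=noise)
        full = fit_model(decay, "iii", b_min=6.0)  # adds free intercept
        nested = fit_model(decay, "vii", b_min=6.0)
        assert full.rss <= nested.rss + 1e-15

    def test_too_few_shells_raises(self):
        decay = decay_from("vii", {"beta": 0.3, "Da_perp": 0.0},
                           np.array([7.0, 9.0, 11.0]))
        with pytest.raises(ValueError, match="shells"):
            fit_model(decay, "vii", b_min=6.0)

    def test_shell_order_invariance(self, rng):
        b = CONNECTOM_HIGH_B
        y = truncated_powerlaw(0.35, 2e-3, 0.0, b) + rng.normal(0, 1e-3, b.size)
        perm = rng.permutation(b.size)
        r1 = fit_model(SphericalMeanDecay(b, y, 0.0), "vii", 6.0)
        r2 = fit_model(SphericalMeanDecay(b[perm], y[perm], 0.0), "vii", 6.0)
        assert r1.params["Da_perp"] == pytest.approx(r2.params["Da_perp"], rel=1e-8)

    def test_rescaling_scales_beta_only(self):
        decay = decay_from("vii", {"beta": 0.35, "Da_perp": 2e-3}, CONNECTOM_HIGH_B)
        half = SphericalMeanDecay(decay.b_values, 0.5 * decay.S_bar, 0.0)
        r1 = fit_model(decay, "vii", 6.0)
        r2 = fit_model(half, "vii", 6.0)
        assert r2.params["beta"] == pytest.approx(0.5 * r1.params["beta"], rel=1e-6)
        assert r2.params["Da_perp"] == pytest.approx(r1.params["Da_perp"], abs=1e-9)

    def test_constrained_intercept_mode(self):
        decay = decay_from("vii", {"beta": 0.35, "Da_perp": 3e-3}, CONNECTOM_HIGH_B)
        res = fit_model(decay, "ii", b_min=6.0, constrain_intercept=True)
        assert res.params["f_im"] >= 0.0

    def test_summary_is_printable(self):
        decay = decay_from("vii", {"beta": 0.35, "Da_perp": 1e-3}, CONNECTOM_HIGH_B)
        text = fit_model(decay, "vii", 6.0).summary()
        assert "Da_perp" in text and "AICc" in text

    def test_from_dataframe(self):
        import pandas as pd
        df = pd.DataFrame({"b": CONNECTOM_HIGH_B,
                           "S_bar": truncated_powerlaw(0.3, 1e-3, 0.0, CONNECTOM_HIGH_B)})
        res = DecayModel.from_dataframe(df, "vii", b_min=6.0).fit()
        assert res.params["beta"] == pytest.approx(0.3, abs=1e-6)


class TestCompareModels:
    def test_all_models_fit_and_rank(self):
        decay = decay_from("vii", {"beta": 0.35, "Da_perp": 3e-3}, CONNECTOM_HIGH_B)
        comp = compare_models(decay, MODEL_IDS, b_min=6.0)
        assert min(comp.delta_aicc.values()) == 0.0
        assert set(comp.results) == set(MODEL_IDS)
        assert len(comp.to_dataframe()) == len(MODEL_IDS)

    def test_finite_radius_truth_prefers_truncated_powerlaw(self, rng, connectom):
        """Noisy Connectom-SNR decays from a thick-axon truth: (vii) beats
        the pure power laws (v)/(vi) in the clear majority of realizations."""
        da = 7 * 2.5 ** 4 / (48 * 2.4 * 13 * (30 - 13 / 3))
        beta = stick_beta(0.6, 2.4)
        sigma = (1 / 52) / np.sqrt(60)
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            noise = rng.normal(0, sigma, CONNECTOM_HIGH_B.size)
            decay = decay_from("vii", {"beta": beta, "Da_perp": da},
                               CONNECTOM_HIGH_B, noise=noise)
            comp = compare_models(decay, ("v", "vi", "vii"), b_min=6.0)
            wins += comp.best == "vii"
        assert wins / n_rep > 0.5

    def test_exchange_truth_prefers_exchange_model(self, rng):
        beta, sigma = stick_beta(0.6, 2.4), (1 / 52) / np.sqrt(60)
        wins = 0
        for _ in range(60):
            noise = rng.normal(0, sigma, CONNECTOM_HIGH_B.size)
            decay = decay_from("viii", {"beta": beta, "c": 5.0},
                               CONNECTOM_HIGH_B, noise=noise)
            comp = compare_models(decay, ("vii", "viii"), b_min=6.0)
            wins += comp.best == "viii"
        assert wins / 60 > 0.5

    def test_stick_truth_no_spurious_radius(self, rng):
        """Pure-stick truth: (vii) is not significantly better than (vi)."""
        beta, sigma = stick_beta(0.6, 2.4), (1 / 52) / np.sqrt(60)
        deltas = []
        for _ in range(60):
            noise = rng.normal(0, sigma, CONNECTOM_HIGH_B.size)
            decay = decay_from("vi", {"beta": beta}, CONNECTOM_HIGH_B, noise=noise)
            comp = compare_models(decay, ("vi", "vii"), b_min=6.0)
            deltas.append(comp.results["vii"].aicc - comp.results["vi"].aicc)
        assert np.mean(deltas) > -2.0  # on average, no significant preference


class TestTangentIntercept:
    def test_zero_daperp_gives_fim(self):
        gamma, eps = tangent_intercept(0.4, 0.0, 0.07, 0.3)
        assert gamma == 0.07 and eps == 0.0

    def test_inflection_point_value(self):
        gamma, eps = tangent_intercept(1.0, 0.02, 0.0, np.sqrt(2 * 0.02))
        assert eps == pytest.approx(-np.sqrt(2 * 0.02 / np.e), abs=1e-10)
        assert eps == pytest.approx(-0.12131, abs=1e-5)

    def test_maximum_located_by_brute_force(self):
        """|eps| is maximal at xi0 = sqrt(2 Da_perp) (independent 1D scan)."""
        da = 3.7e-3
        xi = np.linspace(1e-4, 1.0, 200001)
        eps = np.array([-2 * 0.5 * da * np.exp(-da / x ** 2) / x for x in (xi,)])[0]
        xi_star = xi[np.argmax(np.abs(eps))]
        assert xi_star == pytest.approx(np.sqrt(2 * da), abs=1e-5)

    def test_epsilon_closed_form_identity(self):
        """|eps_max| = f sqrt(pi/(2e) Da_perp/Da_par) when beta is the stick
        coefficient."""
        f, da_par, da_perp = 0.6, 2.4, 2e-3
        beta = stick_beta(f, da_par)
        _, eps = tangent_intercept(beta, da_perp, 0.0, np.sqrt(2 * da_perp))
        assert -eps == pytest.approx(f * np.sqrt(np.pi / (2 * np.e) * da_perp / da_par),
                                     rel=1e-10)

    def test_invalid_xi0(self):
        with pytest.raises(ValueError):
            tangent_intercept(0.3, 1e-3, 0.0, 0.0)
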