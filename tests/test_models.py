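"""Design helpers, priors/likelihood machinery, and small fitting checks."""

import numpy as np
import pandas as pd
import pytest

from gazeflow import models
from gazeflow.glmm import SamplerProfile
from gazeflow.models import (
    MODEL_SPECS,
    Posterior,
    code_contrasts,
    effect_transform,
    fit_model,
    spline_basis,
    summarize_posterior,
    sv_transform,
)
from gazeflow.synthetic import (
    SimConfig,
    simulate_dwell_records,
    simulate_postgte_records,
    simulate_prepost_records,
)

QUICK = SamplerProfile(n_walkers_per_dim=2.2, min_walkers=44, n_burn=500,
                       n_steps=400, thin=1)


class TestSVTransform:
    @pytest.mark.parametrize("h, n, expected", [
        (0.0, 100, 0.005), (1.0, 100, 0.995), (0.5, 37, 0.5), (0.5, 9999, 0.5),
    ])
    def test_values(self, h, n, expected):
        assert sv_transform(h, n) == pytest.approx(expected)

    def test_strictly_interior_for_any_n(self):
        out = sv_transform(np.array([0.0, 1.0]), 3)
        assert (out > 0).all() and (out < 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sv_transform(1.2, 10)
        with pytest.raises(ValueError):
            sv_transform(0.5, 0)


class TestContrasts:
    def test_sum_coding_rows(self):
        cm = code_contrasts(("acontextual", "congruent", "incongruent"), "sum")
        assert cm.loc["acontextual"].tolist() == [1.0, 0.0]
        assert cm.loc["congruent"].tolist() == [0.0, 1.0]
        assert cm.loc["incongruent"].tolist() == [-1.0, -1.0]
        np.testing.assert_allclose(cm.sum(axis=0), 0.0)

    def test_treatment_coding_rows(self):
        cm = code_contrasts(("acontextual", "congruent", "incongruent"), "treatment")
        assert cm.loc["acontextual"].tolist() == [0.0, 0.0]
        assert cm.loc["congruent"].tolist() == [1.0, 0.0]
        assert cm.loc["incongruent"].tolist() == [0.0, 1.0]

    def test_two_levels(self):
        cm = code_contrasts(("pre", "post"), "treatment")
        assert cm.to_numpy().ravel().tolist() == [0.0, 1.0]

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            code_contrasts(("a", "b"), "helmert")

    def test_sum_coded_level_means_identity(self):
        # eta_A = b0+g1, eta_C = b0+g2, eta_I = b0-g1-g2 exactly
        b0, g1, g2 = 0.94, 0.009, -0.015
        cm = code_contrasts(("acontextual", "congruent", "incongruent"), "sum")
        eta = b0 + cm.to_numpy() @ np.array([g1, g2])
        np.testing.assert_allclose(eta, [b0 + g1, b0 + g2, b0 - g1 - g2])


class TestSplineBasis:
    def test_shape_and_centering(self):
        B = spline_basis(np.arange(1, 101), dim=5)
        assert B.shape == (100, 5)
        np.testing.assert_allclose(B.mean(axis=0), 0.0, atol=1e-9)

    def test_degenerate_index_error(self):
        with pytest.raises(ValueError):
            spline_basis(np.full(10, 3.0))
        with pytest.raises(ValueError):
            spline_basis([])

    def test_basis_can_represent_smooth_trend(self):
        k = np.arange(1, 101, dtype=float)
        target = 0.02 * k  # monotone trend
        B = spline_basis(k, dim=5)
        coef, *_ = np.linalg.lstsq(B, target - target.mean(), rcond=None)
        fitted = B @ coef
        r = np.corrcoef(fitted, target)[0, 1]
        assert r >= 0.99


class TestEffectTransform:
    def test_percent_change_matches_printed_value(self):
        assert effect_transform(0.08, "log", "percent_change") == pytest.approx(8.3, abs=0.05)

    def test_null_effect(self):
        assert effect_transform(0.0, "log", "percent_change") == 0.0
        assert effect_transform(0.0, "logit", "odds_ratio") == 1.0
        assert effect_transform(0.0, "logit", "inv_logit") == 0.5

    def test_inv_logit_grand_mean(self):
        assert effect_transform(0.94, "logit", "inv_logit") == pytest.approx(0.72, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effect_transform(np.inf, "log", "percent_change")
        with pytest.raises(ValueError):
            effect_transform(0.1, "logit", "percent_change")


def _fake_posterior(draws: pd.DataFrame) -> Posterior:
    return Posterior(spec=MODEL_SPECS["PERF"], draws=draws,
                     rhat={c: 1.0 for c in draws.columns},
                     ess={c: float(len(draws)) for c in draws.columns},
                     converged=True)


class TestSummaries:
    def test_hdi_of_standard_normal_draws(self, rng):
        draws = pd.DataFrame({"beta0": rng.standard_normal(200_000)})
        summ = summarize_posterior(_fake_posterior(draws), prob=0.89).iloc[0]
        # 89% HDI of N(0,1) is (-1.60, 1.60)
        assert summ["hdi_lo"] == pytest.approx(-1.60, abs=0.03)
        assert summ["hdi_hi"] == pytest.approx(1.60, abs=0.03)
        assert summ["mean"] == pytest.approx(0.0, abs=0.01)

    def test_constant_draws_zero_width(self):
        draws = pd.DataFrame({"beta0": np.full(100, 1.23)})
        summ = summarize_posterior(_fake_posterior(draws), prob=0.95).iloc[0]
        assert summ["hdi_lo"] == summ["hdi_hi"] == pytest.approx(1.23)

    def test_both_probability_levels_supported(self, rng):
        draws = pd.DataFrame({"beta0": rng.standard_normal(50_000)})
        w89 = summarize_posterior(_fake_posterior(draws), prob=0.89).iloc[0]
        w95 = summarize_posterior(_fake_posterior(draws), prob=0.95).iloc[0]
        assert w95["hdi_hi"] - w95["hdi_lo"] > w89["hdi_hi"] - w89["hdi_lo"]


class TestValidation:
    def test_gamma_rejects_nonpositive_response(self):
        df = pd.DataFrame({
            "participant": [0, 0, 1, 1], "session": [0, 1, 0, 1],
            "object_kind": [0, 1, 0, 1],
            "agent_type": ["acontextual"] * 4, "dwell": [1.0, -0.5, 2.0, 1.0],
        })
        with pytest.raises(ValueError, match="positive"):
            models.build_problem(MODEL_SPECS["DWELL"], df)

    def test_beta_rejects_boundary_response(self):
        df = pd.DataFrame({
            "participant": [0, 0, 1, 1], "session": [0, 1, 0, 1],
            "agent_type": ["acontextual", "congruent", "incongruent", "congruent"],
            "H": [0.5, 1.0, 0.4, 0.6],
        })
        with pytest.raises(ValueError, match="inside"):
            models.build_problem(MODEL_SPECS["POSTGTE"], df)

    def test_floor_pointing_errors(self):
        out = models.floor_pointing_errors(np.array([0.0, 0.05, 5.0]))
        assert (out > 0).all()
        assert out[2] == 5.0 and out[0] == pytest.approx(0.1)

    def test_prior_predictive_admissible(self, rng):
        # drawing coefficients from their priors and responses from the
        # likelihood yields admissible values for both families
        eta = rng.normal(0, 1, size=500)
        kappa = np.abs(rng.standard_cauchy(1)[0] * 2.5) + 0.1
        y_gamma = rng.gamma(kappa, np.exp(eta) / kappa)
        assert (y_gamma > 0).all()
        phi = rng.gamma(2.0, 5.0) + 0.5
        mu = 1 / (1 + np.exp(-eta))
        y_beta = rng.beta(mu * phi, (1 - mu) * phi)
        assert ((y_beta > 0) & (y_beta < 1)).all()


def _zscore(post, coef, truth):
    draws = post.draws[coef]
    return abs(draws.mean() - truth) / draws.std()


class TestFitting:
    # single-seed fits assert recovery within 3 posterior SDs; strict 95%
    # interval calibration is established over 50 replicates elsewhere
    def test_dwell_interaction_recovered(self):
        cfg = SimConfig(n_participants=10, n_sessions=2, seed=21)
        data = simulate_dwell_records(cfg, 900, seed=1)
        post = fit_model("DWELL", data, profile=QUICK, seed=3)
        truth = cfg.true_coefficients["dwell"]
        assert _zscore(post, "beta_OI", truth["beta_OI"]) < 3
        assert _zscore(post, "beta_O", truth["beta_O"]) < 3
        assert post.draws["kappa"].mean() == pytest.approx(truth["kappa"], rel=0.25)

    def test_postgte_null_effects_near_zero(self):
        cfg = SimConfig(n_participants=10, n_sessions=2, seed=22)
        cfg.true_coefficients["postgte"].update({"gamma1": 0.0, "gamma2": 0.0})
        data = simulate_postgte_records(cfg, 700, seed=2)
        post = fit_model("POSTGTE", data, profile=QUICK, seed=4)
        for g in ("gamma1", "gamma2"):
            assert _zscore(post, g, 0.0) < 3

    def test_prepost_spline_block_present(self):
        cfg = SimConfig(n_participants=8, n_sessions=2, seed=23)
        data = simulate_prepost_records(cfg, 300, seed=5)
        post = fit_model("PREPOST", data, profile=QUICK, seed=6)
        assert "sd_spline_k" in post.draws.columns
        truth = cfg.true_coefficients["prepost"]
        assert _zscore(post, "beta_P", truth["beta_P"]) < 3

    def test_posterior_metadata_records_sampler(self):
        cfg = SimConfig(n_participants=6, n_sessions=2, seed=24)
        data = simulate_dwell_records(cfg, 240, seed=7)
        post = fit_model("DWELL", data, profile=QUICK, seed=8)
        md = post.metadata
        assert md["seed"] == 8 and md["n_obs"] == 240
        assert set(post.rhat) == set(post.draws.columns)
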