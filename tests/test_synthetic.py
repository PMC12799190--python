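"""The synthetic generator: Markov machinery, sessions, and model datasets."""

import numpy as np
import pandas as pd
import pytest

from gazeflow.entropy import CANONICAL_CATEGORIES, gte
from gazeflow.synthetic import (
    SimConfig,
    default_transition_matrix,
    flatten_environment,
    simulate_encounter_shift,
    simulate_fixation_log,
    simulate_fixation_sequence,
    simulate_gaze_session,
    simulate_mediation_dataset,
    simulate_pointing_trials,
)


class TestFixationSequence:
    def test_absorbing_chain_repeats_start(self):
        seq = simulate_fixation_sequence(np.eye(8), 100, "background", seed=0)
        assert seq == ["background"] * 100

    def test_uniform_chain_transition_frequencies(self):
        # per-row N ~ 50k gives conditional-frequency SE ~ 0.0015, so the
        # worst of the 64 cells stays within 0.005 of 1/8
        P = np.full((8, 8), 1 / 8)
        seq = simulate_fixation_sequence(P, 400_000, 0, seed=1)
        codes = np.array([CANONICAL_CATEGORIES.index(s) for s in seq])
        counts = np.zeros((8, 8))
        np.add.at(counts, (codes[:-1], codes[1:]), 1)
        freq = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(freq - 1 / 8).max() < 0.005

    def test_two_state_occupancy_matches_hand_solution(self):
        P = np.array([[0.9, 0.1], [0.5, 0.5]])
        seq = simulate_fixation_sequence(P, 100_000, 0, seed=2, labels=("x", "y"))
        fx = seq.count("x") / len(seq)
        assert abs(fx - 5 / 6) < 0.01 and abs((1 - fx) - 1 / 6) < 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_fixation_sequence(np.ones((2, 2)), 10, 0, seed=0)
        with pytest.raises(ValueError):
            simulate_fixation_sequence(np.eye(2), 1, 0, seed=0)


class TestEncounterShift:
    def test_lambda_zero_identity(self):
        P = default_transition_matrix()
        np.testing.assert_array_equal(simulate_encounter_shift(P, 0.0), P)

    def test_lambda_one_uniform(self):
        P = default_transition_matrix()
        np.testing.assert_allclose(simulate_encounter_shift(P, 1.0), 1 / 8)

    def test_half_mix_of_point_mass_rows(self):
        P = np.zeros((8, 8))
        P[np.arange(8), (np.arange(8) + 1) % 8] = 1.0
        post = simulate_encounter_shift(P, 0.5)
        for i in range(8):
            tgt = (i + 1) % 8
            assert post[i, tgt] == pytest.approx(0.5625)
            off = np.delete(post[i], tgt)
            np.testing.assert_allclose(off, 0.0625)

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_encounter_shift(default_transition_matrix(), 1.5)

    def test_normalized_gte_monotone_in_lambda(self):
        P = default_transition_matrix()
        values = []
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            seq = simulate_fixation_sequence(
                simulate_encounter_shift(P, lam), 10_000, 0, seed=42)
            values.append(gte(seq).H_norm)
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_environment_flattening_preserves_agent_columns(self):
        P = default_transition_matrix()
        out = flatten_environment(P, 0.6, [5, 6, 7])
        np.testing.assert_allclose(out[:, 5:], P[:, 5:])
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)


class TestGazeSession:
    def test_determinism_same_seed(self, base_config):
        s1, t1 = simulate_gaze_session(base_config, 1, 0, seed=77)
        s2, t2 = simulate_gaze_session(base_config, 1, 0, seed=77)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1.fixation_log, t2.fixation_log)

    def test_single_category_single_object(self):
        P = np.zeros((8, 8))
        P[:, 1] = 1.0  # every transition lands on "building"
        cfg = SimConfig(
            seed=3, objects_per_category=1, session_length=70.0,
            transition_matrix_by_condition={"only": P},
        )
        samples, truth = simulate_gaze_session(cfg, 0, 0, seed=9)
        hits = samples["hit_object_id"].dropna().unique()
        assert len(truth.fixation_log) >= 1
        assert set(truth.fixation_log["object_id"]) <= {"building:0", "background:0"}
        assert set(hits) <= {"building:0", "background:0"}

    def test_fixation_log_disjoint_and_ordered(self, gaze_session):
        _, truth = gaze_session
        log = truth.fixation_log
        assert (log["end"] > log["start"]).all()
        assert (log["start"].to_numpy()[1:] >= log["end"].to_numpy()[:-1] - 1e-9).all()

    def test_velocity_separates_fixations_from_saccades(self, gaze_session, base_config):
        from gazeflow.fixations import angular_velocity

        samples, truth = gaze_session
        vel = angular_velocity(samples)
        in_fix = samples["hit_object_id"].notna().to_numpy()
        fix_vel = vel[1:][in_fix[1:] & in_fix[:-1]]
        sac_vel = vel[1:][~in_fix[1:] | ~in_fix[:-1]]
        assert np.nanmedian(fix_vel) < base_config.fixation_velocity_noise
        assert np.nanmax(sac_vel) >= base_config.saccade_peak_velocity * 0.5

    def test_roundtrip_recovers_generating_matrix(self):
        # full pipeline: rasterized session -> classifier -> transition counts;
        # concentrated cyclic chain, no encounter flattening, ~5,000 fixations
        from gazeflow.fixations import classify_fixations
        from gazeflow.entropy import build_transition_matrix, row_normalize

        P = 0.05 * np.full((8, 8), 1 / 8) + 0.95 * np.roll(np.eye(8), 1, axis=1)
        cfg = SimConfig(seed=9, session_length=2650.0, encounter_flattening=0.0,
                        transition_matrix_by_condition={"cyclic": P})
        samples, _ = simulate_gaze_session(cfg, 0, 0, seed=77)
        seq = [e.category for e in classify_fixations(samples)][:5000]
        assert len(seq) >= 5000
        Phat, _ = row_normalize(build_transition_matrix(seq))
        assert np.abs(Phat - P).max() <= 0.03

    def test_fast_log_matches_session_plan(self, base_config):
        log, truth = simulate_fixation_log(base_config, 0, 0, seed=123)
        _, truth_full = simulate_gaze_session(base_config, 0, 0, seed=123)
        pd.testing.assert_frame_equal(log, truth_full.fixation_log)


class TestPointingTrials:
    def test_empty_request(self, base_config):
        out = simulate_pointing_trials(base_config, 0, seed=0)
        assert len(out) == 0 and "error" in out.columns

    def test_reference_cell_mean(self):
        cfg = SimConfig(seed=4)
        c = cfg.true_coefficients["perf"]
        c.update({"beta_C": 0, "beta_I": 0, "beta_pub": 0, "beta_GTE": 0,
                  "beta_DW_A": 0, "beta_DW_B": 0, "sigma_u": 0, "sigma_v": 0})
        t = simulate_pointing_trials(cfg, 20_000, seed=1)
        se = t["error"].std() / np.sqrt(len(t))
        assert abs(t["error"].mean() - np.exp(c["beta0"])) < 2 * se

    def test_gte_slope_shifts_mean_on_link_scale(self):
        cfg = SimConfig(seed=4)
        c = cfg.true_coefficients["perf"]
        c.update({"beta_C": 0, "beta_I": 0, "beta_pub": 0,
                  "beta_DW_A": 0, "beta_DW_B": 0, "sigma_u": 0, "sigma_v": 0,
                  "beta_GTE": -0.31})
        t = simulate_pointing_trials(cfg, 60_000, seed=2)
        lo = t[t.gte_post < t.gte_post.quantile(0.2)]
        hi = t[t.gte_post > t.gte_post.quantile(0.8)]
        expected = np.exp(-0.31 * (hi.gte_post.mean() - lo.gte_post.mean()))
        ratio = hi.error.mean() / lo.error.mean()
        assert ratio == pytest.approx(expected, rel=0.03)

    def test_missing_coefficient_names_symbol(self, base_config):
        import copy

        cfg = copy.deepcopy(base_config)
        del cfg.true_coefficients["perf"]["beta_GTE"]
        with pytest.raises(KeyError, match="beta_GTE"):
            simulate_pointing_trials(cfg, 10, seed=0)

    def test_errors_strictly_positive(self, base_config):
        t = simulate_pointing_trials(base_config, 5_000, seed=3)
        assert (t["error"] > 0).all()
        assert set(t["agent_type"]) == {"acontextual", "congruent", "incongruent"}


class TestMediationDataset:
    def test_tables_share_keys(self, base_config):
        med, trials = simulate_mediation_dataset(base_config, 500, seed=0)
        assert len(med) == len(trials) == 500
        pd.testing.assert_series_equal(med["participant"], trials["participant"])
        pd.testing.assert_series_equal(med["gte_post"], trials["gte_post"])

    def test_high_precision_null_mediator_centers_at_half(self):
        cfg = SimConfig(seed=6)
        cfg.true_coefficients["mediator"].update(
            {"beta0": 0, "beta_C": 0, "beta_I": 0, "beta_pub": 0,
             "phi": 1000.0, "sigma_u": 0, "sigma_v": 0})
        med, _ = simulate_mediation_dataset(cfg, 4_000, seed=1)
        assert abs(med["gte_post"].mean() - 0.5) < 0.01

    def test_null_mediator_contrast(self):
        cfg = SimConfig(seed=6)
        cfg.true_coefficients["mediator"].update(
            {"beta_C": 0.0, "beta_I": 0.0, "sigma_u": 0, "sigma_v": 0})
        med, _ = simulate_mediation_dataset(cfg, 30_000, seed=2)
        g = med.groupby("agent_type")["gte_post"]
        means, counts = g.mean(), g.count()
        se = np.sqrt(med["gte_post"].var() * (1 / counts["congruent"] + 1 / counts["acontextual"]))
        assert abs(means["congruent"] - means["acontextual"]) < 2 * se

    def test_invalid_precision(self, base_config):
        import copy

        cfg = copy.deepcopy(base_config)
        cfg.true_coefficients["mediator"]["phi"] = -1.0
        with pytest.raises(ValueError):
            simulate_mediation_dataset(cfg, 10, seed=0)


class TestSimConfigValidation:
    def test_bad_transition_matrix(self):
        bad = {"x": np.ones((8, 8))}
        with pytest.raises(ValueError):
            SimConfig(transition_matrix_by_condition=bad)

    def test_short_session_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(session_length=45.0)

    def test_lambda_range(self):
        with pytest.raises(ValueError):
            SimConfig(encounter_flattening=1.2)
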