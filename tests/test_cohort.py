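"""Synthetic cohort generator: latent structure, recognition responses,
ratings and choice backends."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import memchoice as mc
from memchoice import cohort
from memchoice.cohort import LogisticChoiceParams


class TestItemBank:
    def test_requested_memorability_value_correlation_is_achieved(self):
        # Monte-Carlo check of the Gaussian-copula calibration
        b = mc.make_item_bank(mc.CohortConfig(n_items=10000, mem_value_corr=0.15, seed=0))
        r = np.corrcoef(b.table.theta_mem, b.table.mu_value)[0, 1]
        assert abs(r - 0.15) < 0.02

    def test_independent_latents_when_correlation_zero(self):
        b = mc.make_item_bank(mc.CohortConfig(n_items=10000, mem_value_corr=0.0, seed=1))
        assert abs(np.corrcoef(b.table.theta_mem, b.table.mu_value)[0, 1]) < 0.03

    def test_comonotone_copula_gives_perfect_rank_correlation(self):
        b = mc.make_item_bank(mc.CohortConfig(n_items=138, mem_value_corr=1.0, seed=2))
        rho, _ = stats.spearmanr(b.table.theta_mem, b.table.mu_value)
        assert rho == pytest.approx(1.0)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="mem_value_corr"):
            mc.CohortConfig(mem_value_corr=1.5)

    def test_out_of_range_mu_value_rejected(self, bank):
        bad = bank.table.copy()
        bad.loc[0, "mu_value"] = 12.0
        with pytest.raises(ValueError, match="mu_value"):
            mc.ItemBank(bad)

    def test_item_ids_unique_and_latents_finite(self, bank):
        assert bank.table.item_id.is_unique
        assert np.all(np.isfinite(bank.table[["theta_mem", "phi_fa"]]))


def _two_trial_streams(item_ids, n_participants):
    """Minimal streams: every item is a target for every participant."""
    frames = []
    for p in range(n_participants):
        n = len(item_ids)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": p,
                    "trial_index": np.arange(2 * n),
                    "item_id": np.concatenate([item_ids, item_ids]),
                    "role": ["target_first"] * n + ["target_repeat"] * n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestRecognition:
    def test_perfect_memory_limit_gives_cr_one(self):
        cfg = mc.CohortConfig(n_items=4, theta_loc=30.0, theta_scale=0.0, phi_loc=-30.0, phi_scale=0.0,
                              alpha_sd=0.0, gamma_sd=0.0, seed=0)
        b = mc.make_item_bank(cfg)
        log = cohort.simulate_recognition(b, _two_trial_streams(b.item_ids, 10), cfg)
        table = mc.memory.score_memorability(log)
        assert np.allclose(table.cr, 1.0)

    def test_equal_hit_and_false_alarm_propensities_give_cr_zero(self):
        # theta == phi and matched participant-effect SDs: expected CR 0
        cfg = mc.CohortConfig(n_items=6, theta_loc=0.3, theta_scale=0.0, phi_loc=0.3, phi_scale=0.0,
                              alpha_sd=0.4, gamma_sd=0.4, seed=5)
        b = mc.make_item_bank(cfg)
        log = cohort.simulate_recognition(b, _two_trial_streams(b.item_ids, 4000), cfg)
        table = mc.memory.score_memorability(log)
        # SE of mean CR over 6 items x 4000 participants ~ 0.005
        assert abs(table.cr.mean()) < 0.02

    def test_hit_rates_match_population_mean_at_large_n(self):
        # law-of-large-numbers oracle: quadrature over the participant effect
        cfg = mc.CohortConfig(n_items=4, theta_loc=0.4, theta_scale=0.5, alpha_sd=0.5, seed=9)
        b = mc.make_item_bank(cfg)
        log = cohort.simulate_recognition(b, _two_trial_streams(b.item_ids, 5000), cfg)
        table = mc.memory.score_memorability(log).set_index("item_id")
        nodes, weights = np.polynomial.hermite_e.hermegauss(41)
        w = weights / weights.sum()
        for _, item in b.table.iterrows():
            expected = float(np.sum(w * expit(cfg.alpha_sd * nodes + item.theta_mem)))
            assert abs(table.loc[item.item_id, "hit_rate"] - expected) < 0.02

    def test_unknown_item_raises(self, bank, default_config):
        streams = _two_trial_streams(np.array([999_999]), 1)
        with pytest.raises(ValueError, match="unknown item"):
            cohort.simulate_recognition(bank, streams, default_config)


class TestRatings:
    def test_zero_noise_reproduces_latent_values(self, bank):
        r = cohort.simulate_ratings(bank, 3, 0.0, seed=0)
        wide = r.pivot(index="participant_id", columns="item_id", values="rating")
        assert np.allclose(wide.to_numpy(), bank.table.mu_value.to_numpy()[None, :])

    def test_item_means_match_clipped_normal_expectation(self):
        # closed-form mean of clip(mu + sigma Z, 0, 10)
        cfg = mc.CohortConfig(n_items=6, seed=4)
        b = mc.make_item_bank(cfg)
        r = cohort.simulate_ratings(b, 1000, 1.0, seed=1)
        means = r.groupby("item_id")["rating"].mean()
        for _, item in b.table.iterrows():
            mu, s = item.mu_value, 1.0
            a, c = (0 - mu) / s, (10 - mu) / s
            expected = (
                0 * stats.norm.cdf(a)
                + 10 * stats.norm.sf(c)
                + mu * (stats.norm.cdf(c) - stats.norm.cdf(a))
                - s * (stats.norm.pdf(c) - stats.norm.pdf(a))
            )
            assert abs(means[item.item_id] - expected) < 0.1

    def test_negative_noise_rejected(self, bank):
        with pytest.raises(ValueError):
            cohort.simulate_ratings(bank, 2, -1.0, seed=0)


class TestChoices:
    def _skeleton(self, rng, n=600):
        return pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(6), n // 6),
                "delta_value": rng.normal(0, 1, n),
                "delta_mem": rng.normal(0, 1, n),
            }
        )

    def test_extreme_value_weight_forces_choice(self):
        rng = np.random.default_rng(0)
        t = self._skeleton(rng)
        params = LogisticChoiceParams(beta_value=60.0, sd_beta0=0, sd_beta_value=0)
        out = cohort.simulate_choices(t, params, seed=1)
        resp = out[out.choice != "none"]
        pos = resp[resp.delta_value > 0.1]
        assert (pos.choice == "right").all()

    def test_null_world_memorability_effect_centred_on_zero(self):
        # across replicates the fitted delta_mem slope averages to ~0
        from memchoice.screening import simple_logistic

        slopes = []
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            t = self._skeleton(rng, n=900)
            out = cohort.simulate_choices(t, cohort.null_world(), seed=200 + rep)
            resp = out[out.choice != "none"]
            fit = simple_logistic(
                resp.delta_mem.to_numpy()[None, :], (resp.choice == "right").to_numpy(float)[None, :]
            )
            slopes.append(fit["slope"][0])
        slopes = np.array(slopes)
        assert abs(slopes.mean()) < 2.5 * slopes.std(ddof=1) / np.sqrt(len(slopes))

    def test_ddm_backend_matches_closed_form_absorption(self):
        from memchoice.ddm import DDMParams, prob_upper

        params = DDMParams(a=1.6, t0=0.25, v0=0.0, v_val=1.0, v_mem=0.0, v_int=0.0)
        dv = np.repeat([-1.0, 0.0, 1.0], 2000)
        t = pd.DataFrame({"participant_id": 0, "delta_value": dv, "delta_mem": 0.0})
        out = cohort.simulate_choices(t, params, seed=3)
        resp = out[out.choice != "none"]
        for v in (-1.0, 0.0, 1.0):
            sub = resp[resp.delta_value == v]
            expected = float(prob_upper(params, v=v * params.v_val, z_rel=0.5))
            se = np.sqrt(expected * (1 - expected) / len(sub))
            assert abs((sub.choice == "right").mean() - expected) < 4 * se + 0.01

    def test_missing_covariates_raise(self):
        with pytest.raises(ValueError, match="covariate"):
            cohort.simulate_choices(pd.DataFrame({"participant_id": [0]}), LogisticChoiceParams(), 0)

    def test_rts_respect_deadline_flagging(self, choice_trials):
        resp = choice_trials[choice_trials.choice != "none"]
        assert (resp.rt_ms <= 3000).all() and (resp.rt_ms > 0).all()
        assert choice_trials.loc[choice_trials.choice == "none", "rt_ms"].isna().all()


class TestDeterminism:
    def test_identical_config_and_seed_give_identical_outputs(self):
        cfg = mc.CohortConfig(n_items=12, seed=77)
        b1, b2 = mc.make_item_bank(cfg), mc.make_item_bank(cfg)
        pd.testing.assert_frame_equal(b1.table, b2.table)
        r1 = cohort.simulate_ratings(b1, 5, 1.0, seed=77)
        r2 = cohort.simulate_ratings(b2, 5, 1.0, seed=77)
        pd.testing.assert_frame_equal(r1, r2)

    def test_stage_substreams_are_independent(self):
        # regenerating ratings alone does not depend on recognition draws
        cfg = mc.CohortConfig(n_items=12, seed=5)
        b = mc.make_item_bank(cfg)
        r1 = cohort.simulate_ratings(b, 4, 1.0, seed=5)
        _ = cohort.simulate_recognition(b, _two_trial_streams(b.item_ids, 3), cfg)
        r2 = cohort.simulate_ratings(b, 4, 1.0, seed=5)
        pd.testing.assert_frame_equal(r1, r2)


class TestFastCohortPath:
    """The vectorized end-to-end generator must agree with the modular
    ratings -> z-score -> rank -> pair -> assemble -> choices chain."""

    def test_structure_and_covariate_identities(self, bank, power_template):
        rng = np.random.default_rng(5)
        t = cohort.simulate_choice_cohort(bank, power_template.z_mem, 6, LogisticChoiceParams(), rng)
        assert len(t) == 6 * 138
        # every item appears exactly twice per participant
        for _, grp in t.groupby("participant_id"):
            counts = pd.concat([grp.left_item, grp.right_item]).value_counts()
            assert (counts == 2).all()
            assert (grp.pair_type == "close").sum() == 69
        assert np.allclose(t.abs_delta_value, t.delta_value.abs())
        zm = power_template.z_mem
        dm = zm.reindex(t.right_item).to_numpy() - zm.reindex(t.left_item).to_numpy()
        assert np.allclose(t.delta_mem, dm)
        assert np.allclose(t.sum_mem, zm.reindex(t.right_item).to_numpy() + zm.reindex(t.left_item).to_numpy())

    def test_close_pairs_have_adjacent_ranks(self, bank, power_template):
        rng = np.random.default_rng(6)
        t = cohort.simulate_choice_cohort(bank, power_template.z_mem, 3, LogisticChoiceParams(), rng)
        close = t[t.pair_type == "close"]
        # adjacent-rank pairs: |delta_value| of close pairs is far below far pairs
        far = t[t.pair_type == "far"]
        assert close.abs_delta_value.mean() < 0.2 * far.abs_delta_value.mean()
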