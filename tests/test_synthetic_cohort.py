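"""Ground-truth cohort sampling, forward simulation, and volume generation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ddchoice as dc
from ddchoice.structural_association import partial_correlation
from ddchoice.synthetic_cohort import (CohortConfig, child_seed,
                                       generate_cohort_choices, generate_volumes,
                                       sample_cohort)


class TestSampleCohort:
    def test_default_cohort_contract(self):
        truth = sample_cohort(CohortConfig(seed=1))
        assert len(truth) == 70
        assert (truth["K"] > 0).all()
        assert (truth["beta"] > 0).all()
        assert truth["r"].between(-0.25, 0.5).all()
        assert truth["age"].between(19, 44).all()
        assert truth["gender"].sum() == 19  # 51 women, 19 men

    def test_k_median_matches_lognormal_location(self):
        """Monte-Carlo check of the log-normal location: the population
        median of K sits at ~0.03 per day."""
        truth = sample_cohort(CohortConfig(n_subjects=10_000, seed=2))
        assert 0.02 <= np.median(truth["K"]) <= 0.045

    def test_beta_moments_match_targets(self):
        truth = sample_cohort(CohortConfig(n_subjects=20_000, seed=3))
        assert truth["beta"].mean() == pytest.approx(7.04, rel=0.05)
        assert truth["beta"].std() == pytest.approx(8.28, rel=0.05)

    def test_deterministic(self):
        a = sample_cohort(CohortConfig(n_subjects=2, seed=1))
        b = sample_cohort(CohortConfig(n_subjects=2, seed=1))
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort(CohortConfig(log_k_scale=0.0))
        with pytest.raises(ValueError):
            sample_cohort(CohortConfig(n_subjects=1))


class TestCohortChoices:
    def test_reproducible_and_complete(self, default_cohort):
        design, truth, choices = default_cohort
        again = generate_cohort_choices(truth, design, "du", seed=0)
        pd.testing.assert_frame_equal(choices, again)
        assert choices["subject"].nunique() == 70
        assert len(choices) == 70 * 330

    def test_flat_softmax_limit_is_random_responding(self, default_design):
        """beta -> 0: per-subject SbS counts look Binomial(100, 1/2)."""
        truth = sample_cohort(CohortConfig(n_subjects=30, seed=4))
        truth["beta"] = 1e-3
        choices = generate_cohort_choices(truth, default_design, "hyp", seed=5)
        counts = (choices[choices["chose_sbs"] >= 0]
                  .groupby(["subject", "session"])["chose_sbs"].sum())
        assert counts.mean() == pytest.approx(50, abs=2)
        # two-sided binomial band: essentially all counts within +-4 SD
        assert counts.between(30, 70).mean() > 0.98

    def test_unknown_model_rejected(self, default_cohort):
        design, truth, _ = default_cohort
        with pytest.raises(ValueError, match="generating model"):
            generate_cohort_choices(truth, design, "exp", seed=0)


class TestVolumes:
    def test_contract(self, surrogate_scores):
        scores = surrogate_scores(70, np.random.default_rng(6))
        vols = generate_volumes(scores, 0.3, seed=7)
        region_cols = [c for c in vols.columns
                       if c.startswith(("left_", "right_"))]
        assert len(region_cols) == 12
        assert (vols[region_cols] > 0).all().all()
        assert (vols["whole_brain_volume"].to_numpy()[:, None]
                > vols[region_cols].to_numpy()).all()

    def test_null_effect_centers_at_zero(self, surrogate_scores):
        rng = np.random.default_rng(8)
        rs = []
        for rep in range(200):
            scores = surrogate_scores(70, rng)
            vols = generate_volumes(scores, 0.0, seed=int(rng.integers(2**31)))
            C = vols[["whole_brain_volume", "gender", "age"]]
            rs.append(partial_correlation(scores["sbs_mean"],
                                          vols["left_caudate"], C).statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_planted_effect_recovered(self, surrogate_scores):
        rng = np.random.default_rng(9)
        rs = []
        for rep in range(200):
            scores = surrogate_scores(70, rng)
            vols = generate_volumes(scores, 0.3, seed=int(rng.integers(2**31)))
            C = vols[["whole_brain_volume", "gender", "age"]]
            for hemi in ("left", "right"):
                rs.append(partial_correlation(scores["sbs_mean"],
                                              vols[f"{hemi}_caudate"], C).statistic)
        assert np.mean(rs) == pytest.approx(0.3, abs=0.05)

    def test_infeasible_target_rejected(self, surrogate_scores):
        scores = surrogate_scores(30, np.random.default_rng(10))
        with pytest.raises(ValueError):
            generate_volumes(scores, 1.0, seed=1)


class TestEndToEnd:
    def test_rank_order_of_k_recovered(self, default_cohort_fit):
        """truth -> choices -> fits preserves the rank order of K."""
        design, truth, choices, fit_table, _ = default_cohort_fit
        du = fit_table[fit_table["model"] == "du"].set_index("subject")
        merged = truth.set_index("subject").join(du, lsuffix="_true")
        rho = stats.spearmanr(merged["K_true"], merged["K"]).statistic
        assert rho >= 0.8

    def test_planted_effect_survives_battery(self, default_cohort_fit):
        """Power property at effect r = 0.4: the battery flags a caudate row
        at the Bonferroni threshold in at least half of replicates."""
        from ddchoice.structural_association import association_battery
        design, truth, choices, fit_table, _ = default_cohort_fit
        du = fit_table[fit_table["model"] == "du"].set_index("subject")
        scores = truth[["subject", "age", "gender"]].copy()
        sbs = (choices[choices["chose_sbs"] >= 0]
               .groupby("subject")["chose_sbs"].sum() / 3)
        scores["sbs_mean"] = sbs[scores["subject"]].to_numpy()
        scores["log_k"] = np.log(du.loc[scores["subject"], "K"]).to_numpy()
        rng = np.random.default_rng(11)
        hits = 0
        for rep in range(60):
            vols = generate_volumes(scores, 0.4, seed=int(rng.integers(2**31)))
            table, _ = association_battery(vols, scores)
            caud = table[table["region"] == "caudate"]
            hits += caud["significant_bonferroni"].any()
        assert hits >= 30


def test_child_seed_is_deterministic_and_bounded():
    assert child_seed(1, 2, 3) == child_seed(1, 2, 3)
    assert child_seed(1, 2, 3) != child_seed(1, 2, 4)
    assert 0 <= child_seed(123, 7) < 2**31
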