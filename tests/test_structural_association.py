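"""Partial correlations, Bonferroni control, and the association battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ddchoice.behavioral_metrics import pearson
from ddchoice.structural_association import (association_battery,
                                             bonferroni_threshold,
                                             partial_correlation)
from ddchoice.synthetic_cohort import generate_volumes


def _oracle_partial(x, y, C):
    """Independent two-stage oracle: explicit normal-equations residuals,
    then a plain Pearson correlation."""
    X = np.column_stack([np.ones(len(x)), C])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    rx, ry = x - H @ x, y - H @ y
    return float(stats.pearsonr(rx, ry)[0])


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert partial_correlation(x, y).statistic == pytest.approx(
            pearson(x, y).statistic, abs=1e-12)

    def test_matches_two_stage_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = 60
            C = rng.normal(size=(n, 3))
            x, y = rng.normal(size=n), rng.normal(size=n)
            ours = partial_correlation(x, y, C).statistic
            assert ours == pytest.approx(_oracle_partial(x, y, C), abs=1e-12)

    def test_shared_covariate_removed(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=1000)
        x = z + rng.normal(size=1000)
        y = z + rng.normal(size=1000)
        assert abs(pearson(x, y).statistic) > 0.3
        assert abs(partial_correlation(x, y, z[:, None]).statistic) < 0.1

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(3)
        c1 = rng.normal(size=30)
        C = pd.DataFrame({"wbv": c1, "wbv_copy": 2 * c1})
        with pytest.raises(ValueError, match="wbv"):
            partial_correlation(rng.normal(size=30), rng.normal(size=30), C)

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="n >"):
            partial_correlation([1.0, 2, 3], [3.0, 2, 1], np.ones((3, 2)))

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_partial_r_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        r = partial_correlation(rng.normal(size=n), rng.normal(size=n),
                                rng.normal(size=(n, 2)))
        assert -1.0 <= r.statistic <= 1.0
        assert 0.0 <= r.p_value <= 1.0


class TestBonferroni:
    def test_default_battery_threshold(self):
        thr = bonferroni_threshold(0.05, 24)
        assert thr == pytest.approx(0.05 / 24)
        assert round(thr, 3) == 0.002

    def test_edge_cases(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 10) == pytest.approx(0.001)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestBattery:
    def test_default_battery_has_24_rows(self, surrogate_scores):
        rng = np.random.default_rng(10)
        scores = surrogate_scores(70, rng)
        vols = generate_volumes(scores, 0.3, seed=11)
        table, report = association_battery(vols, scores)
        assert len(table) == 24
        assert report["n_tests"] == 24
        assert report["bonferroni_threshold"] == pytest.approx(0.05 / 24)
        assert ((table["p_value"] < report["bonferroni_threshold"])
                == table["significant_bonferroni"]).all()

    def test_single_cell_battery(self, surrogate_scores):
        rng = np.random.default_rng(12)
        scores = surrogate_scores(40, rng)
        vols = generate_volumes(scores, 0.0, seed=13)
        table, report = association_battery(
            vols, scores, dd_parameters=("sbs_mean",), regions=("caudate",))
        assert len(table) == 2  # one region, both hemispheres
        table1, report1 = association_battery(
            vols, scores, dd_parameters=("sbs_mean",), regions=("caudate",))
        assert report1["bonferroni_threshold"] == pytest.approx(0.05 / 2)

    def test_row_order_invariance(self, surrogate_scores):
        rng = np.random.default_rng(14)
        scores = surrogate_scores(50, rng)
        vols = generate_volumes(scores, 0.2, seed=15)
        a, _ = association_battery(vols, scores)
        b, _ = association_battery(vols.sample(frac=1.0, random_state=1),
                                   scores.sample(frac=1.0, random_state=2))
        pd.testing.assert_frame_equal(a, b)

    def test_planted_caudate_ranks_high(self, surrogate_scores):
        """With a planted caudate-SbS effect (r = 0.3, n = 70) both caudate
        rows usually lead the battery by |partial r|."""
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(100):
            scores = surrogate_scores(70, rng)
            vols = generate_volumes(scores, 0.3, seed=int(rng.integers(2**31)))
            table, _ = association_battery(vols, scores)
            lead = table.reindex(
                table["partial_r"].abs().sort_values(ascending=False).index).head(4)
            caud = (lead["region"] == "caudate") & (lead["dd_parameter"] == "sbs_mean")
            hits += caud.sum() >= 2
        assert hits >= 65

    def test_dropped_and_missing_subjects_reported(self, surrogate_scores):
        rng = np.random.default_rng(16)
        scores = surrogate_scores(40, rng)
        vols = generate_volumes(scores, 0.0, seed=17)
        vols_short = vols.iloc[:-3].copy()
        vols_short.loc[vols_short.index[0], "left_caudate"] = np.nan
        table, report = association_battery(vols_short, scores)
        assert report["n_subjects"] == 36
        assert len(report["dropped_subjects"]) == 4

    def test_disjoint_subjects_rejected(self, surrogate_scores):
        rng = np.random.default_rng(18)
        scores = surrogate_scores(30, rng)
        vols = generate_volumes(scores, 0.0, seed=19)
        vols["subject"] = ["x" + s for s in vols["subject"]]
        with pytest.raises(ValueError, match="overlap"):
            association_battery(vols, scores)


class TestCalibration:
    def test_null_fwe_and_uncorrected_rate(self, surrogate_scores):
        """No planted effect: ~5% of cells significant uncorrected, and the
        family-wise error rate at the Bonferroni threshold stays below 5%
        (1000 replicates, n = 40)."""
        rng = np.random.default_rng(0)
        fwe, unc = 0, []
        for rep in range(1000):
            scores = surrogate_scores(40, rng)
            vols = generate_volumes(scores, 0.0, seed=int(rng.integers(2**31)))
            table, _ = association_battery(vols, scores)
            unc.append((table["p_value"] < 0.05).mean())
            fwe += table["significant_bonferroni"].any()
        assert fwe / 1000 <= 0.05
        assert np.mean(unc) == pytest.approx(0.05, abs=0.01)
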