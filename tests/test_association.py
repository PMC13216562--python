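"""Tests of correlations, partial correlations, standardized regression and
multiplicity adjustment."""

import numpy as np
import pandas as pd
import pytest

from truthsdt import (CohortConfig, adjust_pvalues, correlation_screen,
                      generate_cohort, partial_r, pearson_r, score_cohort,
                      split_half_fa_regression, standardized_ols)
from truthsdt.exceptions import (CollinearityError, DegenerateCovariateError,
                                 UndefinedCorrelationError, ValidationError)


class TestPearson:
    def test_identity(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)

    def test_negative_affine(self):
        x = np.arange(10.0)
        assert pearson_r(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_covariance_oracle(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        r, _ = pearson_r(x, y)
        oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartial:
    def test_reduces_to_pearson_without_covariate_signal(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 5000))
        z = rng.normal(size=5000)
        r_plain, _ = pearson_r(x, y)
        r_part, _ = partial_r(x, y, z)
        assert r_part == pytest.approx(r_plain, abs=0.05)

    def test_collinear_covariate(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateCovariateError):
            partial_r(x, np.random.default_rng(1).normal(size=10), x)

    def test_shared_covariate_partials_out(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=10_000)
        x = z + rng.normal(size=10_000)
        y = z + rng.normal(size=10_000)
        r, _ = partial_r(x, y, z)
        assert abs(r) < 0.05

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("xyz"))
        df["y"] += 0.5 * df["x"] + 0.3 * df["z"]
        r, p = partial_r(df["x"], df["y"], df["z"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


class TestStandardizedOLS:
    def test_single_predictor_equals_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        y = 0.4 * x + rng.normal(size=100)
        res = standardized_ols(y, pd.DataFrame({"x": x}))
        assert res.betas["x"] == pytest.approx(pearson_r(x, y)[0], rel=1e-10)

    def test_perfect_fit(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 2 * X["a"] - X["b"]
        res = standardized_ols(y, X)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = rng.normal(size=50)
        res = standardized_ols(y, X)
        Xz = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        yz = (y - y.mean()) / y.std(ddof=1)
        oracle = np.linalg.solve(Xz.T @ Xz, Xz.T @ yz)
        assert np.allclose(res.betas.to_numpy(), oracle, atol=1e-8)

    def test_rank_deficiency(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(CollinearityError):
            standardized_ols(np.random.default_rng(7).normal(size=10), X)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_holm_hand_computed(self):
        # step-down: 3*0.01=0.03; 2*0.02=0.04; max(1*0.03, 0.04)=0.04
        adj = adjust_pvalues([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_boundary(self):
        assert np.allclose(adjust_pvalues([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=45)
        adj = adjust_pvalues(p)
        assert (adj >= p).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.5])


def _scored_cohort(**kw):
    cfg_kw = dict(n_per_group=150, items_per_cell=20, traits=(), seed=13)
    cfg_kw.update(kw)
    cohort = generate_cohort(CohortConfig(**cfg_kw))
    groups = cohort.participants["group"]
    odd = score_cohort(cohort.judgments, cohort.bank, groups, split="odd")
    even = score_cohort(cohort.judgments, cohort.bank, groups, split="even")
    return cohort, odd, even


class TestSplitHalfRegression:
    def test_sign_pattern_heterogeneous_cohort(self):
        _, odd, even = _scored_cohort()
        for res in split_half_fa_regression(odd, even):
            signs = np.sign(res.betas[["d_prime", "c_overall", "myside"]])
            if res.outcome_name == "fa_congruent":
                assert signs.tolist() == [-1, -1, 1]
            else:
                assert signs.tolist() == [-1, -1, -1]

    def test_null_bias_cohort_myside_beta_small(self):
        _, odd, even = _scored_cohort(myside_dist=(0.0, 0.0))
        for res in split_half_fa_regression(odd, even):
            assert abs(res.betas["myside"]) < 0.15

    def test_criterion_variance_dominates(self):
        _, odd, even = _scored_cohort(dprime_dist=(0.5, 0.0),
                                      myside_dist=(0.0, 0.0),
                                      criterion_dist=(0.3, 0.6))
        for res in split_half_fa_regression(odd, even):
            assert abs(res.betas["c_overall"]) > abs(res.betas["d_prime"])
            assert abs(res.betas["c_overall"]) > abs(res.betas["myside"])

    def test_predictors_independent_of_outcome_items(self):
        """Predictor scores come only from the opposite half: replacing the
        outcome half's responses leaves predictors (and betas' design
        matrix) unchanged."""
        cohort, odd, even = _scored_cohort()
        groups = cohort.participants["group"]
        scrambled = cohort.judgments.copy()
        even_items = cohort.bank.loc[cohort.bank["order_index"] % 2 == 0,
                                     "item_id"]
        rng = np.random.default_rng(0)
        scrambled[even_items] = rng.integers(0, 2, scrambled[even_items].shape
                                             ).astype(bool)
        odd_again = score_cohort(scrambled, cohort.bank, groups, split="odd")
        pd.testing.assert_frame_equal(odd, odd_again)

    def test_index_mismatch_rejected(self):
        _, odd, even = _scored_cohort()
        with pytest.raises(ValidationError):
            split_half_fa_regression(odd.iloc[:-1], even)


class TestCorrelationScreen:
    def test_shape_and_adjustment_families(self, cohort, scored):
        from truthsdt import score_all
        traits, _ = score_all(cohort.participants)
        screen = correlation_screen(traits, scored["all"],
                                    group=cohort.participants["group"])
        assert len(screen) == 15 * 4
        assert (screen["p_adjusted"] >= screen["p"] - 1e-15).all()
        assert screen["r"].abs().le(1.0).all()
        # the SDT-index family has 45 members; a Bonferroni-dominating bound
        sdt_rows = screen[screen["index"] != "fa_rate"]
        assert np.all(sdt_rows["p_adjusted"] <=
                      np.minimum(1.0, 45 * sdt_rows["p"] + 1e-12))

    def test_partial_columns_present(self, cohort, scored):
        from truthsdt import score_all
        traits, _ = score_all(cohort.participants)
        screen = correlation_screen(traits, scored["all"],
                                    group=cohort.participants["group"])
        assert {"partial_r", "partial_p", "partial_p_adjusted"} <= \
            set(screen.columns)
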