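"""Association analyses: split-half regressions, correlation screens,
partial correlations and multiplicity adjustment.

The split-half (odd/even) design guarantees mathematical independence of
predictors and outcome: the three SDT indices (d', c, myside) are computed
from one item half and predict the corrected false-alarm rate of the other
half, separately for congruent and incongruent misinformation and in both
directions.  Trait screens correlate each trait score with the false-alarm
rate and the three SDT indices, optionally partialling out group membership,
with Holm step-down adjustment over the trait x index family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (CollinearityError, DegenerateCovariateError,
                         UndefinedCorrelationError, ValidationError)

SDT_PREDICTORS = ("d_prime", "c_overall", "myside")
SCREEN_OUTCOMES = ("fa_rate", "d_prime", "c_overall", "myside")


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if len(x) < 4:
        raise ValidationError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def partial_r(x, y, covariate) -> tuple[float, float]:
    """First-order partial correlation of x and y controlling one covariate.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), with a
    two-sided t-test on n - 3 df.  The covariate may be a binary group dummy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValidationError("x, y and covariate must be equal-length vectors")
    r_xy, _ = pearson_r(x, y)
    r_xz, _ = pearson_r(x, z)
    r_yz, _ = pearson_r(y, z)
    denom = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom <= 1e-12:
        raise DegenerateCovariateError("covariate collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    df = len(x) - 3
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p)


@dataclass
class RegressionResult:
    """One standardized multiple regression."""

    outcome_name: str
    direction: str                # "even_to_odd" | "odd_to_even" | "none"
    betas: pd.Series              # standardized coefficients per predictor
    p_values: pd.Series
    r_squared: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"beta": self.betas, "p": self.p_values})
        out.insert(0, "outcome", self.outcome_name)
        out.insert(1, "direction", self.direction)
        out["r_squared"] = self.r_squared
        out["n"] = self.n
        return out.rename_axis("predictor").reset_index()


def standardized_ols(y, X: pd.DataFrame, outcome_name: str = "y",
                     direction: str = "none") -> RegressionResult:
    """OLS on z-scored outcome and predictors; betas are standardized.

    With a single predictor the beta equals the Pearson correlation.
    Classical (non-robust) standard errors.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    n, k = X.shape
    if n <= k + 1:
        raise ValidationError("need n > number of predictors + 1")
    sds = X.std(ddof=1)
    if (sds == 0).any() or np.std(y, ddof=1) == 0:
        raise CollinearityError("zero-variance column")
    Xz = (X - X.mean()) / sds
    if np.linalg.matrix_rank(Xz.to_numpy()) < k:
        raise CollinearityError("rank-deficient predictor matrix")
    yz = (y - y.mean()) / y.std(ddof=1)
    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    betas = fit.params.drop("const")
    pvals = fit.pvalues.drop("const")
    return RegressionResult(outcome_name, direction, betas, pvals,
                            float(fit.rsquared), n)


def split_half_fa_regression(scores_odd: pd.DataFrame,
                             scores_even: pd.DataFrame,
                             ) -> list[RegressionResult]:
    """The four cross-half regressions: {congruent, incongruent} FA x
    {even -> odd, odd -> even}.

    ``scores_odd`` / ``scores_even`` are per-participant score frames from
    ``sdt.score_cohort`` on the two item halves; predictors (d', c, myside)
    come from the opposite half as the outcome.
    """
    if not scores_odd.index.equals(scores_even.index):
        raise ValidationError("both splits must be scored for all participants")
    halves = {"odd": scores_odd, "even": scores_even}
    results = []
    for pred_half, out_half in (("even", "odd"), ("odd", "even")):
        X = halves[pred_half][list(SDT_PREDICTORS)]
        for outcome in ("fa_congruent", "fa_incongruent"):
            y = halves[out_half][outcome]
            results.append(standardized_ols(
                y, X, outcome_name=outcome,
                direction=f"{pred_half}_to_{out_half}"))
    return results


def adjust_pvalues(p_list, method: str = "holm") -> np.ndarray:
    """Adjusted p-values over one test family (Holm step-down by default,
    Bonferroni available)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def correlation_screen(traits: pd.DataFrame, sdt_scores: pd.DataFrame,
                       group: pd.Series | None = None,
                       adjust: str = "holm") -> pd.DataFrame:
    """Trait x {FA rate, d', c, myside} correlation screen.

    Returns a tidy frame with r, p and family-adjusted p.  The adjustment
    family for the three SDT indices is their full trait x factor crossing
    (45 tests with the 15 bundled traits); the FA-rate column forms its own
    family.  When ``group`` is given, adds the partial correlation
    controlling for a 0/1 group dummy.
    """
    outcomes = sdt_scores[list(SCREEN_OUTCOMES)]
    if not traits.index.equals(outcomes.index):
        traits = traits.reindex(outcomes.index)
        if traits.isna().any().any():
            raise ValidationError("traits and scores index mismatch")
    dummy = None
    if group is not None:
        labels = pd.unique(group.reindex(outcomes.index))
        dummy = (group.reindex(outcomes.index) == labels[0]).astype(float)
    rows = []
    for trait in traits.columns:
        for outcome in SCREEN_OUTCOMES:
            r, p = pearson_r(traits[trait], outcomes[outcome])
            row = {"trait": trait, "index": outcome, "r": r, "p": p}
            if dummy is not None:
                pr, pp = partial_r(traits[trait], outcomes[outcome], dummy)
                row["partial_r"], row["partial_p"] = pr, pp
            rows.append(row)
    screen = pd.DataFrame(rows)
    sdt_family = screen["index"] != "fa_rate"
    for raw, adj in (("p", "p_adjusted"), ("partial_p", "partial_p_adjusted")):
        if raw not in screen.columns:
            continue
        screen[adj] = np.nan
        for fam in (sdt_family, ~sdt_family):
            screen.loc[fam, adj] = adjust_pvalues(
                screen.loc[fam, raw].to_numpy(), adjust)
    return screen
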