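"""Bifactor structural model fit by maximum likelihood on a covariance matrix.

The model has one general factor loading on every indicator plus orthogonal
specific factors for disjoint indicator subsets; outcome variables (the
odd/even-half truth-sensitivity scores) are regressed on all factors.  With
factor covariance fixed to the identity and the structural paths folded into
the outcome rows of the loading matrix, the implied covariance is

    Sigma(theta) = Lambda Lambda' + Theta,   Theta diagonal,

and the ML discrepancy minimized is

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p,

which is nonnegative and zero iff Sigma = S.  Identification fixes factor
variances to 1 with all loadings free.  The fit uses multiple seeded random
starts with analytic gradients; standard errors come from the inverse
observed information (2/(n-1) * H^-1 with H the discrepancy Hessian), and
standardized estimates rescale each observed row by its implied standard
deviation (delta-method SEs under the same scaling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import ConfigurationError, ValidationError

_THETA_FLOOR = 1e-8


@dataclass(frozen=True)
class BifactorSpec:
    """Model structure: indicators, their specific-factor membership, the
    general factor and the outcome variables."""

    indicators: tuple[str, ...]
    specific_map: Mapping[str, str] = field(default_factory=dict)
    outcomes: tuple[str, ...] = ()
    general_name: str = "ROM"

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "specific_map", dict(self.specific_map))
        extra = set(self.specific_map) - set(self.indicators)
        if extra:
            raise ConfigurationError(f"specific_map has unknown indicators: "
                                     f"{sorted(extra)}")
        if self.specific_map and set(self.specific_map) != set(self.indicators):
            raise ConfigurationError(
                "every indicator must load on exactly one specific factor "
                "(or pass an empty specific_map for a one-factor model)")
        if self.general_name in self.specific_map.values():
            raise ConfigurationError("general factor name collides with a "
                                     "specific factor")
        if set(self.indicators) & set(self.outcomes):
            raise ConfigurationError("indicators and outcomes must be disjoint")

    @property
    def factor_names(self) -> tuple[str, ...]:
        specifics = sorted(set(self.specific_map.values()))
        return (self.general_name, *specifics)

    @property
    def observed(self) -> tuple[str, ...]:
        return (*self.indicators, *self.outcomes)

    @property
    def n_free(self) -> int:
        return (len(self.indicators) + len(self.specific_map)
                + len(self.outcomes) * len(self.factor_names)
                + len(self.observed))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "indicators": list(self.indicators),
            "specific_map": dict(self.specific_map),
            "outcomes": list(self.outcomes),
            "general_name": self.general_name,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BifactorSpec":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["indicators"]), d.get("specific_map", {}),
                   tuple(d.get("outcomes", ())),
                   d.get("general_name", "ROM"))


def rom_default_spec(n_parcels: int = 3) -> BifactorSpec:
    """Default reflective-open-mindedness model: parcels of cognitive
    reflection, bullshit receptivity, conspiracy mentality and actively
    open-minded thinking, predicting odd/even truth sensitivity."""
    indicators, smap = [], {}
    for fac, stem in (("CR", "cr"), ("BS", "bs"), ("CM", "cm"), ("AOT", "aot")):
        for j in range(1, n_parcels + 1):
            name = f"{stem}_p{j}"
            indicators.append(name)
            smap[name] = fac
    return BifactorSpec(tuple(indicators), smap, ("ts_odd", "ts_even"))


# ---------------------------------------------------------------------------
# parameter vector layout:
#   [ general loadings (n_ind) | specific loadings (mapped indicators, in
#     indicator order) | paths (n_out x n_fac, row-major) | residuals (n_obs) ]
# ---------------------------------------------------------------------------

def _layout(spec: BifactorSpec):
    n_ind = len(spec.indicators)
    mapped = [i for i, name in enumerate(spec.indicators)
              if name in spec.specific_map]
    n_out = len(spec.outcomes)
    n_fac = len(spec.factor_names)
    n_obs = n_ind + n_out
    sizes = (n_ind, len(mapped), n_out * n_fac, n_obs)
    offsets = np.cumsum((0,) + sizes)
    return mapped, n_ind, n_out, n_fac, n_obs, offsets


def build_lambda(spec: BifactorSpec, params: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Unpack a flat parameter vector into (Lambda, theta_diagonal)."""
    mapped, n_ind, n_out, n_fac, n_obs, off = _layout(spec)
    params = np.asarray(params, dtype=float)
    if params.size != off[-1]:
        raise ValidationError(
            f"parameter vector has {params.size} entries, expected {off[-1]}")
    fac_col = {f: j for j, f in enumerate(spec.factor_names)}
    lam = np.zeros((n_obs, n_fac))
    lam[:n_ind, 0] = params[off[0]:off[1]]
    for k, i in enumerate(mapped):
        lam[i, fac_col[spec.specific_map[spec.indicators[i]]]] = \
            params[off[1] + k]
    lam[n_ind:, :] = params[off[2]:off[3]].reshape(n_out, n_fac)
    theta = params[off[3]:off[4]]
    return lam, theta


def pack_params(spec: BifactorSpec, loadings: pd.DataFrame,
                residuals: pd.Series) -> np.ndarray:
    """Flatten a loading table (observed x factors) and residual vector into
    the parameter layout used by the fitter."""
    mapped, n_ind, n_out, n_fac, n_obs, off = _layout(spec)
    loadings = loadings.reindex(index=spec.observed,
                                columns=spec.factor_names).fillna(0.0)
    out = np.empty(off[-1])
    out[off[0]:off[1]] = loadings.iloc[:n_ind, 0]
    for k, i in enumerate(mapped):
        fac = spec.specific_map[spec.indicators[i]]
        out[off[1] + k] = loadings.iloc[i][fac]
    out[off[2]:off[3]] = loadings.iloc[n_ind:].to_numpy().ravel()
    out[off[3]:off[4]] = residuals.reindex(spec.observed).to_numpy()
    return out


def implied_covariance(spec: BifactorSpec, params: np.ndarray) -> np.ndarray:
    """Sigma(theta) = Lambda Lambda' + diag(theta); symmetric by construction."""
    lam, theta = build_lambda(spec, params)
    return lam @ lam.T + np.diag(theta)


def _discrepancy_and_grad(params, spec, S, log_det_S):
    lam, theta = build_lambda(spec, params)
    sigma = lam @ lam.T + np.diag(theta)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(params)
    p = S.shape[0]
    log_det = 2.0 * np.log(np.diag(L)).sum()
    sigma_inv = np.linalg.inv(sigma)
    F = log_det + float(np.trace(sigma_inv @ S)) - log_det_S - p
    A = sigma_inv - sigma_inv @ S @ sigma_inv       # dF = tr(A dSigma)
    g_lam = 2.0 * A @ lam
    mapped, n_ind, n_out, n_fac, n_obs, off = _layout(spec)
    fac_col = {f: j for j, f in enumerate(spec.factor_names)}
    grad = np.empty_like(params)
    grad[off[0]:off[1]] = g_lam[:n_ind, 0]
    for k, i in enumerate(mapped):
        grad[off[1] + k] = g_lam[i, fac_col[spec.specific_map[spec.indicators[i]]]]
    grad[off[2]:off[3]] = g_lam[n_ind:, :].ravel()
    grad[off[3]:off[4]] = np.diag(A)
    return F, grad


@dataclass
class BifactorFit:
    """Fitted bifactor model.

    ``loadings`` holds indicator loadings and (in the outcome rows) the
    structural paths, one column per factor; ``residuals`` the diagonal
    uniquenesses.  ``standardized`` marks whether the estimates are on the
    correlation (unit observed variance) metric.
    """

    spec: BifactorSpec
    loadings: pd.DataFrame
    residuals: pd.Series
    se_loadings: pd.DataFrame
    se_residuals: pd.Series
    discrepancy: float
    n: int
    converged: bool
    heywood: bool
    standardized: bool = False

    @property
    def structural_paths(self) -> pd.DataFrame:
        return self.loadings.loc[list(self.spec.outcomes)]

    def params(self) -> np.ndarray:
        return pack_params(self.spec, self.loadings, self.residuals)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for obs in self.spec.observed:
            kind = "path" if obs in self.spec.outcomes else "loading"
            for fac in self.spec.factor_names:
                est = self.loadings.loc[obs, fac]
                if est != 0.0 or (kind == "path"):
                    rows.append({"parameter": f"{obs}~{fac}", "kind": kind,
                                 "estimate": est,
                                 "se": self.se_loadings.loc[obs, fac]})
            rows.append({"parameter": f"{obs}~~{obs}", "kind": "residual",
                         "estimate": self.residuals[obs],
                         "se": self.se_residuals[obs]})
        return pd.DataFrame(rows)


def _canonical_signs(lam: np.ndarray, n_ind: int) -> np.ndarray:
    """Resolve per-factor sign indeterminacy: make each factor's summed
    indicator loading nonnegative (general factor over all indicators,
    specific factors over their block)."""
    lam = lam.copy()
    for j in range(lam.shape[1]):
        block = lam[:n_ind, j]
        if block.sum() < 0:
            lam[:, j] = -lam[:, j]
    return lam


def fit_ml(sample_cov, n: int, spec: BifactorSpec, n_starts: int = 20,
           seed: int = 0, gtol: float = 1e-8, max_iter: int = 2000
           ) -> BifactorFit:
    """Fit the model to a sample covariance matrix by maximum likelihood.

    ``sample_cov`` may be a DataFrame (reindexed to ``spec.observed``) or an
    array in that order.  Multiple seeded random starts; the best local
    optimum is kept, non-convergence is flagged rather than raised, and a
    Heywood case (residual variance at the zero bound) sets ``heywood``.
    """
    if isinstance(sample_cov, pd.DataFrame):
        missing = set(spec.observed) - set(sample_cov.columns)
        if missing:
            raise ValidationError(f"sample_cov missing variables: "
                                  f"{sorted(missing)}")
        S = sample_cov.loc[list(spec.observed), list(spec.observed)].to_numpy()
    else:
        S = np.asarray(sample_cov, dtype=float)
    p = len(spec.observed)
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValidationError("sample_cov must be a symmetric p x p matrix")
    sign, log_det_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValidationError("sample covariance matrix is singular")
    if n <= spec.n_free:
        raise ValidationError("n must exceed the number of free parameters")

    mapped, n_ind, n_out, n_fac, n_obs, off = _layout(spec)
    diag = np.diag(S)
    base = np.empty(off[-1])
    base[off[0]:off[1]] = 0.7 * np.sqrt(diag[:n_ind])
    base[off[1]:off[2]] = 0.4 * np.sqrt(diag[mapped]) if mapped else 0.0
    base[off[2]:off[3]] = 0.1
    base[off[3]:off[4]] = 0.5 * diag

    bounds = [(None, None)] * off[3] + \
             [(_THETA_FLOOR, None)] * (off[4] - off[3])
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = base if s == 0 else base * rng.uniform(0.3, 1.7, base.size)
        res = minimize(_discrepancy_and_grad, x0, args=(spec, S, log_det_S),
                       jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter, "ftol": 1e-14,
                                "gtol": gtol})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ValidationError("optimization failed from every start")

    params = best.x
    _, grad = _discrepancy_and_grad(params, spec, S, log_det_S)
    at_bound = params[off[3]:off[4]] <= _THETA_FLOOR * 10
    free_grad = np.concatenate([grad[:off[3]], grad[off[3]:][~at_bound]])
    converged = bool(np.linalg.norm(free_grad, np.inf) < 1e-4)
    heywood = bool(at_bound.any())

    lam, theta = build_lambda(spec, params)
    lam = _canonical_signs(lam, n_ind)
    params = pack_params(
        spec,
        pd.DataFrame(lam, index=spec.observed, columns=spec.factor_names),
        pd.Series(theta, index=spec.observed))

    se = _standard_errors(params, spec, S, log_det_S, n)
    se_lam, se_theta = build_lambda(spec, se)
    obs = list(spec.observed)
    return BifactorFit(
        spec=spec,
        loadings=pd.DataFrame(lam, index=obs, columns=spec.factor_names),
        residuals=pd.Series(theta, index=obs, name="residual_variance"),
        se_loadings=pd.DataFrame(np.abs(se_lam), index=obs,
                                 columns=spec.factor_names),
        se_residuals=pd.Series(np.abs(se_theta), index=obs, name="se"),
        discrepancy=float(best.fun), n=n, converged=converged,
        heywood=heywood)


def _standard_errors(params, spec, S, log_det_S, n) -> np.ndarray:
    """Delta-method SEs from the numerically differentiated discrepancy
    Hessian: acov = 2/(n-1) * H^-1."""
    k = params.size
    H = np.empty((k, k))
    eps = 1e-5 * np.maximum(np.abs(params), 1.0)
    for j in range(k):
        hi, lo = params.copy(), params.copy()
        hi[j] += eps[j]
        lo[j] -= eps[j]
        _, g_hi = _discrepancy_and_grad(hi, spec, S, log_det_S)
        _, g_lo = _discrepancy_and_grad(lo, spec, S, log_det_S)
        H[:, j] = (g_hi - g_lo) / (2.0 * eps[j])
    H = 0.5 * (H + H.T)
    acov = 2.0 / (n - 1) * np.linalg.pinv(H)
    return np.sqrt(np.clip(np.diag(acov), 0.0, None))


def standardize_solution(fit: BifactorFit, sample_cov=None) -> BifactorFit:
    """Rescale estimates to unit observed variance (correlation metric).

    Idempotent; factor variances are already 1, so only observed rows are
    rescaled by the implied standard deviations.
    """
    if fit.standardized:
        return fit
    if not fit.converged:
        raise ValidationError("cannot standardize a non-converged fit")
    sigma = implied_covariance(fit.spec, fit.params())
    sd = np.sqrt(np.diag(sigma))
    if np.any(sd <= 0):
        raise ValidationError("zero implied variance")
    scale = pd.Series(1.0 / sd, index=fit.spec.observed)
    return replace(
        fit,
        loadings=fit.loadings.mul(scale, axis=0),
        residuals=fit.residuals * scale ** 2,
        se_loadings=fit.se_loadings.mul(scale, axis=0),
        se_residuals=fit.se_residuals * scale ** 2,
        standardized=True)


def simulate_bifactor(spec: BifactorSpec, loadings: pd.DataFrame,
                      residuals: pd.Series, n: int,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw ``n`` observations from the model (standard-normal orthogonal
    factors, Gaussian uniquenesses)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    params = pack_params(spec, loadings, residuals)
    lam, theta = build_lambda(spec, params)
    if np.any(theta < 0):
        raise ConfigurationError("residual variances must be nonnegative")
    f = rng.standard_normal((n, lam.shape[1]))
    e = rng.standard_normal((n, lam.shape[0])) * np.sqrt(theta)
    return pd.DataFrame(f @ lam.T + e, columns=spec.observed)
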