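"""Scoring of the 15 individual-difference measures and reliability estimation.

Likert scales are scored as the item mean after recoding reverse-keyed items
(r -> min + max - r); performance scales (cognitive reflection, narcissism
inventory) are summed 0/1 correctness/endorsement counts; identification
with likeminded people is the mean item-wise difference between two rating
blocks ("people who share my views" minus "all humanity").

Internal consistency is Cronbach's alpha

    alpha = k/(k-1) * (1 - sum(item variances) / var(row sums))

which for binary items coincides with KR-20.  The reliability of the SDT
indices themselves is estimated by splitting each veracity x congruence cell
into order-based item parcels, scoring the index per parcel and taking alpha
across parcel scores.  The bundled registry is an editable stand-in for the
cited instruments; item wording and exact reverse-key sets belong to those
instruments, not to this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import (ConfigurationError, UndefinedReliabilityError,
                         ValidationError)

AGGREGATIONS = ("mean", "sum", "difference_of_means")


@dataclass(frozen=True)
class ScaleSpec:
    """Structure of one measure: length, response range, reverse-keyed items
    (1-based) and how item responses aggregate into a score."""

    scale_name: str
    n_items: int
    response_min: int
    response_max: int
    reverse_items: frozenset[int] = frozenset()
    aggregation: str = "mean"

    def __post_init__(self):
        if self.response_min >= self.response_max:
            raise ConfigurationError("response_min must be < response_max")
        if self.aggregation not in AGGREGATIONS:
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        bad = set(self.reverse_items) - set(range(1, self.n_items + 1))
        if bad:
            raise ConfigurationError(f"reverse_items out of range: {sorted(bad)}")


def load_scale_registry(path: str | Path | None = None) -> dict[str, ScaleSpec]:
    """Load a scale registry from JSON (the bundled one by default)."""
    if path is None:
        text = (resources.files("truthsdt") / "data" /
                "scale_registry.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return {
        name: ScaleSpec(scale_name=name,
                        n_items=entry["n_items"],
                        response_min=entry["response_min"],
                        response_max=entry["response_max"],
                        reverse_items=frozenset(entry.get("reverse_items", [])),
                        aggregation=entry.get("aggregation", "mean"))
        for name, entry in raw.items()
    }


_REGISTRY_CACHE: dict[str, ScaleSpec] | None = None


def default_registry() -> dict[str, ScaleSpec]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = load_scale_registry()
    return dict(_REGISTRY_CACHE)


def _validate_responses(resp: np.ndarray, spec: ScaleSpec) -> None:
    if resp.ndim == 1 and len(resp) != spec.n_items:
        raise ValidationError(
            f"{spec.scale_name}: expected {spec.n_items} responses, "
            f"got {len(resp)}")
    if np.isnan(resp).any():
        raise ValidationError(f"{spec.scale_name}: missing responses are "
                              "rejected, not imputed")
    if resp.min() < spec.response_min or resp.max() > spec.response_max:
        raise ValidationError(f"{spec.scale_name}: responses outside "
                              f"[{spec.response_min}, {spec.response_max}]")


def reverse_code(responses, spec: ScaleSpec) -> np.ndarray:
    """Recode reverse-keyed items as min + max - r (an involution)."""
    out = np.array(responses, dtype=float)
    idx = np.fromiter(spec.reverse_items, dtype=int) - 1
    if idx.size:
        out[..., idx] = spec.response_min + spec.response_max - out[..., idx]
    return out


def score_scale(responses, spec: ScaleSpec) -> float:
    """Score one participant's responses on one scale."""
    resp = np.asarray(responses, dtype=float)
    _validate_responses(resp, spec)
    if spec.aggregation == "difference_of_means":
        raise ValidationError(
            "difference scales take two rating blocks; use "
            "score_likeminded_identification")
    recoded = reverse_code(resp, spec)
    return float(recoded.sum() if spec.aggregation == "sum" else recoded.mean())


def score_likeminded_identification(ratings_likeminded,
                                    ratings_humanity) -> float:
    """Mean item-wise (likeminded - humanity) rating difference."""
    like = np.asarray(ratings_likeminded, dtype=float)
    hum = np.asarray(ratings_humanity, dtype=float)
    if like.shape != hum.shape:
        raise ValidationError("rating blocks must have equal length")
    if np.isnan(like).any() or np.isnan(hum).any():
        raise ValidationError("missing responses are rejected, not imputed")
    return float(np.mean(like - hum))


def cronbach_alpha(item_matrix) -> float:
    """alpha = k/(k-1) * (1 - sum item variances / variance of row sums).

    May be negative; undefined (error) when the row sums have no variance.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 items")
    if X.shape[0] < 3:
        raise ValidationError("need >= 3 participants")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedReliabilityError("zero total-score variance")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def score_all(participants: pd.DataFrame,
              registry: dict[str, ScaleSpec] | None = None,
              ) -> tuple[pd.DataFrame, pd.Series]:
    """Score every registry scale found in a wide participant table.

    Item columns are named ``<scale>_<i>`` (``<scale>_like_<i>`` /
    ``<scale>_hum_<i>`` for difference scales).  Returns per-participant
    trait scores and per-scale Cronbach's alpha.
    """
    registry = registry or default_registry()
    scores, alphas = {}, {}
    for name, spec in registry.items():
        if spec.aggregation == "difference_of_means":
            like_cols = [f"{name}_like_{j + 1}" for j in range(spec.n_items)]
            hum_cols = [f"{name}_hum_{j + 1}" for j in range(spec.n_items)]
            if not set(like_cols) <= set(participants.columns):
                continue
            like = participants[like_cols].to_numpy(dtype=float)
            hum = participants[hum_cols].to_numpy(dtype=float)
            _validate_responses(like, spec)
            _validate_responses(hum, spec)
            diffs = like - hum
            scores[name] = diffs.mean(axis=1)
            alphas[name] = cronbach_alpha(diffs)
        else:
            cols = [f"{name}_{j + 1}" for j in range(spec.n_items)]
            if not set(cols) <= set(participants.columns):
                continue
            resp = participants[cols].to_numpy(dtype=float)
            _validate_responses(resp, spec)
            recoded = reverse_code(resp, spec)
            scores[name] = (recoded.sum(axis=1) if spec.aggregation == "sum"
                            else recoded.mean(axis=1))
            alphas[name] = cronbach_alpha(recoded)
    return (pd.DataFrame(scores, index=participants.index),
            pd.Series(alphas, name="cronbach_alpha"))


def _parcel_index(resp: np.ndarray, veracity: np.ndarray, in_parcel: np.ndarray,
                  congruent: np.ndarray, index: str) -> np.ndarray:
    """One SDT index per participant on the parcel's items (extreme-corrected
    with the parcel's own trial counts)."""
    def rate(mask):
        n = int(mask.sum())
        r = resp[:, mask].mean(axis=1)
        lo = 1.0 / (2.0 * n)
        return np.where(r == 0.0, lo, np.where(r == 1.0, 1.0 - lo, r))

    if index in ("d_prime", "c_overall"):
        zh = norm.ppf(rate(in_parcel & veracity))
        zfa = norm.ppf(rate(in_parcel & ~veracity))
        return zh - zfa if index == "d_prime" else -0.5 * (zh + zfa)
    if index == "myside":
        c_c = -0.5 * (norm.ppf(rate(in_parcel & veracity & congruent)) +
                      norm.ppf(rate(in_parcel & ~veracity & congruent)))
        c_i = -0.5 * (norm.ppf(rate(in_parcel & veracity & ~congruent)) +
                      norm.ppf(rate(in_parcel & ~veracity & ~congruent)))
        return c_i - c_c
    if index == "fa_rate":
        return rate(in_parcel & ~veracity)
    raise ValidationError(f"unknown index {index!r}")


def sdt_index_reliability(judgments: pd.DataFrame, bank: pd.DataFrame,
                          groups: pd.Series, index: str = "d_prime",
                          k_parcels: int = 4) -> float:
    """Parcel-based alpha for an SDT index.

    Each veracity x slant cell is split, in presentation order, into
    ``k_parcels`` contiguous item parcels; the index is computed per parcel
    and participant, and alpha is taken across parcel scores.  ``k_parcels``
    must divide the per-cell item count evenly.
    """
    cells = bank.groupby(["veracity", "slant"], sort=True)
    sizes = cells.size()
    if (sizes % k_parcels != 0).any():
        raise ConfigurationError(
            f"k_parcels={k_parcels} must divide every cell size "
            f"({sizes.min()}..{sizes.max()}) evenly")
    parcel_of = pd.Series(index=bank["item_id"], dtype=int)
    for _, cell in cells:
        ordered = cell.sort_values("order_index")["item_id"]
        chunk = len(ordered) // k_parcels
        for p in range(k_parcels):
            parcel_of[ordered.iloc[p * chunk:(p + 1) * chunk]] = p

    cols = bank["item_id"].to_numpy()
    resp = judgments[cols].to_numpy(dtype=float)
    veracity = bank["veracity"].to_numpy(dtype=bool)
    slant = bank["slant"].to_numpy()
    parcels = parcel_of[cols].to_numpy()
    grp = groups.reindex(judgments.index).to_numpy()

    parcel_scores = np.empty((len(judgments), k_parcels))
    for g in np.unique(grp):
        rows = grp == g
        congruent = slant == g
        for p in range(k_parcels):
            parcel_scores[rows, p] = _parcel_index(
                resp[rows], veracity, parcels == p, congruent, index)
    return cronbach_alpha(parcel_scores)
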