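"""Equal-variance Gaussian signal-detection scoring of binary truth judgments.

Judgments of true/false items as "true" define hits (true item judged true)
and false alarms (false item judged true).  Under the equal-variance Gaussian
model the two indices are

    d' = z(H) - z(FA)            truth sensitivity
    c  = -0.5 * [z(H) + z(FA)]   acceptance threshold (higher = more rejecting)

where z is the probit (inverse standard-normal CDF).  Myside bias is the
criterion difference between belief-incongruent and belief-congruent items:
a positive value means a lower threshold for accepting congruent claims.

Observed rates of exactly 0 or 1 are converted to 1/(2N) and 1 - 1/(2N)
(N = number of trials in the subset) before the probit transform.

The item bank is a DataFrame with columns ``item_id`` (str), ``veracity``
(bool, True = the claim is true), ``slant`` (one of two group labels) and
``order_index`` (1-based, contiguous presentation order; parity defines the
odd/even split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError

GROUP_LABELS = ("side_A", "side_B")
SPLITS = ("all", "odd", "even")

#: columns emitted by :func:`score_cohort`
SCORE_COLUMNS = (
    "d_prime", "c_overall", "c_congruent", "c_incongruent", "myside",
    "hit_rate", "fa_rate", "fa_congruent", "fa_incongruent",
)


@dataclass(frozen=True)
class SDTScores:
    """Per-participant signal-detection indices for one item split."""

    d_prime: float
    c_overall: float
    c_congruent: float
    c_incongruent: float
    myside: float
    hit_rate: float
    fa_rate: float
    fa_congruent: float
    fa_incongruent: float
    split: str = "all"


def congruence_of(group: str, slant: str) -> str:
    """Classify an item as congruent/incongruent for a participant.

    An item is congruent iff its slant matches the participant's group
    (e.g. a pro-Democrat headline is congruent for a Democrat).
    """
    if group not in GROUP_LABELS:
        raise ValidationError(f"unknown group label: {group!r}")
    if slant not in GROUP_LABELS:
        raise ValidationError(f"unknown slant label: {slant!r}")
    return "congruent" if group == slant else "incongruent"


def correct_extreme_rate(p: float, n_trials: int) -> float:
    """Replace a rate of exactly 0 or 1 with 1/(2N) or 1 - 1/(2N).

    Interior rates are returned unchanged.  ``n_trials`` is the number of
    trials the proportion was computed from.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"rate must be in [0, 1], got {p}")
    if p == 0.0:
        return 1.0 / (2.0 * n_trials)
    if p == 1.0:
        return 1.0 - 1.0 / (2.0 * n_trials)
    return p


def z_transform(p):
    """Probit of ``p``; domain error outside the open unit interval."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValidationError("z_transform requires rates strictly in (0, 1); "
                              "apply correct_extreme_rate first")
    out = norm.ppf(arr)
    return float(out) if np.isscalar(p) else out


def d_prime(hit_rate, fa_rate):
    """Truth sensitivity: z(H) - z(FA)."""
    return z_transform(hit_rate) - z_transform(fa_rate)


def criterion(hit_rate, fa_rate):
    """Acceptance threshold: -0.5 * [z(H) + z(FA)]."""
    return -0.5 * (z_transform(hit_rate) + z_transform(fa_rate))


def myside_bias(c_congruent, c_incongruent):
    """Criterion difference c_incongruent - c_congruent.

    Positive values mean a lower threshold for accepting belief-congruent
    than belief-incongruent claims.
    """
    return c_incongruent - c_congruent


def validate_item_bank(bank: pd.DataFrame) -> None:
    """Check the item-bank invariants (contiguous 1-based order, valid labels)."""
    required = {"item_id", "veracity", "slant", "order_index"}
    missing = required - set(bank.columns)
    if missing:
        raise ValidationError(f"item bank missing columns: {sorted(missing)}")
    n = len(bank)
    order = np.sort(bank["order_index"].to_numpy())
    if not np.array_equal(order, np.arange(1, n + 1)):
        raise ValidationError("order_index must be a permutation of 1..n_items")
    if bank["item_id"].duplicated().any():
        raise ValidationError("duplicate item_id in bank")
    bad = set(bank["slant"]) - set(GROUP_LABELS)
    if bad:
        raise ValidationError(f"unknown slant labels: {sorted(bad)}")


def select_split(bank: pd.DataFrame, split: str) -> pd.DataFrame:
    """Subset the bank to all items or the odd/even half by order_index parity."""
    if split == "all":
        return bank
    if split == "odd":
        return bank[bank["order_index"] % 2 == 1]
    if split == "even":
        return bank[bank["order_index"] % 2 == 0]
    raise ValidationError(f"unknown split: {split!r}")


def _corrected_rates(resp: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Column-masked mean of a participants x items 0/1 matrix with extreme-rate
    correction.  Returns (corrected rates per participant, n trials)."""
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("empty item subset after split/congruence selection")
    rates = resp[:, mask].mean(axis=1)
    lo = 1.0 / (2.0 * n)
    return np.where(rates == 0.0, lo, np.where(rates == 1.0, 1.0 - lo, rates)), n


def score_cohort(
    judgments: pd.DataFrame,
    bank: pd.DataFrame,
    groups: pd.Series,
    split: str = "all",
) -> pd.DataFrame:
    """Score every participant of a cohort on one item split.

    Parameters
    ----------
    judgments
        Wide boolean frame, participants x items; ``judgments.loc[p, i]`` is
        True iff participant ``p`` judged item ``i`` "true".  Columns must
        cover the split's items.
    bank
        Item bank frame (see module docstring).
    groups
        Participant group labels indexed like ``judgments``.
    split
        ``"all"``, ``"odd"`` or ``"even"`` (1-based order_index parity).

    Returns
    -------
    DataFrame indexed by participant with columns :data:`SCORE_COLUMNS`;
    all rates are extreme-corrected with the subset's own trial count.
    """
    validate_item_bank(bank)
    sub = select_split(bank, split)
    missing = set(sub["item_id"]) - set(judgments.columns)
    if missing:
        raise ValidationError(f"judgments missing items: {sorted(missing)[:5]} ...")
    groups = groups.reindex(judgments.index)
    if groups.isna().any():
        raise ValidationError("group labels missing for some participants")

    cols = sub["item_id"].to_numpy()
    resp = judgments[cols].to_numpy(dtype=float)
    veracity = sub["veracity"].to_numpy(dtype=bool)
    slant = sub["slant"].to_numpy()

    out = {c: np.empty(len(judgments)) for c in SCORE_COLUMNS}
    grp = groups.to_numpy()
    for g in np.unique(grp):
        rows = grp == g
        r = resp[rows]
        cong = slant == g

        h_all, _ = _corrected_rates(r, veracity)
        fa_all, _ = _corrected_rates(r, ~veracity)
        h_c, _ = _corrected_rates(r, veracity & cong)
        fa_c, _ = _corrected_rates(r, ~veracity & cong)
        h_i, _ = _corrected_rates(r, veracity & ~cong)
        fa_i, _ = _corrected_rates(r, ~veracity & ~cong)

        zh, zfa = norm.ppf(h_all), norm.ppf(fa_all)
        c_cong = -0.5 * (norm.ppf(h_c) + norm.ppf(fa_c))
        c_incong = -0.5 * (norm.ppf(h_i) + norm.ppf(fa_i))
        out["d_prime"][rows] = zh - zfa
        out["c_overall"][rows] = -0.5 * (zh + zfa)
        out["c_congruent"][rows] = c_cong
        out["c_incongruent"][rows] = c_incong
        out["myside"][rows] = c_incong - c_cong
        out["hit_rate"][rows] = h_all
        out["fa_rate"][rows] = fa_all
        out["fa_congruent"][rows] = fa_c
        out["fa_incongruent"][rows] = fa_i

    res = pd.DataFrame(out, index=judgments.index)
    res["split"] = split
    return res


def score_participant(
    judgments: Mapping[str, bool],
    bank: pd.DataFrame,
    group: str,
    split: str = "all",
) -> SDTScores:
    """Score a single participant; see :func:`score_cohort` for conventions."""
    if group not in GROUP_LABELS:
        raise ValidationError(f"unknown group label: {group!r}")
    wide = pd.DataFrame([dict(judgments)], index=["p"])
    row = score_cohort(wide, bank, pd.Series({"p": group}), split=split).iloc[0]
    return SDTScores(*(float(row[c]) for c in SCORE_COLUMNS), split=split)


def rates_summary(judgments: pd.DataFrame, bank: pd.DataFrame) -> pd.DataFrame:
    """Cohort means/SDs of raw hit, false-alarm, miss and correct-rejection rates.

    Misses and correct rejections are the complements of hits and false
    alarms (miss = 1 - H, CR = 1 - FA); no extreme-rate correction is applied
    to this descriptive table.
    """
    validate_item_bank(bank)
    cols = bank["item_id"].to_numpy()
    resp = judgments[cols].to_numpy(dtype=float)
    veracity = bank["veracity"].to_numpy(dtype=bool)
    h = resp[:, veracity].mean(axis=1)
    fa = resp[:, ~veracity].mean(axis=1)
    rows = {
        "hits": h, "false_alarms": fa, "misses": 1.0 - h,
        "correct_rejections": 1.0 - fa,
    }
    return pd.DataFrame(
        {"mean": {k: v.mean() for k, v in rows.items()},
         "sd": {k: pd.Series(v).std(ddof=1) for k, v in rows.items()}}
    )
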