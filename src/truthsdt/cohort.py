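"""Synthetic respondent cohorts from an equal-variance Gaussian SDT model.

Each participant carries three latent parameters: truth sensitivity ``d``,
baseline acceptance threshold ``c`` and a myside criterion shift ``m``.  The
criterion applied to an item depends on its congruence with the participant's
group:

    c_congruent   = c - m/2
    c_incongruent = c + m/2

so the estimated myside index (c_incongruent - c_congruent) recovers ``m``
and the overall criterion recovers ``c``.  A "true" response to an item is
Bernoulli with probability Phi(d/2 - c_used) for true items and
Phi(-d/2 - c_used) for false items — the exact generative inverse of the
d' / c estimators, which makes estimator consistency testable in closed form.

Trait covariates are drawn jointly Gaussian with the three SDT latents at
configurable target correlations, and optionally emitted as discretized
Likert item responses with a configurable reliability.  Default parameter
distributions and trait targets mirror the magnitudes of a published
political-misinformation cohort (N = 300, 20 items per veracity x slant
cell, d' ~ N(0.52, 0.49), c ~ N(0.38, 0.50), myside ~ N(0.66, 0.70)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigurationError, ValidationError
from .scales import ScaleSpec, default_registry
from .sdt import GROUP_LABELS

__all__ = [
    "TraitSpec", "CohortConfig", "LatentParams", "Cohort",
    "response_probability", "generate_item_bank", "sample_latents",
    "sample_participant_params", "generate_cohort", "write_cohort",
    "load_cohort", "default_trait_specs",
]


@dataclass(frozen=True)
class TraitSpec:
    """One trait covariate: marginal moments and target latent correlations
    with (d, c, m)."""

    name: str
    mean: float
    sd: float
    r_dprime: float = 0.0
    r_criterion: float = 0.0
    r_myside: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigurationError(f"trait {self.name}: sd must be >= 0")
        for r in (self.r_dprime, self.r_criterion, self.r_myside):
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError(
                    f"trait {self.name}: correlations must be in [-1, 1]")


# Trait marginals follow the published Study-1 descriptives; correlation
# targets follow the corresponding trait x (d', c, myside) screen entries.
_DEFAULT_TRAITS = (
    ("extraversion",          2.86, 0.91, -0.10, -0.01, -0.16),
    ("agreeableness",         3.88, 0.80, -0.03,  0.16,  0.00),
    ("conscientiousness",     3.78, 0.90, -0.05,  0.12, -0.06),
    ("neuroticism",           2.62, 1.10, -0.02, -0.09,  0.00),
    ("openness",              3.89, 0.82,  0.03,  0.02,  0.19),
    ("cognitive_reflection",  4.02, 2.03,  0.30,  0.02,  0.11),
    ("aot",                   4.63, 0.73,  0.28,  0.15,  0.13),
    ("intellectual_humility", 3.95, 0.73,  0.10,  0.11, -0.09),
    ("need_to_evaluate",      3.05, 0.67, -0.02, -0.17,  0.09),
    ("bullshit_receptivity",  2.61, 0.87, -0.25, -0.14, -0.25),
    ("conspiracy_mentality",  6.12, 2.06, -0.14, -0.23,  0.01),
    ("self_esteem",           3.06, 0.74,  0.06,  0.01, -0.02),
    ("narcissism",            3.42, 3.16, -0.24, -0.07, -0.07),
    ("need_to_belong",        2.83, 0.81, -0.13,  0.00, -0.13),
    ("likeminded_identification", 0.35, 0.65, 0.00, -0.04, 0.00),
)


def default_trait_specs() -> tuple[TraitSpec, ...]:
    """The 15 bundled trait covariates (editable by passing your own list)."""
    return tuple(TraitSpec(*row) for row in _DEFAULT_TRAITS)


@dataclass(frozen=True)
class CohortConfig:
    """Full generative specification of a synthetic cohort.

    ``n_per_group`` participants are generated for each of the two groups.
    Latent (d, c, m, traits) are jointly Gaussian; the implied correlation
    matrix (SDT latents mutually orthogonal, traits correlated with them per
    ``traits``, traits mutually uncorrelated) is validated PSD here.
    """

    n_per_group: int = 150
    items_per_cell: int = 20
    dprime_dist: tuple[float, float] = (0.52, 0.49)
    criterion_dist: tuple[float, float] = (0.38, 0.50)
    myside_dist: tuple[float, float] = (0.66, 0.70)
    traits: tuple[TraitSpec, ...] = field(default_factory=default_trait_specs)
    trait_reliability: float = 0.85
    discretize_traits: bool = True
    n_attention_failures: int = 0
    n_inconsistent: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.items_per_cell < 1:
            raise ConfigurationError("items_per_cell must be >= 1")
        for name, (mu, sd) in (("dprime", self.dprime_dist),
                               ("criterion", self.criterion_dist),
                               ("myside", self.myside_dist)):
            if sd < 0:
                raise ConfigurationError(f"{name} sd must be >= 0")
        if not 0.0 < self.trait_reliability <= 1.0:
            raise ConfigurationError("trait_reliability must be in (0, 1]")
        n_excl = self.n_attention_failures + self.n_inconsistent
        if n_excl > 2 * self.n_per_group:
            raise ConfigurationError("more exclusions than participants")
        R = self.latent_correlation()[1]
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigurationError(
                "implied latent correlation matrix is not positive semi-definite")

    def latent_correlation(self) -> tuple[list[str], np.ndarray]:
        """Names and correlation matrix of (d, c, m, trait latents)."""
        names = ["d_true", "c_base", "m_true"] + [t.name for t in self.traits]
        k = len(names)
        R = np.eye(k)
        for j, t in enumerate(self.traits, start=3):
            R[0, j] = R[j, 0] = t.r_dprime
            R[1, j] = R[j, 1] = t.r_criterion
            R[2, j] = R[j, 2] = t.r_myside
        return names, R

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "traits" in d:
            d["traits"] = tuple(
                t if isinstance(t, TraitSpec) else TraitSpec(**t)
                for t in d["traits"])
        for key in ("dprime_dist", "criterion_dist", "myside_dist"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LatentParams:
    """Generative truth for one participant."""

    d_true: float
    c_base: float
    m_true: float
    trait_latents: dict[str, float]

    @property
    def c_congruent(self) -> float:
        return self.c_base - self.m_true / 2.0

    @property
    def c_incongruent(self) -> float:
        return self.c_base + self.m_true / 2.0


@dataclass
class Cohort:
    """A generated dataset: item bank, participant table, judgment matrix and
    the latent truth table used for recovery testing."""

    bank: pd.DataFrame
    participants: pd.DataFrame
    judgments: pd.DataFrame           # wide bool, participants x items
    latents: pd.DataFrame             # participant_id-indexed truth table
    config: CohortConfig


def response_probability(d: float, c: float, veracity: bool) -> float:
    """P("true" response) under equal-variance Gaussian SDT.

    Phi(d/2 - c) for a true item, Phi(-d/2 - c) for a false one.
    """
    d, c = float(d), float(c)
    if not (np.isfinite(d) and np.isfinite(c)):
        raise ValidationError("d and c must be finite")
    mu = d / 2.0 if veracity else -d / 2.0
    return float(norm.cdf(mu - c))


def generate_item_bank(items_per_cell: int = 20, seed: int = 0) -> pd.DataFrame:
    """A 2 x 2 (veracity x slant) bank with ``items_per_cell`` items per cell
    in a seeded fixed presentation order."""
    if items_per_cell < 1:
        raise ConfigurationError("items_per_cell must be >= 1")
    rows = []
    i = 0
    for veracity in (True, False):
        for slant in GROUP_LABELS:
            for _ in range(items_per_cell):
                i += 1
                rows.append((f"item_{i:04d}", veracity, slant))
    bank = pd.DataFrame(rows, columns=["item_id", "veracity", "slant"])
    rng = np.random.default_rng(seed)
    bank["order_index"] = rng.permutation(len(bank)) + 1
    return bank.sort_values("order_index", ignore_index=True)


def _correlation_factor(R: np.ndarray) -> np.ndarray:
    """Square root of a PSD correlation matrix (eigen-based, handles singular
    targets such as a trait perfectly correlated with d)."""
    w, V = np.linalg.eigh(R)
    return V * np.sqrt(np.clip(w, 0.0, None))


def sample_latents(config: CohortConfig, rng: np.random.Generator,
                   n: int) -> pd.DataFrame:
    """Draw ``n`` joint latent vectors (d_true, c_base, m_true, traits)."""
    names, R = config.latent_correlation()
    L = _correlation_factor(R)
    z = rng.standard_normal((n, len(names))) @ L.T
    means = np.array([config.dprime_dist[0], config.criterion_dist[0],
                      config.myside_dist[0]] + [t.mean for t in config.traits])
    sds = np.array([config.dprime_dist[1], config.criterion_dist[1],
                    config.myside_dist[1]] + [t.sd for t in config.traits])
    return pd.DataFrame(means + sds * z, columns=names)


def sample_participant_params(config: CohortConfig,
                              rng: np.random.Generator) -> LatentParams:
    """Draw one participant's latent parameters."""
    row = sample_latents(config, rng, 1).iloc[0]
    traits = {t.name: float(row[t.name]) for t in config.traits}
    return LatentParams(float(row["d_true"]), float(row["c_base"]),
                        float(row["m_true"]), traits)


def _likert_items(target: np.ndarray, spec: ScaleSpec, reliability: float,
                  discretize: bool, rng: np.random.Generator) -> np.ndarray:
    """Item responses whose scale score tracks ``target`` at roughly the
    requested reliability.  Likert scales add Gaussian item noise then round
    and clip; binary sum scales draw items Bernoulli(target / k)."""
    n, k = len(target), spec.n_items
    lo, hi = spec.response_min, spec.response_max
    if spec.aggregation == "sum":
        p = np.clip(target[:, None] / k, 0.0, 1.0)
        return (rng.uniform(size=(n, k)) < p).astype(int)
    var_t = max(np.var(target), 1e-12)
    noise_var = var_t * (1.0 - reliability) / reliability
    items = target[:, None] + rng.normal(0.0, np.sqrt(k * noise_var), (n, k))
    if discretize:
        items = np.rint(items)
    items = np.clip(items, lo, hi)
    # store reverse-keyed items in their raw (reversed) direction so that
    # standard scoring recodes them back
    for j in spec.reverse_items:
        items[:, j - 1] = lo + hi - items[:, j - 1]
    return items


def _emit_scale_responses(latents: pd.DataFrame, config: CohortConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    registry = default_registry()
    cols = {}
    for t in config.traits:
        spec = registry.get(t.name)
        if spec is None:
            spec = ScaleSpec(t.name, 10, 1, 5)
        target = latents[t.name].to_numpy()
        if spec.aggregation == "difference_of_means":
            # two rating blocks; the score is the mean item-wise difference
            mid = (spec.response_min + spec.response_max) / 2.0
            hum = np.clip(np.rint(
                mid + rng.normal(0.0, 0.7, (len(target), spec.n_items))),
                spec.response_min, spec.response_max)
            noise_var = max(np.var(target), 1e-12) * \
                (1.0 - config.trait_reliability) / config.trait_reliability
            like = hum + target[:, None] + rng.normal(
                0.0, np.sqrt(spec.n_items * noise_var),
                (len(target), spec.n_items))
            if config.discretize_traits:
                like = np.rint(like)
            like = np.clip(like, spec.response_min, spec.response_max)
            for j in range(spec.n_items):
                cols[f"{t.name}_like_{j + 1}"] = like[:, j]
                cols[f"{t.name}_hum_{j + 1}"] = hum[:, j]
        else:
            items = _likert_items(target, spec, config.trait_reliability,
                                  config.discretize_traits, rng)
            for j in range(spec.n_items):
                cols[f"{t.name}_{j + 1}"] = items[:, j]
    return pd.DataFrame(cols)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic dataset, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    bank = generate_item_bank(config.items_per_cell, seed=config.seed)

    n = 2 * config.n_per_group
    ids = [f"p{i + 1:04d}" for i in range(n)]
    groups = np.array([GROUP_LABELS[0]] * config.n_per_group +
                      [GROUP_LABELS[1]] * config.n_per_group)

    latents = sample_latents(config, rng, n)
    latents.index = pd.Index(ids, name="participant_id")
    latents.insert(0, "group", groups)

    d = latents["d_true"].to_numpy()[:, None]
    c = latents["c_base"].to_numpy()[:, None]
    m = latents["m_true"].to_numpy()[:, None]
    veracity = bank["veracity"].to_numpy(dtype=bool)[None, :]
    congruent = (bank["slant"].to_numpy()[None, :] == groups[:, None])
    c_used = c + np.where(congruent, -m / 2.0, m / 2.0)
    mu = np.where(veracity, d / 2.0, -d / 2.0)
    p_true = norm.cdf(mu - c_used)
    resp = rng.uniform(size=p_true.shape) < p_true
    judgments = pd.DataFrame(resp, index=pd.Index(ids, name="participant_id"),
                             columns=bank["item_id"].to_numpy())

    # exclusion flags: attention failures first, then (among passers) an
    # additional batch with inconsistent prescreen group
    attention_passed = np.ones(n, dtype=bool)
    fail_idx = rng.choice(n, size=config.n_attention_failures, replace=False)
    attention_passed[fail_idx] = False
    prescreen = groups.copy()
    passers = np.flatnonzero(attention_passed)
    if config.n_inconsistent > len(passers):
        raise ConfigurationError("n_inconsistent exceeds attention passers")
    flip_idx = rng.choice(passers, size=config.n_inconsistent, replace=False)
    other = {GROUP_LABELS[0]: GROUP_LABELS[1], GROUP_LABELS[1]: GROUP_LABELS[0]}
    prescreen[flip_idx] = [other[g] for g in groups[flip_idx]]

    participants = pd.DataFrame({
        "participant_id": ids,
        "group": groups,
        "prescreen_group": prescreen,
        "attention_passed": attention_passed,
        "completed": True,
    })
    scale_items = _emit_scale_responses(latents, config, rng)
    scale_items.index = participants.index
    participants = pd.concat([participants, scale_items], axis=1)
    participants = participants.set_index("participant_id", drop=False)

    return Cohort(bank=bank, participants=participants, judgments=judgments,
                  latents=latents, config=config)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as plain CSVs (judgments long format, participants
    wide, item bank, latent truth) plus the config as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bank": outdir / "item_bank.csv",
        "participants": outdir / "participants.csv",
        "judgments": outdir / "judgments.csv",
        "latents": outdir / "latents.csv",
        "config": outdir / "cohort_config.json",
    }
    cohort.bank.to_csv(paths["bank"], index=False)
    cohort.participants.to_csv(paths["participants"], index=False)
    long = cohort.judgments.stack().rename("response").reset_index()
    long.columns = ["participant_id", "item_id", "response"]
    long.to_csv(paths["judgments"], index=False)
    cohort.latents.to_csv(paths["latents"])
    paths["config"].write_text(json.dumps(cohort.config.to_dict(), indent=2))
    return paths


def load_cohort(indir: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (or user CSVs in the
    same layout).  Judgments must cover every bank item for every
    participant; incomplete imports are rejected."""
    indir = Path(indir)
    bank = pd.read_csv(indir / "item_bank.csv")
    participants = pd.read_csv(indir / "participants.csv")
    participants = participants.set_index("participant_id", drop=False)
    long = pd.read_csv(indir / "judgments.csv")
    judgments = long.pivot(index="participant_id", columns="item_id",
                           values="response")
    if judgments.isna().any().any():
        raise ValidationError("imported judgments are incomplete")
    judgments = judgments.astype(bool)
    judgments = judgments.reindex(index=participants.index,
                                  columns=bank["item_id"].to_numpy())
    if judgments.isna().any().any():
        raise ValidationError("judgments do not cover all participants x items")
    latents_path = indir / "latents.csv"
    latents = (pd.read_csv(latents_path, index_col="participant_id")
               if latents_path.exists() else pd.DataFrame(index=judgments.index))
    cfg_path = indir / "cohort_config.json"
    config = (CohortConfig.from_dict(json.loads(cfg_path.read_text()))
              if cfg_path.exists() else CohortConfig())
    return Cohort(bank=bank, participants=participants, judgments=judgments,
                  latents=latents, config=config)
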