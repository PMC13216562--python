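"""End-to-end study pipeline: exclusions -> scale scoring -> SDT scoring ->
split-half regressions -> correlation screens -> optional bifactor model.

Runs on a simulated cohort or on imported CSVs with the same layout, writes
plain-CSV analogues of the study's descriptive and inferential tables (full
precision plus 3-decimal display copies), and records a machine-readable run
manifest (config hash, seed, versions) so that a seed fully determines all
outputs.  Nothing is written until every requested stage has completed, so a
failing stage leaves no partial output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import TruthSDTError, ValidationError
from .cohort import Cohort, CohortConfig, generate_cohort, load_cohort
from .scales import default_registry, reverse_code, score_all, \
    sdt_index_reliability
from .sdt import rates_summary, score_cohort
from .association import correlation_screen, split_half_fa_regression
from .bifactor import BifactorSpec, fit_ml, rom_default_spec, \
    standardize_solution

log = logging.getLogger("truthsdt")


@dataclass
class ExclusionReport:
    """Stage counts of the exclusion cascade."""

    n_started: int
    n_completed: int
    n_failed_attention: int
    n_inconsistent_group: int
    n_final: int
    per_group: dict[str, int]

    def __post_init__(self):
        if self.n_final != (self.n_completed - self.n_failed_attention
                            - self.n_inconsistent_group):
            raise ValidationError("exclusion counts are inconsistent")
        if sum(self.per_group.values()) != self.n_final:
            raise ValidationError("per-group counts do not sum to n_final")


def apply_exclusions(records: pd.DataFrame
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop attention-check failures first, then (among the remainder)
    participants whose reported group contradicts the prescreen, preserving
    input order."""
    for col in ("group", "prescreen_group", "attention_passed"):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    completed = (records["completed"].astype(bool)
                 if "completed" in records.columns
                 else pd.Series(True, index=records.index))
    done = records[completed]
    passed = done[done["attention_passed"].astype(bool)]
    kept = passed[passed["group"] == passed["prescreen_group"]]
    report = ExclusionReport(
        n_started=len(records),
        n_completed=len(done),
        n_failed_attention=len(done) - len(passed),
        n_inconsistent_group=len(passed) - len(kept),
        n_final=len(kept),
        per_group=kept["group"].value_counts().sort_index().to_dict(),
    )
    return kept, report


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input mode."""

    mode: str = "simulate"                 # "simulate" | "import"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    data_dir: str | None = None            # import mode
    output_dir: str = "truthsdt_out"
    seed: int | None = None                # overrides cohort.seed if set
    run_regressions: bool = True
    run_screen: bool = True
    partial_by_group: bool = True
    adjust_method: str = "holm"
    run_bifactor: bool = False
    bifactor_spec_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("simulate", "import"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "import" and not self.data_dir:
            raise ValidationError("import mode requires data_dir")
        if self.seed is not None and self.mode == "simulate":
            self.cohort = CohortConfig.from_dict(
                {**self.cohort.to_dict(), "seed": int(self.seed)})

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = (yaml.safe_load(text) if str(path).endswith((".yml", ".yaml"))
               else json.loads(text))
        if "cohort" in raw:
            raw["cohort"] = CohortConfig.from_dict(raw["cohort"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _parcel_scores(participants: pd.DataFrame) -> pd.DataFrame:
    """Item parcels for the default ROM bifactor model: contiguous item
    chunks of the four reflection-related scales, scored as recoded means."""
    registry = default_registry()
    chunks = {"cognitive_reflection": ("cr", (3, 2, 2)),
              "bullshit_receptivity": ("bs", (4, 3, 3)),
              "conspiracy_mentality": ("cm", (2, 2, 1)),
              "aot": ("aot", (5, 4, 4))}
    out = {}
    for scale, (stem, sizes) in chunks.items():
        spec = registry[scale]
        cols = [f"{scale}_{j + 1}" for j in range(spec.n_items)]
        items = reverse_code(participants[cols].to_numpy(dtype=float), spec)
        start = 0
        for j, size in enumerate(sizes, start=1):
            out[f"{stem}_p{j}"] = items[:, start:start + size].mean(axis=1)
            start += size
    return pd.DataFrame(out, index=participants.index)


def run_study(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle and writes it to
    ``config.output_dir``."""
    logging.basicConfig(level=config.log_level, format="%(name)s: %(message)s")
    stage = "load"
    try:
        if config.mode == "simulate":
            log.info("[%s] simulating cohort (seed=%d)", stage,
                     config.cohort.seed)
            cohort = generate_cohort(config.cohort)
        else:
            log.info("[%s] importing cohort from %s", stage, config.data_dir)
            cohort = load_cohort(config.data_dir)
        bundle = _analyze(cohort, config)
    except TruthSDTError as err:
        raise TruthSDTError(f"stage {stage!r} failed: {err}") from err
    _write_bundle(bundle, config)
    return bundle


def _analyze(cohort: Cohort, config: RunConfig) -> dict:
    bundle: dict = {}

    log.info("[exclusions] applying exclusion cascade")
    kept, report = apply_exclusions(cohort.participants)
    bundle["exclusions"] = report
    ids = kept.index
    judgments = cohort.judgments.loc[ids]
    groups = kept["group"]

    log.info("[rates] Table-2 analogue on %d participants", len(ids))
    bundle["rates"] = rates_summary(judgments, cohort.bank)

    log.info("[scoring] SDT indices per split and trait scores")
    scores = {split: score_cohort(judgments, cohort.bank, groups, split=split)
              for split in ("all", "odd", "even")}
    bundle["sdt_scores"] = scores
    traits, alphas = score_all(kept)
    bundle["traits"], bundle["trait_alphas"] = traits, alphas

    desc_rows = []
    k_parcels = 4 if cohort.config.items_per_cell % 4 == 0 else 1
    for index, label in (("d_prime", "truth_sensitivity"),
                         ("c_overall", "acceptance_threshold"),
                         ("myside", "myside_bias")):
        alpha = (sdt_index_reliability(judgments, cohort.bank, groups,
                                       index=index, k_parcels=k_parcels)
                 if k_parcels > 1 else np.nan)
        desc_rows.append({"variable": label,
                          "mean": scores["all"][index].mean(),
                          "sd": scores["all"][index].std(ddof=1),
                          "cronbach_alpha": alpha})
    for t in traits.columns:
        desc_rows.append({"variable": t, "mean": traits[t].mean(),
                          "sd": traits[t].std(ddof=1),
                          "cronbach_alpha": alphas.get(t, np.nan)})
    bundle["descriptives"] = pd.DataFrame(desc_rows)

    if config.run_regressions:
        log.info("[regressions] four split-half FA regressions")
        results = split_half_fa_regression(scores["odd"], scores["even"])
        bundle["regressions"] = pd.concat([r.to_frame() for r in results],
                                          ignore_index=True)

    if config.run_screen:
        log.info("[screen] trait x index correlation screen")
        bundle["screen"] = correlation_screen(
            traits, scores["all"],
            group=groups if config.partial_by_group else None,
            adjust=config.adjust_method)

    if config.run_bifactor:
        log.info("[bifactor] fitting ROM bifactor model")
        spec = (BifactorSpec.from_json(config.bifactor_spec_path)
                if config.bifactor_spec_path else rom_default_spec())
        data = _parcel_scores(kept)
        data["ts_odd"] = scores["odd"]["d_prime"]
        data["ts_even"] = scores["even"]["d_prime"]
        sample_cov = data[list(spec.observed)].cov()
        fit = standardize_solution(
            fit_ml(sample_cov, n=len(data), spec=spec,
                   seed=cohort.config.seed), sample_cov)
        bundle["bifactor"] = fit

    seed = cohort.config.seed if config.mode == "simulate" else None
    hashed = {k: v for k, v in config.to_dict().items()
              if k not in ("output_dir", "log_level")}
    cfg_json = json.dumps(hashed, sort_keys=True, default=str)
    bundle["manifest"] = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "mode": config.mode,
        "n_final": report.n_final,
        "truthsdt_version": __version__,
    }
    return bundle


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(outdir / f"{name}.csv", index=index)
        df.round(3).to_csv(outdir / f"{name}_display.csv", index=index)

    (outdir / "exclusions.json").write_text(
        json.dumps(asdict(bundle["exclusions"]), indent=2, sort_keys=True))
    emit(bundle["rates"], "rates", index=True)
    emit(bundle["descriptives"], "descriptives")
    for split, frame in bundle["sdt_scores"].items():
        frame.to_csv(outdir / f"sdt_scores_{split}.csv")
    bundle["traits"].to_csv(outdir / "trait_scores.csv")
    if "regressions" in bundle:
        emit(bundle["regressions"], "regressions")
    if "screen" in bundle:
        emit(bundle["screen"], "screen")
    if "bifactor" in bundle:
        fit = bundle["bifactor"]
        fit.to_frame().to_csv(outdir / "bifactor_estimates.csv", index=False)
        (outdir / "bifactor_summary.json").write_text(json.dumps({
            "discrepancy": fit.discrepancy,
            "n": fit.n,
            "df": len(fit.spec.observed) * (len(fit.spec.observed) + 1) // 2
                  - fit.spec.n_free,
            "converged": fit.converged,
            "heywood": fit.heywood,
        }, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2, sort_keys=True))
    log.info("[write] outputs in %s", outdir)
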