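"""One-command orchestration: ingest or simulate, detect, score, fit, report.

The report mirrors the analysis flow of a showing study: overall success
against chance, the distribution of showing types, the success models
(correct showing; condition x time), the effort models, the accuracy-time
correlation, and the exploratory owner-behavior models.  Every reported
number is traceable to a serialized intermediate (showings table,
observation table, coefficient tables).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import io as cio
from .detector import showings_to_records, detect_showings
from .metrics import (
    build_observation_table,
    format_type_summary,
    showing_accuracy_series,
    summarize_types,
)
from .mixed import (
    TIME_TERMS,
    ModelComparison,
    ModelFit,
    add_nested_time_columns,
    fit_gaussian_lmm,
    fit_logistic_glmm,
    select_model_aic,
)
from .simulate import SimConfig, simulate_dataset
from .stats import CorrelationResult, TestResult, accuracy_time_correlation, one_sample_t_vs_chance, paired_t

__all__ = ["RunConfig", "PipelineError", "ReportBundle", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pairs: int = 30
    phase_duration: float = Field(60.0, gt=0)
    p_correct: float = Field(0.35, ge=0.0, le=1.0)
    beta0: float = -2.2
    beta_correct: float = 6.8
    sigma_pair: float = Field(0.5, ge=0.0)


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML key-value file).

    Exactly one of ``simulate`` / (``events`` + ``metadata``) is active.
    Defaults: 2.0 s detector window, 25% chance level, alpha 0.05.
    """

    model_config = ConfigDict(extra="forbid")

    events: str | None = None
    metadata: str | None = None
    simulate: SimulateSection | None = None
    window: float = Field(2.0, ge=0.0)
    chance: float = Field(25.0, gt=0.0, lt=100.0)
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    choice_rate_phase: str = "matched"
    d_method: str = "pooled"
    outdir: str = "canishow_out"
    seed: int = 0
    verbose: bool = True

    @model_validator(mode="after")
    def _one_input(self) -> "RunConfig":
        has_files = self.events is not None
        if has_files == (self.simulate is not None):
            raise ValueError(
                "exactly one input must be configured: either 'events' (+ "
                "'metadata') paths or a 'simulate' section"
            )
        if has_files and self.metadata is None:
            raise ValueError("'events' requires a 'metadata' table")
        if self.choice_rate_phase not in ("matched", "phase2"):
            raise ValueError("choice_rate_phase must be 'matched' or 'phase2'")
        if self.d_method not in ("diff", "pooled"):
            raise ValueError("d_method must be 'diff' or 'pooled'")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys raise an error listing the valid keys.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if raw.get("simulate") == "default" or raw.get("simulate") is True:
        raw["simulate"] = {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        valid = sorted(RunConfig.model_fields)
        raise ValueError(f"invalid config {path}: {exc}\nvalid keys: {valid}") from None


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(exclude_none=True),
                                         sort_keys=True))


@dataclass
class ReportBundle:
    """Everything one pipeline run computed."""

    config: RunConfig
    validation: cio.ValidationReport
    observations: pd.DataFrame
    showings: pd.DataFrame
    type_summary: pd.DataFrame
    success_tests: dict[str, TestResult]
    success_model: ModelFit
    success_model_comparison: ModelComparison
    condition_model_comparison: ModelComparison
    effort_model_comparison: ModelComparison
    accuracy_time: CorrelationResult
    owner_models: dict[str, ModelFit]
    excluded_rows: dict[str, int]
    report_text: str = ""


def _success_percent_per_pair(obs: pd.DataFrame, phase: int) -> pd.Series:
    sub = obs[obs.phase == phase]
    return sub.groupby("pair")["success"].mean() * 100.0


def _fit_nested_ladder(design: pd.DataFrame, response: str, base_terms: list[str],
                       add_terms: list[list[str]], labels: list[str],
                       family: str) -> ModelComparison:
    """Fit base model plus cumulative term additions; AIC-select + LRT."""
    fits, terms = [], list(base_terms)
    fit_fn = (fit_logistic_glmm if family == "binomial" else
              lambda d, r, f: fit_gaussian_lmm(d, r, f, reml=False))
    fits.append(fit_fn(design, response, list(terms)))
    nested = []
    for i, extra in enumerate(add_terms):
        terms = terms + extra
        fits.append(fit_fn(design, response, list(terms)))
        nested.append((i, i + 1))
    return select_model_aic(fits, labels=labels, nested=nested)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write all intermediates to ``outdir``.

    Deterministic under ``config.seed``.  Raises :class:`PipelineError`
    naming the failing stage; an empty dataset fails at validation.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def say(msg: str) -> None:
        log_lines.append(msg)
        if config.verbose:
            print(msg, file=sys.stderr)

    # ---- ingest or simulate -------------------------------------------------
    try:
        if config.simulate is not None:
            sim = SimConfig(n_pairs=config.simulate.n_pairs,
                            phase_duration=config.simulate.phase_duration,
                            p_correct=config.simulate.p_correct,
                            beta0=config.simulate.beta0,
                            beta_correct=config.simulate.beta_correct,
                            sigma_pair=config.simulate.sigma_pair,
                            detector_window=config.window,
                            seed=config.seed)
            logs, contexts, truth = simulate_dataset(sim)
            truth.per_observation.to_csv(outdir / "ground_truth.csv", index=False)
            say(f"simulated {len(logs)} event logs for {sim.n_pairs} pairs")
        else:
            logs, contexts = cio.load_dataset(config.events, config.metadata)
            say(f"read {len(logs)} event logs from {config.events}")
    except Exception as exc:
        raise PipelineError(f"ingest stage failed: {exc}") from exc

    # ---- validation ---------------------------------------------------------
    if not logs:
        raise PipelineError("validation stage failed: dataset is empty")
    validation = cio.validate_dataset(logs)
    say(str(validation))
    if not validation.ok:
        raise PipelineError(
            f"validation stage failed: {len(validation.violations)} violation(s); "
            "first: " + validation.violations[0]
        )

    # ---- detection & scoring ------------------------------------------------
    try:
        obs, cells = build_observation_table(logs, window=config.window)
        showing_records = []
        for log in logs:
            showing_records += showings_to_records(
                log, detect_showings(log, config.window))
        showings_df = pd.DataFrame(showing_records)
        type_summary = summarize_types(
            cells, choice_rate_phase=config.choice_rate_phase)
    except Exception as exc:
        raise PipelineError(f"scoring stage failed: {exc}") from exc
    obs.to_csv(outdir / "observations.csv", index=False)
    showings_df.to_csv(outdir / "showings.csv", index=False)
    type_summary.to_csv(outdir / "type_summary.csv", index=False)
    say(f"{len(showings_df)} showings over {len(obs)} observation cells")

    # ---- overall success ----------------------------------------------------
    try:
        p1 = _success_percent_per_pair(obs, 1)
        p2 = _success_percent_per_pair(obs, 2)
        success_tests = {
            "phase1_vs_chance": one_sample_t_vs_chance(p1, config.chance),
            "phase2_vs_chance": one_sample_t_vs_chance(p2, config.chance),
            "phase2_vs_phase1": paired_t(p2.to_numpy(), p1.to_numpy(),
                                         d_method=config.d_method),
        }
    except Exception as exc:
        raise PipelineError(f"success-test stage failed: {exc}") from exc

    # ---- models -------------------------------------------------------------
    design = add_nested_time_columns(obs)
    excluded = {
        "prop_correct_showing": int(design["prop_correct_showing"].isna().sum()),
        "effort": int(design["effort"].isna().sum()),
    }
    say("rows excluded for missing values: " +
        ", ".join(f"{k}: {v}" for k, v in excluded.items()))
    try:
        success_cmp = _fit_nested_ladder(
            design.dropna(subset=["prop_correct_showing"]), "success",
            ["prop_correct_showing"], [list(TIME_TERMS)],
            ["success ~ correct_showing", "success ~ correct_showing + time"],
            family="binomial")
        success_model = success_cmp.fits[success_cmp.selected]
        condition_cmp = _fit_nested_ladder(
            design, "success",
            list(TIME_TERMS), [["condition_far"]],
            ["success ~ time", "success ~ time + condition"],
            family="binomial")
        effort_design = design.dropna(subset=["effort"])
        effort_cmp = _fit_nested_ladder(
            effort_design, "effort",
            list(TIME_TERMS), [["condition_far"]],
            ["effort ~ time", "effort ~ time + condition"],
            family="gaussian")
        owner_design = design.assign(
            owner_x_condition=design["owner_behavior_count"] * design["condition_far"])
        owner_models = {
            "correct_showing ~ owner*condition + time": fit_gaussian_lmm(
                owner_design.dropna(subset=["prop_correct_showing"]),
                "prop_correct_showing",
                ["owner_behavior_count", "condition_far", "owner_x_condition",
                 *TIME_TERMS]),
            "effort ~ owner*condition + time": fit_gaussian_lmm(
                owner_design.dropna(subset=["effort"]), "effort",
                ["owner_behavior_count", "condition_far", "owner_x_condition",
                 *TIME_TERMS]),
        }
    except Exception as exc:
        raise PipelineError(f"model stage failed: {exc}") from exc

    # ---- accuracy-time correlation -----------------------------------------
    flags, seconds = showing_accuracy_series(cells)
    try:
        accuracy_time = accuracy_time_correlation(flags, seconds)
    except Exception as exc:
        raise PipelineError(f"correlation stage failed: {exc}") from exc

    # ---- report -------------------------------------------------------------
    bundle = ReportBundle(
        config=config, validation=validation, observations=obs,
        showings=showings_df, type_summary=type_summary,
        success_tests=success_tests, success_model=success_model,
        success_model_comparison=success_cmp,
        condition_model_comparison=condition_cmp,
        effort_model_comparison=effort_cmp,
        accuracy_time=accuracy_time, owner_models=owner_models,
        excluded_rows=excluded,
    )
    bundle.report_text = render_report(bundle)
    (outdir / "report.txt").write_text(bundle.report_text)
    coef_frames = []
    for label, fit in _all_fits(bundle):
        tab = fit.coef_table()
        tab.insert(0, "model", label)
        coef_frames.append(tab)
    pd.concat(coef_frames, ignore_index=True).to_csv(
        outdir / "model_coefficients.csv", index=False)
    say(f"report written to {outdir / 'report.txt'}")
    return bundle


def _all_fits(bundle: ReportBundle):
    for cmp_, prefix in ((bundle.success_model_comparison, "success"),
                         (bundle.condition_model_comparison, "condition"),
                         (bundle.effort_model_comparison, "effort")):
        for label, fit in zip(cmp_.labels, cmp_.fits):
            yield f"{prefix}: {label}", fit
    for label, fit in bundle.owner_models.items():
        yield f"owner: {label}", fit


def render_report(bundle: ReportBundle) -> str:
    """Human-readable results report (mirrors the analysis flow)."""
    obs = bundle.observations
    lines = [
        "canishow analysis report",
        "=" * 60,
        f"observation cells: {len(obs)}  |  showings: {len(bundle.showings)}",
        f"rows excluded for missing values: {bundle.excluded_rows}",
        "",
        "Overall success (per-pair percent correct vs "
        f"{bundle.success_tests['phase1_vs_chance'].extra['chance']:.0f}% chance)",
        "-" * 60,
    ]
    for name, tr in bundle.success_tests.items():
        mean_part = (f"M = {tr.mean:.2f}, SD = {tr.sd:.2f}, "
                     if "chance" in tr.extra else f"mean diff = {tr.mean:.2f}, ")
        lines.append(f"  {name}: {mean_part}{tr}")
    lines += ["", "Distribution of showing types", "-" * 60,
              format_type_summary(bundle.type_summary), ""]
    lines += ["Success ~ correct showing", "-" * 60,
              bundle.success_model_comparison.summary(),
              bundle.success_model.summary(), ""]
    lines += ["Success ~ condition + time", "-" * 60,
              bundle.condition_model_comparison.summary(),
              bundle.condition_model_comparison.fits[
                  bundle.condition_model_comparison.selected].summary(), ""]
    lines += ["Showing effort ~ time (+condition)", "-" * 60,
              bundle.effort_model_comparison.summary(),
              bundle.effort_model_comparison.fits[
                  bundle.effort_model_comparison.selected].summary(), ""]
    lines += ["Showing accuracy vs seconds within trial", "-" * 60,
              f"  {bundle.accuracy_time}", ""]
    lines += ["Owner-behavior models (exploratory)", "-" * 60]
    for label, fit in bundle.owner_models.items():
        lines += [f"[{label}]", fit.summary(), ""]
    return "\n".join(lines)
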