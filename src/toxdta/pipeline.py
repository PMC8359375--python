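"""End-to-end orchestration: read -> fit -> score -> classify -> summarize -> report.

Runs the whole direct-toxicity-assessment analysis for every species x round
trial in a tidy survival table: fits the candidate time-response families to
each group, selects by AIC, derives LT10/LT50 with confidence limits, scores
the five weighted response criteria for every test solution, classifies
Response / No response, and writes the lethal-time table, the response
matrix, the relative-toxicity summaries and a short run report.  Fit
failures for individual groups degrade to criterion evidence ("not
estimable"); they never abort the run.

Also home to the solution-preparation arithmetic: the mass-balance dilution
a sample undergoes when hypersaline brine is added to raise it to test
salinity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import survival_data as sd
from . import time_response as tr
from . import response_matrix as rm

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "run_pipeline",
    "dilution_fraction",
    "read_manual_overrides",
    "read_external_labels",
]

logger = logging.getLogger("toxdta")


class PipelineError(Exception):
    """Invalid configuration or unusable input."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; all expert-judgment constants overridable."""

    survival_csv: str | Path
    output_dir: str | Path = "toxdta_output"
    overrides_csv: str | Path | None = None        # manual criterion scores
    external_labels_csv: str | Path | None = None  # e.g. Microtox labels
    families: tuple[str, ...] = tr.FAMILY_ORDER
    lt_levels: tuple[float, ...] = (10.0, 50.0)
    confidence: float = 0.95
    margin: float = 20.0             # criterion-1 full-score shortfall (points)
    borderline_margin: float = 15.0  # criterion-1 borderline shortfall (points)
    threshold: float = rm.DEFAULT_THRESHOLD
    weights: tuple[float, float, float, float, float] = (4.0, 3.0, 2.0, 1.0, 1.0)
    relative_lt: bool = True
    dialect: str = ","
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 100.0:
            raise PipelineError(f"threshold must be in (0, 100], got {self.threshold}")
        if not self.families:
            raise PipelineError("at least one model family must be enabled")
        unknown = [f for f in self.families if f not in tr.FAMILIES]
        if unknown:
            raise PipelineError(f"unknown model families {unknown}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML (or JSON — a YAML subset) config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PipelineError(f"config file {path} must contain a mapping")
        for key in ("families", "lt_levels", "weights"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_manual_overrides(path: str | Path, dialect: str = ",") -> dict[tuple[str, str, int], dict[int, float]]:
    """Read manual criterion scores: columns species, solution, round, criterion, score."""
    df = pd.read_csv(path, sep=dialect)
    required = {"species", "solution", "round", "criterion", "score"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"{path}: overrides file missing columns {sorted(missing)}")
    out: dict[tuple[str, str, int], dict[int, float]] = {}
    for _, row in df.iterrows():
        key = (str(row["species"]), str(row["solution"]), int(row["round"]))
        out.setdefault(key, {})[int(row["criterion"])] = float(row["score"])
    return out


def read_external_labels(path: str | Path, dialect: str = ",") -> dict[tuple[str, str, int], rm.ResponseLabel]:
    """Read external assay labels: columns name, solution, round, label."""
    df = pd.read_csv(path, sep=dialect)
    required = {"name", "solution", "round", "label"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"{path}: labels file missing columns {sorted(missing)}")
    return {
        (str(r["name"]), str(r["solution"]), int(r["round"])): rm.ResponseLabel(str(r["label"]))
        for _, r in df.iterrows()
    }


@dataclass
class GroupFitResult:
    """Model selection outcome and LT estimates for one group of one trial."""

    species: str
    round: int
    group: str
    fit: tr.ModelFit | None
    lt: dict[float, tr.LTEstimate | None]
    note: str = ""


@dataclass
class PipelineResult:
    """In-memory outputs of one pipeline run."""

    group_fits: list[GroupFitResult]
    matrix: rm.ResponseMatrix
    lt_table: pd.DataFrame
    matrix_table: pd.DataFrame
    summary_solutions: dict[str, int]
    summary_rows: dict[str, int]
    output_files: dict[str, Path] = field(default_factory=dict)


def _fit_group(
    dataset: sd.TrialDataset, group: str, config: PipelineConfig
) -> GroupFitResult:
    data = dataset.group_survival(group)
    fits = []
    for name in config.families:
        try:
            fits.append(tr.fit_model(data["day"], data["percent_survival"], name))
        except tr.InsufficientDataError:
            continue
    try:
        best = tr.select_best(fits)
        note = ""
    except tr.SelectionError as exc:
        logger.info("%s r%s %s: non-modellable (%s)", dataset.species, dataset.round, group, exc)
        return GroupFitResult(dataset.species, dataset.round, group, None,
                              {p: None for p in config.lt_levels}, str(exc))
    lt: dict[float, tr.LTEstimate | None] = {}
    for p in config.lt_levels:
        try:
            lt[p] = tr.estimate_lt(best, p, level=config.confidence, relative=config.relative_lt)
        except tr.LTUnavailableError as exc:
            logger.info("%s r%s %s: LT%g unavailable (%s)", dataset.species, dataset.round, group, p, exc)
            lt[p] = None
            note = str(exc)
    return GroupFitResult(dataset.species, dataset.round, group, best, lt, note)


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run the full analysis described in the module docstring.

    With ``write=True`` the result tables are also written under
    ``config.output_dir`` with fixed float formatting, so re-running with
    identical inputs reproduces byte-identical files.
    """
    trials = sd.read_survival_trials(config.survival_csv, dialect=config.dialect)
    overrides = (
        read_manual_overrides(config.overrides_csv, config.dialect)
        if config.overrides_csv else {}
    )
    external = (
        read_external_labels(config.external_labels_csv, config.dialect)
        if config.external_labels_csv else {}
    )
    weights = rm.CriterionWeights(*config.weights)

    group_fits: list[GroupFitResult] = []
    assessments: list[rm.ResponseAssessment] = []
    for (species, rnd), dataset in trials.items():
        duration = dataset.schedule.duration
        by_group = {
            g: _fit_group(dataset, g, config)
            for g in dataset.groups
            if g in dataset.test_solutions or g == "HSB"
        }
        group_fits.extend(by_group.values())
        hsb = by_group.get("HSB")
        for ts in dataset.test_solutions:
            res = by_group[ts]
            c1 = rm.score_criterion1(dataset, ts, config.margin, config.borderline_margin)
            c2 = rm.score_criterion2(sd.end_survival_difference(dataset, ts, "HSB"))
            c3 = rm.score_criterion3(sd.mean_survival(dataset, ts, duration)[0])
            c4 = rm.score_criterion_ci(res.lt.get(10.0), hsb.lt.get(10.0) if hsb else None,
                                       duration, criterion=4)
            c5 = rm.score_criterion_ci(res.lt.get(50.0), hsb.lt.get(50.0) if hsb else None,
                                       duration, criterion=5)
            assessment = rm.ResponseAssessment(
                species, ts, rnd, (c1, c2, c3, c4, c5), weights, config.threshold
            )
            manual = overrides.get((species, ts, rnd))
            if manual:
                assessment = assessment.with_overrides(manual)
            for s in assessment.scores:
                logger.debug("%s r%s %s criterion %d: %g (%s) — %s",
                             species, rnd, ts, s.criterion, s.score, s.basis, s.evidence)
            assessments.append(assessment)

    matrix = rm.ResponseMatrix(assessments, external)
    summary_solutions, summary_rows = rm.summarize_matrix(matrix)
    lt_table = _lt_table(group_fits)
    matrix_table = _matrix_table(matrix, trials)

    result = PipelineResult(group_fits, matrix, lt_table, matrix_table,
                            summary_solutions, summary_rows)
    if write:
        _write_outputs(result, config)
    return result


# -- output shaping ----------------------------------------------------------


def _fmt1(x: float | None) -> str:
    """LT values reported to 1 decimal; blank when unavailable."""
    return "" if x is None or not math.isfinite(x) else f"{x:.1f}"


def _lt_table(group_fits: Sequence[GroupFitResult]) -> pd.DataFrame:
    rows = []
    for g in group_fits:
        lt10, lt50 = g.lt.get(10.0), g.lt.get(50.0)
        rows.append({
            "species": g.species, "group": g.group, "round": g.round,
            "model": g.fit.family.name if g.fit else "",
            "LT10": _fmt1(lt10.estimate if lt10 else None),
            "LT10_LL": _fmt1(lt10.lower if lt10 else None),
            "LT10_UL": _fmt1(lt10.upper if lt10 else None),
            "LT50": _fmt1(lt50.estimate if lt50 else None),
            "LT50_LL": _fmt1(lt50.lower if lt50 else None),
            "LT50_UL": _fmt1(lt50.upper if lt50 else None),
            "note": g.note,
        })
    return pd.DataFrame(rows)


def _matrix_table(matrix: rm.ResponseMatrix, trials: Mapping) -> pd.DataFrame:
    df = matrix.to_frame()
    end_surv, diff = [], []
    for _, row in df.iterrows():
        dataset = trials[(row["species"], row["round"])]
        last = dataset.schedule.duration
        end_surv.append(round(sd.mean_survival(dataset, row["solution"], last)[0]))
        diff.append(round(sd.end_survival_difference(dataset, row["solution"], "HSB")))
    df.insert(3, "end_survival", end_surv)
    df.insert(4, "difference", diff)
    return df


def _fits_json(group_fits: Sequence[GroupFitResult]) -> list[dict]:
    out = []
    for g in group_fits:
        entry: dict[str, object] = {"species": g.species, "round": g.round, "group": g.group,
                                    "note": g.note}
        if g.fit is not None:
            entry["model"] = {
                "family": g.fit.family.name,
                "params": {k: round(v, 10) for k, v in g.fit.params.items()},
                "free": list(g.fit.family.free),
                "cov": None if g.fit.cov is None else np.round(g.fit.cov, 10).tolist(),
                "rss": round(g.fit.rss, 10),
                "n_obs": g.fit.n_obs,
                "aic": round(g.fit.aic, 10),
            }
        entry["lt"] = {
            f"LT{p:g}": None if est is None else {
                "estimate": round(est.estimate, 10),
                "lower": None if not math.isfinite(est.lower) else round(est.lower, 10),
                "upper": None if not math.isfinite(est.upper) else round(est.upper, 10),
                "level": est.level,
            }
            for p, est in g.lt.items()
        }
        out.append(entry)
    return out


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def save_csv(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        result.output_files[name] = path

    save_csv("lt_table.csv", result.lt_table)
    save_csv("response_matrix.csv", result.matrix_table)
    save_csv("summary_solutions.csv", pd.DataFrame(
        sorted(result.summary_solutions.items()), columns=["solution", "percent_toxic"]))
    save_csv("summary_rows.csv", pd.DataFrame(
        sorted(result.summary_rows.items()), columns=["name", "percent_toxic_response"]))

    fits_path = out_dir / "fits.json"
    fits_path.write_text(json.dumps(_fits_json(result.group_fits), indent=1, sort_keys=True))
    result.output_files["fits.json"] = fits_path

    manifest = {
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in asdict(config).items()},
        "input_sha256": hashlib.sha256(Path(config.survival_csv).read_bytes()).hexdigest(),
        "n_assessments": len(result.matrix.assessments),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    result.output_files["manifest.json"] = manifest_path

    report = _report_markdown(result)
    report_path = out_dir / "report.md"
    report_path.write_text(report)
    result.output_files["report.md"] = report_path
    logger.info("wrote %d output files to %s", len(result.output_files), out_dir)


def _report_markdown(result: PipelineResult) -> str:
    lines = ["# Direct toxicity assessment report", ""]
    n = len(result.matrix.assessments)
    n_resp = sum(1 for a in result.matrix.assessments
                 if a.label is rm.ResponseLabel.RESPONSE)
    lines += [f"Assessed combinations: {n}; classified Response: {n_resp}.", ""]
    lines += ["## Percent toxic by test solution", ""]
    for sol, pct in sorted(result.summary_solutions.items()):
        lines.append(f"- {sol}: {pct}%")
    lines += ["", "## Percent toxic response by species/assay", ""]
    for name, pct in sorted(result.summary_rows.items()):
        lines.append(f"- {name}: {pct}%")
    lines += ["", "## Non-modellable groups", ""]
    flagged = [g for g in result.group_fits if g.fit is None]
    if flagged:
        for g in flagged:
            lines.append(f"- {g.species} round {g.round} {g.group}: {g.note}")
    else:
        lines.append("- none")
    return "\n".join(lines) + "\n"


# -- solution preparation ----------------------------------------------------


def dilution_fraction(s_sample: float, s_target: float, s_brine: float) -> float:
    """Percent of original sample left after brine addition to reach test salinity.

    Mixing a sample at salinity ``s_sample`` (per mille) with hypersaline
    brine at ``s_brine`` to hit ``s_target`` dilutes the sample to the
    mass-balance fraction (s_brine - s_target) / (s_brine - s_sample),
    returned as a percent.  For near-fresh groundwater raised to seawater
    salinity this is the 76-88% concentration range typical of the design.
    """
    if s_sample < 0:
        raise PipelineError(f"sample salinity must be non-negative, got {s_sample}")
    if s_target < s_sample:
        raise PipelineError("target salinity below sample salinity: no brine addition can reach it")
    if s_brine <= s_target:
        raise PipelineError(
            f"brine salinity ({s_brine}) must exceed target ({s_target}) for the adjustment to be feasible"
        )
    return 100.0 * (s_brine - s_target) / (s_brine - s_sample)
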