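"""Weighted five-criterion response matrix: scoring, classification, summaries.

Because many exposures produce partial responses, a single modelled endpoint
is not a reliable basis for calling a test solution toxic to a species.
Instead, five lines of evidence are scored 1 (met), 0.5 (borderline) or 0
(not met) and combined with expert-judgment weights into a response score:

    1. survival through time in the test solution is visually distinct from
       both the HSB and SW controls at one or more observation days (weight 4);
    2. end-of-test mean survival is >= 20 percentage points below the HSB
       control (borderline at 15-20) (weight 3);
    3. end-of-test mean survival is below 80% (borderline at 80-85) (weight 2);
    4. the test solution's LT10 95% confidence range lies below the HSB
       control's (borderline on partial separation) (weight 1);
    5. the same comparison for LT50 (weight 1).

The response score is 100 * sum(w_i * s_i) / sum(w_i); a score of at least
65% classifies the species x test-solution x round combination as a
"Response".  Criterion 1 is an expert visual call in origin; this module
provides a configurable automatic operationalization plus a manual-override
channel so externally judged scores can be injected verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .survival_data import TrialDataset, mean_survival
from .time_response import LTEstimate

__all__ = [
    "ResponseLabel",
    "CriterionScore",
    "CriterionWeights",
    "ResponseAssessment",
    "ResponseMatrix",
    "ScoringError",
    "score_criterion1",
    "score_criterion2",
    "score_criterion3",
    "score_criterion_ci",
    "response_score",
    "classify",
    "microtox_category",
    "summarize_matrix",
    "NO_MEASURABLE_TOXICITY",
    "DEFAULT_THRESHOLD",
]

VALID_SCORES = (0.0, 0.5, 1.0)
DEFAULT_THRESHOLD = 65.0

#: Marker for a Microtox EC50 above 100% dilution.
NO_MEASURABLE_TOXICITY = "NMT"


class ScoringError(Exception):
    """A criterion cannot be scored from the available data."""


class ResponseLabel(str, Enum):
    RESPONSE = "Response"
    NO_RESPONSE = "NoResponse"
    NOT_TESTED = "NotTested"


@dataclass(frozen=True)
class CriterionScore:
    """One criterion's 0 / 0.5 / 1 score with its provenance."""

    criterion: int
    score: float
    basis: str = "auto"  # "auto" | "manual"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.criterion not in (1, 2, 3, 4, 5):
            raise ScoringError(f"criterion must be 1..5, got {self.criterion}")
        if self.score not in VALID_SCORES:
            raise ScoringError(f"score must be one of {VALID_SCORES}, got {self.score}")
        if self.basis not in ("auto", "manual"):
            raise ScoringError(f"basis must be 'auto' or 'manual', got {self.basis!r}")


@dataclass(frozen=True)
class CriterionWeights:
    """Positive expert-judgment weights for the five criteria."""

    w1: float = 4.0
    w2: float = 3.0
    w3: float = 2.0
    w4: float = 1.0
    w5: float = 1.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.as_tuple()):
            raise ScoringError(f"weights must all be positive, got {self.as_tuple()}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.w1, self.w2, self.w3, self.w4, self.w5)

    @property
    def total(self) -> float:
        return sum(self.as_tuple())


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def response_score(
    scores: Sequence[CriterionScore | float],
    weights: CriterionWeights = CriterionWeights(),
) -> tuple[float, int]:
    """Weighted response score as a percentage: (unrounded, rounded).

    ``scores`` are the five criterion scores in order (CriterionScore objects
    or bare 0/0.5/1 values).  Rounding is to the nearest integer, halves away
    from zero, and is for reporting only — classification always uses the
    unrounded value.
    """
    if len(scores) != 5:
        raise ScoringError(f"exactly five criterion scores required, got {len(scores)}")
    values = [s.score if isinstance(s, CriterionScore) else float(s) for s in scores]
    for v in values:
        if v not in VALID_SCORES:
            raise ScoringError(f"score must be one of {VALID_SCORES}, got {v}")
    w = weights.as_tuple()
    pct = 100.0 * sum(wi * si for wi, si in zip(w, values)) / weights.total
    return pct, _round_half_away(pct)


def classify(score: float, threshold: float = DEFAULT_THRESHOLD) -> ResponseLabel:
    """Response if the (unrounded) score is at or above the threshold (default 65%)."""
    if not 0.0 <= score <= 100.0:
        raise ScoringError(f"response score must be in [0, 100], got {score}")
    return ResponseLabel.RESPONSE if score >= threshold else ResponseLabel.NO_RESPONSE


# -- individual criteria -----------------------------------------------------


def _banded_score(value: float, met: float, borderline: float, criterion: int, evidence: str) -> CriterionScore:
    """Score 1 at >= met, 0.5 in [borderline, met), else 0."""
    if value >= met:
        s = 1.0
    elif value >= borderline:
        s = 0.5
    else:
        s = 0.0
    return CriterionScore(criterion, s, "auto", evidence)


def score_criterion1(
    dataset: TrialDataset,
    ts: str,
    margin: float = 20.0,
    borderline_margin: float = 15.0,
) -> CriterionScore:
    """Distinctness of the test-solution time course from BOTH controls.

    Automatic stand-in for the visual raw-data-plot judgment: at each
    observation day the shortfall of mean test-solution survival below the
    *higher-lying* of the two control means is computed; the largest
    day-wise shortfall against both controls drives the score (>= ``margin``
    points -> 1, within [``borderline_margin``, ``margin``) -> 0.5, else 0).
    A manually judged score, when supplied, takes precedence (see
    ResponseAssessment.with_overrides).
    """
    for ctrl in ("HSB", "SW"):
        if ctrl not in dataset.groups:
            raise ScoringError(f"criterion 1 needs both controls; {ctrl!r} missing")
    shortfalls = []
    for day in dataset.schedule:
        ts_mean, _ = mean_survival(dataset, ts, day)
        hsb_mean, _ = mean_survival(dataset, "HSB", day)
        sw_mean, _ = mean_survival(dataset, "SW", day)
        # below BOTH controls: the binding comparison is the lower shortfall
        shortfalls.append(min(hsb_mean - ts_mean, sw_mean - ts_mean))
    worst = max(shortfalls)
    ev = f"max shortfall vs both controls = {worst:.1f} points"
    return _banded_score(worst, margin, borderline_margin, 1, ev)


def score_criterion2(difference: float) -> CriterionScore:
    """End-of-test survival difference (HSB control minus test solution).

    >= 20 points -> 1; 15 to <20 -> 0.5; below 15 -> 0.
    """
    return _banded_score(difference, 20.0, 15.0, 2, f"HSB - TS end survival = {difference:.1f} points")


def score_criterion3(end_survival: float) -> CriterionScore:
    """End-of-test mean survival in the test solution.

    Below 80% -> 1; 80% to 85% inclusive -> 0.5; above 85% -> 0.
    """
    if end_survival < 80.0:
        s = 1.0
    elif end_survival <= 85.0:
        s = 0.5
    else:
        s = 0.0
    return CriterionScore(3, s, "auto", f"end survival = {end_survival:.1f}%")


def score_criterion_ci(
    ts_lt: LTEstimate | None,
    ctrl_lt: LTEstimate | None,
    duration: float,
    criterion: int = 4,
) -> CriterionScore:
    """Confidence-range separation of a test-solution LT from the HSB control's.

    Applied with LT10 estimates for criterion 4 and LT50 for criterion 5:
    score 1 when the test solution's upper limit lies strictly below the
    control's lower limit (disjoint ranges, test solution faster); 0.5 when
    the test solution's upper limit reaches into the control range but its
    point estimate is still below the control's lower limit; otherwise 0.

    When the control is non-modellable (clean control survival gives no
    fittable decline) its LT behaves as "beyond test end", so the fallback
    scores 1 if the test solution's upper limit lies within the test
    duration, else 0.  A missing test-solution estimate scores 0.
    """
    if criterion not in (4, 5):
        raise ScoringError(f"CI criterion must be 4 or 5, got {criterion}")
    if ts_lt is None or not math.isfinite(ts_lt.estimate):
        return CriterionScore(criterion, 0.0, "auto", "not estimable")
    if not (math.isfinite(ts_lt.lower) and math.isfinite(ts_lt.upper)):
        return CriterionScore(criterion, 0.0, "auto", "test-solution CI unavailable")
    if ctrl_lt is None or not math.isfinite(ctrl_lt.estimate):
        s = 1.0 if ts_lt.upper < duration else 0.0
        return CriterionScore(
            criterion, s, "auto",
            f"control not estimable; TS upper {ts_lt.upper:.1f} vs duration {duration:g} d",
        )
    ev = (
        f"TS [{ts_lt.lower:.1f}, {ts_lt.upper:.1f}] est {ts_lt.estimate:.1f}; "
        f"ctrl [{ctrl_lt.lower:.1f}, {ctrl_lt.upper:.1f}]"
    )
    if ts_lt.upper < ctrl_lt.lower:
        return CriterionScore(criterion, 1.0, "auto", ev)
    if ctrl_lt.lower <= ts_lt.upper <= ctrl_lt.upper and ts_lt.estimate < ctrl_lt.lower:
        return CriterionScore(criterion, 0.5, "auto", ev)
    return CriterionScore(criterion, 0.0, "auto", ev)


# -- Microtox ----------------------------------------------------------------

_MICROTOX_BANDS = (
    (25.0, "extremely toxic"),
    (50.0, "highly toxic"),
    (75.0, "moderately toxic"),
    (100.0, "slightly toxic"),
)


def microtox_category(ec50: float | str) -> str:
    """Toxicity band for a 15-min Microtox EC50 expressed as % dilution.

    EC50 <= 25% extremely toxic; (25, 50] highly toxic; (50, 75] moderately
    toxic; (75, 100] slightly toxic; above 100% (or the "NMT" marker) no
    measurable toxicity.
    """
    if isinstance(ec50, str):
        if ec50.strip().upper() == NO_MEASURABLE_TOXICITY:
            return "no measurable toxicity"
        raise ScoringError(f"unrecognised EC50 marker {ec50!r}")
    if not ec50 > 0:
        raise ScoringError(f"EC50 must be positive, got {ec50}")
    for bound, label in _MICROTOX_BANDS:
        if ec50 <= bound:
            return label
    return "no measurable toxicity"


# -- assessments and the matrix ---------------------------------------------


@dataclass(frozen=True)
class ResponseAssessment:
    """The scored matrix row for one species x test solution x round."""

    species: str
    solution: str
    round: int
    scores: tuple[CriterionScore, ...]
    weights: CriterionWeights = CriterionWeights()
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.scores) != 5 or [s.criterion for s in self.scores] != [1, 2, 3, 4, 5]:
            raise ScoringError("scores must be the five criteria in order 1..5")

    @property
    def response_score(self) -> float:
        return response_score(self.scores, self.weights)[0]

    @property
    def response_score_rounded(self) -> int:
        return response_score(self.scores, self.weights)[1]

    @property
    def label(self) -> ResponseLabel:
        return classify(self.response_score, self.threshold)

    def with_overrides(self, overrides: Mapping[int, float]) -> "ResponseAssessment":
        """Replace individual criterion scores with manually judged values."""
        new = []
        for s in self.scores:
            if s.criterion in overrides:
                new.append(
                    CriterionScore(s.criterion, float(overrides[s.criterion]), "manual",
                                   f"manual override (auto was {s.score:g})")
                )
            else:
                new.append(s)
        return replace(self, scores=tuple(new))


@dataclass
class ResponseMatrix:
    """All assessments plus externally supplied labels (e.g. the Microtox assay).

    ``external_labels`` maps (row label, solution, round) to a ResponseLabel;
    rows may be assay names rather than species.  NotTested entries are
    excluded from every summary denominator.
    """

    assessments: list[ResponseAssessment] = field(default_factory=list)
    external_labels: dict[tuple[str, str, int], ResponseLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(a.species, a.solution, a.round) for a in self.assessments]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ScoringError(f"duplicate assessments for {sorted(dupes)}")

    def labels(self) -> dict[tuple[str, str, int], ResponseLabel]:
        """Tested cells only: assessment labels merged with external labels."""
        out = {(a.species, a.solution, a.round): a.label for a in self.assessments}
        for key, label in self.external_labels.items():
            if label is not ResponseLabel.NOT_TESTED:
                out[key] = label
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of the assessments, one row per combination."""
        rows = []
        for a in self.assessments:
            row: dict[str, object] = {
                "species": a.species, "solution": a.solution, "round": a.round,
            }
            for s in a.scores:
                row[f"c{s.criterion}"] = s.score
                row[f"c{s.criterion}_basis"] = s.basis
            row["response_score"] = a.response_score_rounded
            row["judgment"] = a.label.value
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_matrix(
    matrix: ResponseMatrix,
) -> tuple[dict[str, int], dict[str, int]]:
    """Relative-toxicity summary: percent responding per solution and per row.

    Returns ``(percent_toxic_by_solution, percent_toxic_response_by_row)``
    where each percentage is 100 * responses / tested cells (both rounds
    pooled; species and external assays alike count toward the solution
    denominators), rounded to the nearest integer.
    """
    labels = matrix.labels()
    if not labels:
        raise ScoringError("matrix is empty")
    by_solution: dict[str, list[ResponseLabel]] = {}
    by_row: dict[str, list[ResponseLabel]] = {}
    for (row, solution, _round), label in labels.items():
        by_solution.setdefault(solution, []).append(label)
        by_row.setdefault(row, []).append(label)

    def pct(cells: list[ResponseLabel]) -> int:
        hits = sum(1 for c in cells if c is ResponseLabel.RESPONSE)
        return _round_half_away(100.0 * hits / len(cells))

    return (
        {sol: pct(cells) for sol, cells in by_solution.items()},
        {row: pct(cells) for row, cells in by_row.items()},
    )
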