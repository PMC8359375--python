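"""Data model, I/O and descriptive summaries for replicate time-course survival counts.

A direct toxicity assessment (DTA) trial exposes replicate vials of a fixed
cohort of invertebrates (10 individuals per vial by default) to undiluted,
salinity-adjusted groundwater test solutions and to two reference waters — a
hypersaline-brine (HSB) control and a natural seawater (SW) control — and
counts survivors on a fixed observation schedule over a 14- or 21-day press
exposure.  This module holds those counts in a tidy, validated container and
provides the per-group descriptive summaries the response criteria consume.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "ObservationSchedule",
    "SurvivalObservation",
    "TrialDataset",
    "SurvivalDataError",
    "SurvivalFormatError",
    "SurvivalValidationError",
    "SurvivalLookupError",
    "read_survival_table",
    "read_survival_trials",
    "write_survival_table",
    "mean_survival",
    "end_survival_difference",
]

#: Canonical tidy-table column order.
COLUMNS = ("species", "round", "group", "replicate", "day", "n_alive", "n_initial")

#: Group labels recognised as controls.
CONTROL_GROUPS = ("HSB", "SW")

#: Observation schedules used in the study design (days).
SCHEDULE_14D = (1.0, 2.0, 4.0, 7.0, 10.0, 14.0)
SCHEDULE_21D = (4.0, 7.0, 10.0, 14.0, 21.0)


class SurvivalDataError(Exception):
    """Base class for survival-data errors."""


class SurvivalFormatError(SurvivalDataError):
    """A table does not have the expected columns or parseable values."""


class SurvivalValidationError(SurvivalDataError):
    """A table violates a hard invariant (e.g. more alive than initial)."""


class SurvivalLookupError(SurvivalDataError, KeyError):
    """A requested group or observation day is absent from the dataset."""


@dataclass(frozen=True)
class ObservationSchedule:
    """Ordered observation times in days; the last day is the test duration."""

    days: tuple[float, ...]

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        if len(days) == 0:
            raise SurvivalValidationError("schedule must contain at least one day")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise SurvivalValidationError(f"schedule days must be strictly increasing: {days}")
        if days[0] < 1:
            raise SurvivalValidationError(f"first observation day must be >= 1, got {days[0]}")
        object.__setattr__(self, "days", days)

    @property
    def duration(self) -> float:
        """Test duration in days (the final scheduled observation)."""
        return self.days[-1]

    def __iter__(self):
        return iter(self.days)

    def __len__(self) -> int:
        return len(self.days)


@dataclass(frozen=True)
class SurvivalObservation:
    """One replicate count: survivors out of the initial cohort on one day."""

    species: str
    round: int
    group: str
    replicate: int
    day: float
    n_alive: int
    n_initial: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_alive <= self.n_initial:
            raise SurvivalValidationError(
                f"n_alive must satisfy 0 <= n_alive <= n_initial, got "
                f"{self.n_alive}/{self.n_initial} "
                f"({self.species} r{self.round} {self.group} rep {self.replicate} day {self.day})"
            )

    @property
    def percent_survival(self) -> float:
        return 100.0 * self.n_alive / self.n_initial


class TrialDataset:
    """Replicate-level time-course survival for one species x round across groups.

    Parameters
    ----------
    observations
        The replicate counts.  All must share the same species and round.
    schedule
        The observation schedule.  Derived from the observed days if omitted.
    metadata
        Free-form trial metadata (collection site, test volume, chemistry).
    """

    def __init__(
        self,
        observations: Iterable[SurvivalObservation],
        schedule: ObservationSchedule | None = None,
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        obs = list(observations)
        if not obs:
            raise SurvivalValidationError("dataset must contain at least one observation")
        keys = {(o.species, o.round) for o in obs}
        if len(keys) != 1:
            raise SurvivalValidationError(
                f"a TrialDataset holds one species x round; got {sorted(keys)}"
            )
        ((self.species, self.round),) = keys
        if schedule is None:
            schedule = ObservationSchedule(tuple(sorted({o.day for o in obs})))
        self.schedule = schedule
        self.metadata: dict[str, object] = dict(metadata or {})
        self.observations: list[SurvivalObservation] = obs
        self._frame = pd.DataFrame([o.__dict__ for o in obs], columns=list(COLUMNS))
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        df = self._frame
        extra = set(df["day"]) - set(self.schedule.days)
        if extra:
            raise SurvivalValidationError(
                f"observation days {sorted(extra)} not on schedule {self.schedule.days}"
            )
        for (group, rep), g in df.groupby(["group", "replicate"], sort=False):
            missing = set(self.schedule.days) - set(g["day"])
            if missing:
                raise SurvivalValidationError(
                    f"group {group!r} replicate {rep} missing days {sorted(missing)}"
                )
            ordered = g.sort_values("day")["n_alive"].to_numpy()
            if np.any(np.diff(ordered) > 0):
                # Recounting noise is possible in the raw data: warn, keep.
                warnings.warn(
                    f"n_alive increases within replicate {group!r}/{rep} of "
                    f"{self.species} round {self.round}; keeping as observed",
                    UserWarning,
                    stacklevel=3,
                )

    # -- accessors -----------------------------------------------------------

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self._frame["group"]))

    @property
    def test_solutions(self) -> list[str]:
        """Non-control group labels."""
        return [g for g in self.groups if g not in CONTROL_GROUPS]

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame copy with the canonical seven columns."""
        return self._frame.copy()

    def group_survival(self, group: str) -> pd.DataFrame:
        """Replicate-level (day, percent survival) pairs for one group."""
        g = self._frame[self._frame["group"] == group]
        if g.empty:
            raise SurvivalLookupError(f"unknown group {group!r}")
        out = g[["replicate", "day"]].copy()
        out["percent_survival"] = 100.0 * g["n_alive"] / g["n_initial"]
        return out.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.observations)

    def __repr__(self) -> str:
        return (
            f"TrialDataset(species={self.species!r}, round={self.round}, "
            f"groups={self.groups}, n_obs={len(self)})"
        )


# -- I/O ---------------------------------------------------------------------


def _frame_to_observations(df: pd.DataFrame, source: str) -> list[SurvivalObservation]:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SurvivalFormatError(f"{source}: missing required column(s) {missing}")
    obs = []
    for idx, row in df.iterrows():
        try:
            obs.append(
                SurvivalObservation(
                    species=str(row["species"]),
                    round=int(row["round"]),
                    group=str(row["group"]),
                    replicate=int(row["replicate"]),
                    day=float(row["day"]),
                    n_alive=int(row["n_alive"]),
                    n_initial=int(row["n_initial"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SurvivalFormatError(f"{source}: unparseable values in row {idx}: {exc}") from exc
        except SurvivalValidationError as exc:
            raise SurvivalValidationError(f"{source}: row {idx}: {exc}") from exc
    return obs


def read_survival_trials(
    path: str | Path | io.TextIOBase, dialect: str = ","
) -> dict[tuple[str, int], TrialDataset]:
    """Read a tidy survival CSV/TSV and split it into one dataset per species x round.

    Parameters
    ----------
    path
        File path or open text handle.
    dialect
        Field delimiter; "," (default) or "\\t".
    """
    df = pd.read_csv(path, sep=dialect)
    source = getattr(path, "name", str(path))
    if df.empty:
        raise SurvivalFormatError(f"{source}: no data rows")
    obs = _frame_to_observations(df, source)
    out: dict[tuple[str, int], TrialDataset] = {}
    for key in dict.fromkeys((o.species, o.round) for o in obs):
        out[key] = TrialDataset([o for o in obs if (o.species, o.round) == key])
    return out


def read_survival_table(path: str | Path | io.TextIOBase, dialect: str = ",") -> TrialDataset:
    """Read a tidy survival table containing a single species x round trial."""
    trials = read_survival_trials(path, dialect=dialect)
    if len(trials) != 1:
        raise SurvivalFormatError(
            f"expected a single species x round, found {sorted(trials)}; "
            "use read_survival_trials for multi-trial files"
        )
    (dataset,) = trials.values()
    return dataset


def write_survival_table(
    datasets: TrialDataset | Iterable[TrialDataset],
    path: str | Path | io.TextIOBase,
    dialect: str = ",",
) -> None:
    """Write one or more trial datasets back to the tidy seven-column format."""
    if isinstance(datasets, TrialDataset):
        datasets = [datasets]
    df = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    # integer counts round-trip exactly; day kept as a general float
    df.to_csv(path, sep=dialect, index=False)


# -- descriptive summaries ---------------------------------------------------


def mean_survival(dataset: TrialDataset, group: str, day: float) -> tuple[float, float]:
    """Mean and SD of percent survival across replicates of ``group`` at ``day``.

    Percent survival is computed per replicate and then averaged; the SD uses
    the n-1 (sample) denominator, matching a mean +/- SD summary over
    replicate vials.
    """
    g = dataset.group_survival(group)
    at_day = g[g["day"] == float(day)]
    if at_day.empty:
        raise SurvivalLookupError(f"group {group!r} has no observation at day {day}")
    values = at_day["percent_survival"].to_numpy()
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return float(np.mean(values)), sd


def end_survival_difference(dataset: TrialDataset, ts: str, control: str = "HSB") -> float:
    """Control-minus-test-solution mean survival at the final scheduled day.

    The quantity feeding response criterion 2: percentage points by which mean
    survival in the test solution falls short of the control at test end.
    Negative values (test solution outliving the control) are legitimate.
    """
    last = dataset.schedule.duration
    ctrl_mean, _ = mean_survival(dataset, control, last)
    ts_mean, _ = mean_survival(dataset, ts, last)
    return ctrl_mean - ts_mean
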