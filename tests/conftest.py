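"""Shared fixtures: printed worked-example data and synthetic trials."""

from __future__ import annotations

import pytest

from toxdta import (
    ObservationSchedule,
    ResponseLabel,
    ResponseMatrix,
    SyntheticConfig,
    SyntheticGroupConfig,
    generate_trial,
)
from toxdta.survival_data import SCHEDULE_14D

# Published worked example: for two species the five criterion scores, the
# expected weighted response score (rounded) and the classification.  The
# first row's printed total (93) disagrees with its own criteria, which give
# 91; the expected value here is what the formula yields.
RESPONSE_MATRIX_EXCERPT = [
    # species, solution, (c1..c5), end_survival, difference, expected score, response?
    ("Gaimardia trapesina", "TS1", (1, 1, 1, 0, 1), 0, 78, 91, True),
    ("Gaimardia trapesina", "TS2", (1, 1, 1, 1, 1), 0, 78, 100, True),
    ("Gaimardia trapesina", "TS3", (0, 0, 0, 0, 0), 96, -18, 0, False),
    ("Gaimardia trapesina", "TS4", (0, 0, 0.5, 0, 0), 85, -7, 9, False),
    ("Gaimardia trapesina", "TS5", (1, 0.5, 1, 0, 0), 61, 18, 68, True),
    ("Gaimardia trapesina", "TS6", (1, 1, 1, 1, 1), 0, 78, 100, True),
    ("Gaimardia trapesina", "TS7", (0, 0, 0, 0, 0), 96, -18, 0, False),
    ("Parawaldeckia kidderi", "TS1", (0, 0, 1, 0, 0), 78, 2, 18, False),
    ("Parawaldeckia kidderi", "TS2", (0, 0, 0, 0, 0), 88, -8, 0, False),
    ("Parawaldeckia kidderi", "TS3", (0, 0, 1, 0, 0), 78, 2, 18, False),
    ("Parawaldeckia kidderi", "TS4", (0, 0, 0, 0, 0), 88, -8, 0, False),
    ("Parawaldeckia kidderi", "TS6", (0, 0, 0, 0, 0), 90, -10, 0, False),
    ("Parawaldeckia kidderi", "TS7", (0.5, 0, 1, 0, 0.5), 70, 10, 41, False),
]

# Published summary grid: per row (species or the Microtox assay), the
# Response / no-response / not-tested status for each test solution in each
# round.  "R" = response, "N" = no response, None = not tested.
_SOLUTIONS = ("TS1", "TS2", "TS3", "TS4", "TS5", "TS6", "TS7")

SUMMARY_GRID: dict[str, dict[str, tuple[str | None, str | None]]] = {
    # name: {solution: (round 1, round 2)}
    "Paramoera sp.": dict(zip(_SOLUTIONS, [("N", None)] * 7)),
    "Parawaldeckia kidderi": dict(zip(_SOLUTIONS, [
        (None, "N"), (None, "N"), (None, "N"), (None, "N"),
        (None, None), (None, "N"), (None, "N")])),
    "Exosphaeroma gigas": dict(zip(_SOLUTIONS, [
        ("R", None), ("N", None), ("N", None), ("N", None),
        ("N", None), ("R", None), ("N", None)])),
    "Zaus sp.": dict(zip(_SOLUTIONS, [
        ("R", "R"), ("R", "R"), ("N", "N"), ("R", "R"),
        ("R", None), ("R", "R"), ("N", "N")])),
    "Tigriopus angulatus": dict(zip(_SOLUTIONS, [
        ("N", "N"), ("N", "R"), ("N", "N"), ("R", "R"),
        ("N", None), ("N", "N"), ("N", "R")])),
    "Laevilitorina caliginosa": dict(zip(_SOLUTIONS, [
        ("N", "R"), ("N", "R"), ("N", "N"), ("N", "N"),
        ("N", None), ("N", "N"), ("N", "N")])),
    "Macquariella hamiltoni": dict(zip(_SOLUTIONS, [
        ("R", "R"), ("R", "R"), ("N", "N"), ("R", "R"),
        ("R", None), ("R", "R"), ("N", "N")])),
    "Gaimardia trapesina": dict(zip(_SOLUTIONS, [
        ("R", "R"), ("R", "R"), ("N", "N"), ("N", "N"),
        ("R", None), ("R", "R"), ("N", "N")])),
    "Lasaea hinemoa": dict(zip(_SOLUTIONS, [
        (None, "N"), (None, "N"), (None, "N"), (None, "N"),
        (None, None), (None, "N"), (None, "N")])),
    "Obrimoposthia ohlini": dict(zip(_SOLUTIONS, [
        (None, "R"), (None, "N"), (None, "N"), (None, "N"),
        (None, None), (None, "N"), (None, "N")])),
    "Obrimoposthia wandeli": dict(zip(_SOLUTIONS, [
        ("N", "R"), ("N", "N"), ("N", "N"), ("N", "R"),
        ("N", None), ("N", "N"), ("N", "N")])),
    "Microtox test": dict(zip(_SOLUTIONS, [
        ("N", "R"), ("N", "R"), ("N", "N"), ("R", "R"),
        ("N", None), ("N", "N"), ("N", "N")])),
}


def summary_grid_matrix() -> ResponseMatrix:
    """The summary grid as a ResponseMatrix of external labels."""
    labels = {}
    for name, by_solution in SUMMARY_GRID.items():
        for solution, (r1, r2) in by_solution.items():
            for rnd, status in ((1, r1), (2, r2)):
                if status is not None:
                    labels[(name, solution, rnd)] = (
                        ResponseLabel.RESPONSE if status == "R" else ResponseLabel.NO_RESPONSE
                    )
    return ResponseMatrix([], labels)


@pytest.fixture(scope="session")
def summary_matrix() -> ResponseMatrix:
    return summary_grid_matrix()


@pytest.fixture(scope="session")
def toxic_trial():
    """A synthetic trial with one clearly toxic test solution, one benign, and
    both controls at realistic background mortality."""
    cfg = SyntheticConfig(
        groups=(
            SyntheticGroupConfig("TS1", lt50_true=5.0, shape_true=4.0, immune_fraction=0.0),
            SyntheticGroupConfig("TS2", lt50_true=30.0, shape_true=3.0, immune_fraction=0.95),
            SyntheticGroupConfig("HSB", lt50_true=30.0, shape_true=3.0,
                                 immune_fraction=0.8, n_replicates=6),
            SyntheticGroupConfig("SW", lt50_true=30.0, shape_true=3.0,
                                 immune_fraction=0.8, n_replicates=6),
        ),
        schedule=ObservationSchedule(SCHEDULE_14D),
        seed=42,
        species="testspecies",
        round=1,
    )
    return generate_trial(cfg)
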