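"""Worked-example dataset reconstruction and dataset I/O.

The worked example is a content analysis of n = 110 newspaper reports of
cyber-abuse incidents.  Each incident carries three binary variables:

* ``Method``       — 0 = direct abuse, 1 = indirect abuse (the response),
* ``Relationship`` — 0 = no prior offender–victim relationship, 1 = prior
  relationship,
* ``Motivation``   — 0 = instrumental, 1 = expressive.

The published summary gives, for each of the four (Relationship, Motivation)
predictor cells, the cell total and the proportion of indirect-method cases.
Because the predictors are binary, those four totals and proportions determine
the individual-level dataset exactly (up to row order), so the dataset is
reconstructed here from frozen integer counts rather than shipped as a file.

Cells are indexed throughout in "profile" order

    1: (Rel=0, Mot=0)   2: (Rel=1, Mot=0)   3: (Rel=0, Mot=1)   4: (Rel=1, Mot=1)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "PROFILE_ORDER",
    "CodingScheme",
    "CellTable",
    "ObservationSet",
    "DatasetError",
    "MissingColumnError",
    "EmptyDatasetError",
    "CodedLevelError",
    "reconstruct_example_cells",
    "expand_to_observations",
    "collapse_to_cells",
    "example_observations",
    "read_dataset",
    "write_dataset",
]

#: Column names of the study CSV layout, in file order.
COLUMNS = ("Method", "Relationship", "Motivation")

#: (Relationship, Motivation) codes of the four predictor cells, profile order.
PROFILE_ORDER: tuple[tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1))

_DEFAULT_CODING: Mapping[str, tuple[str, str]] = {
    "Method": ("Direct", "Indirect"),
    "Relationship": ("No prior relationship", "Prior relationship"),
    "Motivation": ("Instrumental", "Expressive"),
}


class DatasetError(ValueError):
    """Base class for malformed study datasets."""


class MissingColumnError(DatasetError):
    """A required column is absent from the input."""


class EmptyDatasetError(DatasetError):
    """The input contains no data rows."""


class CodedLevelError(DatasetError):
    """A value outside the {0, 1} coding was encountered."""


@dataclass(frozen=True)
class CodingScheme:
    """Mapping from each binary variable to its (level-0, level-1) labels."""

    levels: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_CODING)
    )

    def __post_init__(self) -> None:
        if set(self.levels) != set(COLUMNS):
            raise ValueError(f"coding scheme must define exactly {COLUMNS}")
        for name, labels in self.levels.items():
            if len(tuple(labels)) != 2:
                raise ValueError(f"variable {name!r} must have exactly two levels")

    def label(self, variable: str, code: int) -> str:
        if code not in (0, 1):
            raise CodedLevelError(f"code for {variable!r} must be 0 or 1, got {code}")
        return self.levels[variable][code]


@dataclass(frozen=True)
class CellTable:
    """Counts for the four (Relationship, Motivation) predictor cells.

    ``totals[i]`` is the number of incidents in profile ``i`` (see
    :data:`PROFILE_ORDER`); ``successes[i]`` is how many of those used the
    indirect method (``Method = 1``).
    """

    totals: tuple[int, int, int, int]
    successes: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.totals) != 4 or len(self.successes) != 4:
            raise ValueError("a CellTable has exactly four cells")
        for n, s in zip(self.totals, self.successes):
            if int(n) != n or int(s) != s:
                raise ValueError("cell counts must be integers")
            if n < 0 or s < 0:
                raise ValueError("cell counts must be non-negative")
            if s > n:
                raise ValueError("indirect count exceeds cell total")
        object.__setattr__(self, "totals", tuple(int(n) for n in self.totals))
        object.__setattr__(self, "successes", tuple(int(s) for s in self.successes))

    # -- derived quantities -------------------------------------------------

    @property
    def grand_total(self) -> int:
        return sum(self.totals)

    @property
    def total_successes(self) -> int:
        return sum(self.successes)

    def proportions(self) -> np.ndarray:
        """Observed proportion of indirect method per cell (NaN if empty)."""
        n = np.asarray(self.totals, dtype=float)
        s = np.asarray(self.successes, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, s / n, np.nan)

    def cell_logits(self) -> np.ndarray:
        """log-odds of the observed cell proportions (the saturated-fit MLEs)."""
        n = np.asarray(self.totals, dtype=float)
        s = np.asarray(self.successes, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.log(s / (n - s))

    def rel_codes(self) -> np.ndarray:
        return np.array([r for r, _ in PROFILE_ORDER], dtype=float)

    def mot_codes(self) -> np.ndarray:
        return np.array([m for _, m in PROFILE_ORDER], dtype=float)

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "profile": [1, 2, 3, 4],
                "Relationship": [r for r, _ in PROFILE_ORDER],
                "Motivation": [m for _, m in PROFILE_ORDER],
                "n": self.totals,
                "n_indirect": self.successes,
                "proportion": self.proportions(),
            }
        )

    def to_json(self) -> str:
        payload = {
            "cells": [
                {"Relationship": r, "Motivation": m, "n_total": n, "n_indirect": s}
                for (r, m), n, s in zip(PROFILE_ORDER, self.totals, self.successes)
            ],
            "grand_total": self.grand_total,
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True, eq=False)
class ObservationSet:
    """Individual-level binary observations in the study layout.

    Wraps a DataFrame with integer 0/1 columns ``Method``, ``Relationship``,
    ``Motivation``.  ``provenance`` records where the rows came from
    (``reconstructed`` / ``file`` / ``simulated``); ``seed`` is recorded for
    simulated data.
    """

    frame: pd.DataFrame
    provenance: str = "file"
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", _validate_frame(self.frame))

    def __len__(self) -> int:
        return len(self.frame)

    def to_dataframe(self) -> pd.DataFrame:
        return self.frame.copy()

    def means(self) -> pd.Series:
        """Per-variable sample means (the descriptive-statistics summary)."""
        return self.frame[list(COLUMNS)].mean()

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise MissingColumnError(f"missing column(s): {', '.join(missing)}")
    out = pd.DataFrame(index=range(len(frame)))
    for col in COLUMNS:
        values = frame[col].to_numpy()
        coded = np.empty(len(values), dtype=np.int8)
        for i, v in enumerate(values):
            try:
                iv = int(str(v).strip())
            except (TypeError, ValueError):
                iv = -1
            if iv not in (0, 1):
                raise CodedLevelError(
                    f"row {i}, column {col!r}: value {v!r} is not a 0/1 code"
                )
            coded[i] = iv
        out[col] = coded
    return out


# -- the worked example ------------------------------------------------------

#: Frozen reconstruction of the example dataset's cell counts.  The published
#: per-cell proportions (0.22, 0.27, 0.34, 0.62) times the published totals
#: (18, 11, 29, 52) round to these integer indirect-method counts; the
#: reconstruction is confirmed by the published per-cell log-odds
#: (-1.25, -0.98, -0.64, 0.47).
_EXAMPLE_TOTALS = (18, 11, 29, 52)
_EXAMPLE_SUCCESSES = (4, 3, 10, 32)


def reconstruct_example_cells() -> CellTable:
    """Cell counts of the cyber-abuse worked example (n = 110)."""
    return CellTable(_EXAMPLE_TOTALS, _EXAMPLE_SUCCESSES)


def expand_to_observations(
    cells: CellTable, provenance: str = "reconstructed", seed: int | None = None
) -> ObservationSet:
    """One row per subject, in a fixed deterministic order.

    Cells are laid out lexicographically in (Relationship, Motivation) and,
    within a cell, indirect-method rows (Method = 1) precede direct ones, so
    repeated expansions are byte-identical.
    """
    lex = sorted(range(4), key=lambda i: PROFILE_ORDER[i])
    method, rel, mot = [], [], []
    for i in lex:
        r, m = PROFILE_ORDER[i]
        n, s = cells.totals[i], cells.successes[i]
        method.extend([1] * s + [0] * (n - s))
        rel.extend([r] * n)
        mot.extend([m] * n)
    frame = pd.DataFrame(
        {"Method": method, "Relationship": rel, "Motivation": mot}, dtype=np.int8
    )
    return ObservationSet(frame, provenance=provenance, seed=seed)


def collapse_to_cells(obs: ObservationSet) -> CellTable:
    """Inverse of :func:`expand_to_observations` up to row order."""
    rel = obs.column("Relationship")
    mot = obs.column("Motivation")
    y = obs.column("Method")
    totals, successes = [], []
    for r, m in PROFILE_ORDER:
        mask = (rel == r) & (mot == m)
        totals.append(int(mask.sum()))
        successes.append(int(y[mask].sum()))
    return CellTable(tuple(totals), tuple(successes))


def example_observations() -> ObservationSet:
    """The reconstructed 110-row worked-example dataset."""
    return expand_to_observations(reconstruct_example_cells())


# -- CSV I/O -----------------------------------------------------------------


def read_dataset(path: str | Path) -> ObservationSet:
    """Read a comma-separated dataset with a Method,Relationship,Motivation header."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"{path}: file is empty") from exc
    if len(frame) == 0:
        raise EmptyDatasetError(f"{path}: no data rows")
    return ObservationSet(frame, provenance="file")


def write_dataset(obs: ObservationSet, path: str | Path) -> None:
    """Write in the study's CSV dialect (comma separator, header, 0/1 values)."""
    obs.frame.to_csv(Path(path), index=False)
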