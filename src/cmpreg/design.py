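"""Categorical coding and design-matrix construction.

All three model parts use treatment (dummy) coding with the first level of
each variable as the baseline, matching the conventions of the Thai
road-accident study this package was validated against: National highway,
Dry, Straight, Clear, Day and January are the reference levels.  Column
order is deterministic: variables in the order requested, levels in coding
order, preceded by an intercept column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .frequency import CountFrequencyTable

MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


@dataclass(frozen=True)
class CategoricalCoding:
    """Ordered level labels per variable; the first level is the baseline."""

    levels: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        for var, levs in self.levels.items():
            if len(levs) == 0:
                raise ValueError(f"variable {var!r} has no levels")
            if len(set(levs)) != len(levs):
                raise ValueError(f"variable {var!r} has duplicate levels")

    def baseline(self, variable: str) -> str:
        return self.levels[variable][0]


#: Coding of the six study covariates, baselines first.
THAILAND_CODING = CategoricalCoding(
    {
        "roadway_class": ("National highway", "Rural highway", "Urban road", "Local street"),
        "road_surface": ("Dry", "Wet"),
        "road_section": ("Straight", "Curve", "Crossing and others"),
        "weather": ("Clear", "Fog", "Rain"),
        "light": ("Day", "Night with light", "Night without light"),
        "month": MONTHS,
    }
)


@dataclass
class DesignSet:
    """Outcome, case weights and the three model-part design matrices.

    ``X`` parameterizes the rate (log link), ``S`` the dispersion (log
    link) and ``W`` the structural-zero probability (logit link).  Every
    matrix has one row per observation and a leading intercept column.
    A frequency table maps to one row per distinct outcome value with the
    frequency as case weight.
    """

    y: np.ndarray
    w: np.ndarray
    X: np.ndarray
    S: np.ndarray
    W: np.ndarray
    x_names: list[str]
    s_names: list[str]
    w_names: list[str]
    coding: CategoricalCoding | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        n = len(self.y)
        if np.any(self.y < 0):
            raise ValueError("outcome must be nonnegative")
        if np.any(self.w <= 0):
            raise ValueError("case weights must be positive")
        for name, mat in (("X", self.X), ("S", self.S), ("W", self.W)):
            if mat.shape[0] != n:
                raise ValueError(f"{name} has {mat.shape[0]} rows for {n} observations")
            if not np.allclose(mat[:, 0], 1.0):
                raise ValueError(f"{name} must carry a leading intercept column")

    @property
    def n_obs(self) -> float:
        """Effective number of observations (sum of case weights)."""
        return float(self.w.sum())

    @classmethod
    def from_frequency(cls, table: CountFrequencyTable) -> "DesignSet":
        """Intercept-only design with frequencies as case weights."""
        k = len(table.values)
        ones = np.ones((k, 1))
        return cls(
            y=table.values,
            w=table.counts.astype(float),
            X=ones, S=ones.copy(), W=ones.copy(),
            x_names=["(Intercept)"], s_names=["(Intercept)"], w_names=["(Intercept)"],
        )

    @classmethod
    def from_outcome(cls, y, w=None) -> "DesignSet":
        """Intercept-only design over record-level outcomes."""
        y = np.asarray(y, dtype=np.int64)
        w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
        ones = np.ones((len(y), 1))
        return cls(
            y=y, w=w, X=ones, S=ones.copy(), W=ones.copy(),
            x_names=["(Intercept)"], s_names=["(Intercept)"], w_names=["(Intercept)"],
        )


def _encode_part(
    records: pd.DataFrame, terms: Sequence[str], coding: CategoricalCoding
) -> tuple[np.ndarray, list[str]]:
    n = len(records)
    columns = [np.ones(n)]
    names = ["(Intercept)"]
    for var in terms:
        if var not in coding.levels:
            raise KeyError(f"variable {var!r} has no coding")
        if var not in records.columns:
            raise KeyError(f"variable {var!r} is not a record column")
        levels = list(coding.levels[var])
        observed = records[var].astype(object)
        unknown = ~observed.isin(levels)
        if unknown.any():
            idx = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValueError(
                f"record {idx}: unknown level {observed.iloc[idx]!r} for variable {var!r}"
            )
        for level in levels[1:]:
            columns.append((observed == level).to_numpy(dtype=float))
            names.append(f"{var}[{level}]")
    return np.column_stack(columns), names


def build_design(
    records: pd.DataFrame,
    count_terms: Sequence[str] = (),
    dispersion_terms: Sequence[str] = (),
    zero_terms: Sequence[str] = (),
    coding: CategoricalCoding = THAILAND_CODING,
    outcome: str = "fatalities",
    weights: str | None = None,
) -> DesignSet:
    """Build the three treatment-coded design matrices from tabular records.

    Empty term lists give intercept-only parts.  Unknown levels raise with
    the offending record index; the outcome column must hold nonnegative
    integers.
    """
    if outcome not in records.columns:
        raise KeyError(f"outcome column {outcome!r} missing from records")
    y_raw = records[outcome].to_numpy()
    y = np.asarray(y_raw, dtype=np.int64)
    if np.any(y != y_raw) or np.any(y < 0):
        raise ValueError(f"outcome column {outcome!r} must hold nonnegative integers")
    w = (
        records[weights].to_numpy(dtype=float)
        if weights is not None
        else np.ones(len(records))
    )
    X, x_names = _encode_part(records, count_terms, coding)
    S, s_names = _encode_part(records, dispersion_terms, coding)
    W, w_names = _encode_part(records, zero_terms, coding)
    return DesignSet(
        y=y, w=w, X=X, S=S, W=W,
        x_names=x_names, s_names=s_names, w_names=w_names, coding=coding,
    )
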