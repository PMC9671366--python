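"""Outcome frequency tables: distinct count value -> number of observations.

A frequency table is the natural exchange format for intercept-only count
models: fitting the table with case weights equal to the frequencies is
exactly equivalent to fitting the expanded record-level vector.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np


class CountFrequencyTable:
    """Immutable mapping from nonnegative integer outcome values to counts."""

    def __init__(self, counts: Mapping[int, int]):
        items = []
        seen = set()
        for value, count in counts.items():
            v = int(value)
            c = int(count)
            if v != value or v < 0:
                raise ValueError(f"outcome values must be nonnegative integers, got {value!r}")
            if c != count or c < 0:
                raise ValueError(f"counts must be nonnegative integers, got {count!r}")
            if v in seen:
                raise ValueError(f"duplicate outcome value {v}")
            seen.add(v)
            items.append((v, c))
        items.sort()
        self._values = np.array([v for v, _ in items], dtype=np.int64)
        self._counts = np.array([c for _, c in items], dtype=np.int64)
        if self.n == 0:
            raise ValueError("frequency table is empty")

    @classmethod
    def from_records(cls, y) -> "CountFrequencyTable":
        values, counts = np.unique(np.asarray(y, dtype=np.int64), return_counts=True)
        return cls(dict(zip(values.tolist(), counts.tolist())))

    @property
    def values(self) -> np.ndarray:
        return self._values.copy()

    @property
    def counts(self) -> np.ndarray:
        return self._counts.copy()

    @property
    def n(self) -> int:
        """Total number of observations."""
        return int(self._counts.sum())

    @property
    def n_zero(self) -> int:
        """Number of observations with outcome zero."""
        mask = self._values == 0
        return int(self._counts[mask].sum()) if mask.any() else 0

    @property
    def total(self) -> int:
        """Sum of the outcome over all observations."""
        return int((self._values * self._counts).sum())

    @property
    def mean(self) -> float:
        return self.total / self.n

    @property
    def variance(self) -> float:
        """Unbiased sample variance of the expanded records."""
        if self.n < 2:
            return float("nan")
        m = self.mean
        ss = float((self._counts * (self._values - m) ** 2).sum())
        return ss / (self.n - 1)

    def expand(self) -> np.ndarray:
        """One outcome value per observation, in ascending order."""
        return np.repeat(self._values, self._counts)

    def as_dict(self) -> dict[int, int]:
        return dict(zip(self._values.tolist(), self._counts.tolist()))

    def items(self):
        return self.as_dict().items()

    def __eq__(self, other) -> bool:
        return isinstance(other, CountFrequencyTable) and self.as_dict() == other.as_dict()

    def __repr__(self) -> str:
        return f"CountFrequencyTable({self.as_dict()!r})"
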