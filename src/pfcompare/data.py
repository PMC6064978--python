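"""The Dataset container: binomial trial summaries per (condition, level) cell."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError


@dataclass
class ConditionData:
    """One condition: stimulus levels with positive-response and trial counts."""

    levels: np.ndarray
    k: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, float)
        self.k = np.asarray(self.k, int)
        self.n = np.asarray(self.n, int)
        if not (self.levels.shape == self.k.shape == self.n.shape):
            raise DataError("levels, k and n must have equal length")
        if len(np.unique(self.levels)) != len(self.levels):
            raise DataError("stimulus levels within a condition must be distinct")
        if np.any(self.n < 1):
            raise DataError("every cell needs at least one trial")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise DataError("response counts must satisfy 0 <= k <= n")

    @property
    def proportions(self) -> np.ndarray:
        return self.k / self.n

    @property
    def n_cells(self) -> int:
        return len(self.levels)

    def is_degenerate(self) -> bool:
        """True when all responses agree (all k = 0 or all k = n).

        Such a condition carries no information about where the function
        rises; fits proceed but results are flagged.
        """
        return bool(np.all(self.k == 0) or np.all(self.k == self.n))


@dataclass
class Dataset:
    """Trial summaries for one or more conditions.

    Conditions are indexed 0-based internally; ``labels`` keeps the user's
    own condition identifiers in file order.
    """

    conditions: list[ConditionData]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise DataError("a Dataset needs at least one condition")
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.conditions))]
        if len(self.labels) != len(self.conditions):
            raise DataError("one label per condition required")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_cells(self) -> int:
        """Total number of (condition, level) cells across all conditions."""
        return sum(c.n_cells for c in self.conditions)

    @property
    def n_trials(self) -> int:
        return int(sum(c.n.sum() for c in self.conditions))

    def degenerate_conditions(self) -> list[int]:
        return [i for i, c in enumerate(self.conditions) if c.is_degenerate()]
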