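"""Abundance matrix container with explicit processing state and lineage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List

import pandas as pd

#: Declared processing order; state may only advance along this sequence.
STATE_ORDER = ("raw", "floored", "log2", "imputed", "normalized")


class StateError(RuntimeError):
    """An operation was applied to a matrix in the wrong processing state."""


@dataclass
class AbundanceMatrix:
    """Features x samples intensities with provenance.

    ``data`` holds raw-scale intensities while ``state`` is ``raw`` or
    ``floored`` and log2 intensities from ``log2`` onwards; missing
    observations are NaN.  ``lineage`` is an append-only record of the
    operations applied, with their parameters.
    """

    data: pd.DataFrame
    state: str = "raw"
    lineage: List[Dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in STATE_ORDER:
            raise ValueError(f"unknown state {self.state!r}")
        self.data.index.name = self.data.index.name or "feature"

    @property
    def features(self) -> List[str]:
        return list(self.data.index)

    @property
    def samples(self) -> List[str]:
        return list(self.data.columns)

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise StateError(
                f"operation requires state in {allowed}, matrix is {self.state!r}"
            )

    def evolve(self, data: pd.DataFrame, state: str, op: str, **params) -> "AbundanceMatrix":
        """New matrix with ``op`` appended to the lineage.

        The state may stay put (e.g. a filter) or advance, never regress.
        """
        if STATE_ORDER.index(state) < STATE_ORDER.index(self.state):
            raise StateError(f"cannot move state back from {self.state} to {state}")
        entry = {"op": op, "state": state, **params}
        return AbundanceMatrix(data, state, [*self.lineage, entry])

    def completeness(self) -> pd.Series:
        """Per-sample fraction of present (non-missing) features."""
        if self.data.shape[0] == 0:
            return pd.Series(1.0, index=self.data.columns)
        return self.data.notna().mean(axis=0)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, state: str = "normalized") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, state=state, lineage=[{"op": "load", "state": state, "path": str(path)}])
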