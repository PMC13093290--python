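"""Experimental sample design.

The study layout this package targets is a factorial thermal-stress
experiment: several coral species held in replicate flow-through tanks under
two treatments (ambient vs. heat stress), sampled at a small number of
timepoints.  One species may undergo polyp bail-out and therefore contribute
no stress samples at the final timepoint; the design object represents that
missing cell explicitly rather than padding it.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

TREATMENTS = ("ambient", "stress")
DEFAULT_TIMEPOINTS = ("TP0", "TP1", "TP2")

DESIGN_COLUMNS = ["sample_id", "species", "tank", "treatment", "timepoint", "replicate"]


@dataclass
class SampleDesign:
    """A table of samples with their factorial coordinates.

    Wraps a DataFrame with columns ``sample_id, species, tank, treatment,
    timepoint, replicate``.  ``sample_id`` values are unique.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        self.table = self.table.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    @property
    def timepoints(self) -> list[str]:
        order = {tp: i for i, tp in enumerate(DEFAULT_TIMEPOINTS)}
        tps = self.table["timepoint"].unique()
        return sorted(tps, key=lambda t: (order.get(t, 99), t))

    def __len__(self) -> int:
        return len(self.table)

    def subset(
        self,
        species: Optional[str] = None,
        treatment: Optional[str] = None,
        timepoint: Optional[str] = None,
    ) -> "SampleDesign":
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        if treatment is not None:
            t = t[t["treatment"] == treatment]
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        return SampleDesign(t.copy())

    def ids_for(self, species=None, treatment=None, timepoint=None) -> list[str]:
        return self.subset(species, treatment, timepoint).sample_ids

    # -- serialization ---------------------------------------------------
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path))


def species_labels(n: int) -> list[str]:
    """A, B, ..., Z, then AA, AB, ... for pathological n."""
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def generate_design(
    species_count: int = 3,
    tanks_per_treatment: int = 3,
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    reps: int = 1,
    bailout_species: Optional[str] = None,
) -> SampleDesign:
    """Build the factorial sample design, deterministically.

    One sample is produced per (species, treatment, timepoint, tank,
    replicate) cell, so each species x treatment x timepoint group holds
    ``tanks_per_treatment * reps`` samples.  Ambient tanks are numbered
    ``1..t`` and stress tanks ``t+1..2t``.  If ``bailout_species`` is given,
    that species contributes no stress samples at the last timepoint
    (complete tissue loss before sampling).
    """
    if species_count < 1:
        raise ValueError("species_count must be >= 1")
    if tanks_per_treatment < 1:
        raise ValueError("tanks_per_treatment must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("at least one timepoint required")

    labels = species_labels(species_count)
    if bailout_species is not None and bailout_species not in labels:
        raise ValueError(
            f"bailout_species {bailout_species!r} not among species {labels}"
        )

    rows = []
    for sp in labels:
        for ti, tp in enumerate(timepoints):
            for trt in TREATMENTS:
                if (
                    bailout_species == sp
                    and trt == "stress"
                    and ti == len(timepoints) - 1
                ):
                    continue  # bail-out: no stress samples at the last timepoint
                for tank in range(1, tanks_per_treatment + 1):
                    tank_id = tank if trt == "ambient" else tank + tanks_per_treatment
                    for rep in range(1, reps + 1):
                        rows.append(
                            {
                                "sample_id": f"{sp}_{trt}_{tp}_t{tank_id}r{rep}",
                                "species": sp,
                                "tank": tank_id,
                                "treatment": trt,
                                "timepoint": tp,
                                "replicate": rep,
                            }
                        )
    return SampleDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))
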