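"""Protein-group parsing and the cleaning cascade.

The cascade mirrors standard label-free proteomics practice for a low-input,
high-variance dataset: identity filters on the search-engine output
(peptide evidence, group-level q-value, contaminant/decoy flags, host vs.
symbiont fraction), a raw-intensity floor that removes likely false
assignments, log2 transform, advisory outlier flagging (completeness + PCA),
a per-species presence filter, random-forest iterative imputation, and
group-median normalization.  Symbiont-fraction intensities can additionally
be divided by endosymbiont cell abundance before the floor, so bleaching-
driven cell loss is not mistaken for per-cell protein loss.

Matrix-shaped stages are sklearn-style transformers (``fit``/``transform``,
``get_params``); the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

from .design import SampleDesign
from .matrix import AbundanceMatrix, StateError

MANDATORY_COLUMNS = (
    "Unique peptides",
    "Razor + unique peptides",
    "Q-value",
    "Potential contaminant",
    "Reverse",
)
_ID_COLUMNS = ("Protein IDs", "Majority protein IDs", "Protein.IDs")


# ---------------------------------------------------------------------------
# Parsing


@dataclass
class ProteinGroupTable:
    """Parsed protein-group rows plus their per-sample raw intensities.

    ``meta`` has canonical columns (group_id, fraction, unique_peptides,
    razor_unique_peptides, q_value, contaminant, reverse); ``intensities``
    is group x sample on the raw scale with NaN for not-quantified.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meta["group_id"].duplicated().any():
            d = sorted(self.meta.loc[self.meta["group_id"].duplicated(), "group_id"])
            raise ValueError(f"duplicate protein group ids: {d}")
        bad = self.meta["razor_unique_peptides"] < self.meta["unique_peptides"]
        if bad.any():
            ids = sorted(self.meta.loc[bad, "group_id"])
            raise ValueError(f"razor+unique < unique peptides for groups: {ids}")

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.intensities.columns)

    def subset(self, keep: pd.Series) -> "ProteinGroupTable":
        keep = keep.to_numpy(dtype=bool)
        return ProteinGroupTable(
            self.meta.loc[keep].reset_index(drop=True),
            self.intensities.loc[keep].reset_index(drop=True),
        )

    def to_matrix(self, samples: Optional[Sequence[str]] = None) -> AbundanceMatrix:
        """Raw-scale abundance matrix (features x samples)."""
        data = self.intensities.copy()
        data.index = pd.Index(self.meta["group_id"], name="feature")
        if samples is not None:
            data = data[list(samples)]
        return AbundanceMatrix(data, state="raw",
                               lineage=[{"op": "from_protein_groups", "state": "raw"}])


def _flag(series: pd.Series) -> pd.Series:
    """MaxQuant-style '+' flags; also accepts booleans/0-1."""
    if series.dtype == bool:
        return series
    s = series.fillna("").astype(str).str.strip()
    return s.isin(("+", "True", "true", "1"))


def read_protein_groups(path, design: Optional[SampleDesign] = None) -> ProteinGroupTable:
    """Read a tab-separated search-engine protein-group table.

    Recognizes the standard dialect: an id column (``Protein IDs``), peptide
    evidence counts, ``Q-value``, '+'-flagged ``Potential contaminant`` and
    ``Reverse`` columns, an optional ``Fraction`` column (host/symbiont/
    unassigned; defaults to host), and one ``Intensity <sample>`` column per
    sample.  Zero or empty intensities become the absent state (NaN) —
    a zero from these instruments means "not quantified", not "none present".
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"protein-group table missing mandatory columns: {missing}")
    id_col = next((c for c in _ID_COLUMNS if c in df.columns), None)
    if id_col is None:
        raise ValueError(f"protein-group table needs an id column, one of {_ID_COLUMNS}")

    intensity_cols = [c for c in df.columns if c.startswith("Intensity ")]
    if not intensity_cols:
        raise ValueError("no 'Intensity <sample>' columns found")
    sample_names = [c[len("Intensity "):] for c in intensity_cols]

    if design is not None:
        unmatched = sorted(set(design.sample_ids) - set(sample_names))
        if unmatched:
            raise ValueError(
                f"design samples without an intensity column: {unmatched}"
            )
        keep = [f"Intensity {s}" for s in design.sample_ids]
        intensity_cols, sample_names = keep, list(design.sample_ids)

    meta = pd.DataFrame(
        {
            "group_id": df[id_col].astype(str),
            "fraction": (
                df["Fraction"].fillna("unassigned").astype(str)
                if "Fraction" in df.columns
                else "host"
            ),
            "unique_peptides": df["Unique peptides"].astype(int),
            "razor_unique_peptides": df["Razor + unique peptides"].astype(int),
            "q_value": df["Q-value"].astype(float),
            "contaminant": _flag(df["Potential contaminant"]),
            "reverse": _flag(df["Reverse"]),
        }
    )
    intens = df[intensity_cols].apply(pd.to_numeric, errors="coerce")
    intens.columns = sample_names
    intens = intens.mask(intens <= 0.0)  # zero means not quantified
    return ProteinGroupTable(meta, intens.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Identity filters


def filter_protein_groups(
    table: ProteinGroupTable,
    min_unique: int = 1,
    min_razor: int = 1,
    max_q: float = 0.01,
    drop_contaminants: bool = True,
    drop_reverse: bool = True,
    keep_fraction: Optional[str] = "host",
) -> Tuple[ProteinGroupTable, Dict[str, int]]:
    """Apply the identity filter cascade; thresholds are strict.

    Retains rows with unique peptides > ``min_unique``, razor+unique >
    ``min_razor``, q-value < ``max_q``, no contaminant/decoy flag, and the
    requested database fraction.  Returns the retained table and a tally of
    rows passing each criterion individually plus the final retained count.
    """
    if max_q <= 0:
        raise ValueError("max_q must be positive")
    m = table.meta
    crit = {
        "unique_peptides": m["unique_peptides"] > min_unique,
        "razor_unique_peptides": m["razor_unique_peptides"] > min_razor,
        "q_value": m["q_value"] < max_q,
        "not_contaminant": ~m["contaminant"] if drop_contaminants else pd.Series(True, index=m.index),
        "not_reverse": ~m["reverse"] if drop_reverse else pd.Series(True, index=m.index),
    }
    if keep_fraction is not None:
        crit["fraction"] = m["fraction"] == keep_fraction
    keep = pd.Series(True, index=m.index)
    tally: Dict[str, int] = {"input": len(m)}
    for name, c in crit.items():
        tally[name] = int(c.sum())
        keep &= c
    tally["retained"] = int(keep.sum())
    return table.subset(keep), tally


# ---------------------------------------------------------------------------
# Matrix transformers (sklearn-style)


class IntensityFloor(BaseEstimator, TransformerMixin):
    """Mask raw intensities strictly below ``floor`` as missing.

    Values below the floor are treated as likely false assignments; values
    exactly at the floor are retained.  Must run before the log2 transform.
    """

    def __init__(self, floor: float = 5.0):
        self.floor = floor

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_state("raw")
        data = X.data.mask(X.data < self.floor)
        return X.evolve(data, "floored", "intensity_floor", floor=self.floor)


class Log2Transform(BaseEstimator, TransformerMixin):
    """log2-transform present values; the absent state passes through."""

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_state("floored")
        if (X.data <= 0).any().any():
            raise ValueError("nonpositive intensity present; cannot log2-transform")
        return X.evolve(np.log2(X.data), "log2", "log2_transform")


class PresenceFilter(BaseEstimator, TransformerMixin):
    """Drop features present in fewer than ``min_presence`` of the samples.

    The matrix at this point holds one species' retained samples, so the
    presence denominator is exactly the species' sample count, evaluated
    after the intensity floor and any outlier-sample removal.
    """

    def __init__(self, min_presence: float = 0.80):
        self.min_presence = min_presence

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_state("log2")
        if not 0.0 <= self.min_presence <= 1.0:
            raise ValueError("min_presence must be in [0, 1]")
        presence = X.data.notna().mean(axis=1)
        keep = presence >= self.min_presence
        return X.evolve(
            X.data.loc[keep], "log2", "presence_filter",
            min_presence=self.min_presence, dropped=int((~keep).sum()),
        )


class ForestImputer(BaseEstimator, TransformerMixin):
    """missForest-style iterative random-forest imputation.

    Each feature with missing entries is regressed on all other features
    using a random-forest ensemble, cycling over features (most complete
    first) until the normalized squared difference between successive
    imputed matrices first increases, or ``max_rounds`` is reached; the
    imputation from the previous round is then returned.  Deterministic
    given ``random_state``.  Observed entries are never altered.
    """

    def __init__(self, max_rounds: int = 10, n_trees: int = 100,
                 random_state: int = 124):
        self.max_rounds = max_rounds
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_state("log2")
        data = X.data
        present = data.notna().sum(axis=1)
        starved = present[present < 2]
        if len(starved):
            raise ValueError(
                "features with <2 present values cannot be imputed: "
                f"{sorted(starved.index)}"
            )
        if not data.isna().any().any():
            return X.evolve(data.copy(), "imputed", "impute", method="identity")

        # Work sample x feature: features are the variables.
        M = data.to_numpy(dtype=float).T.copy()
        miss = np.isnan(M)
        col_means = np.nanmean(M, axis=0)
        filled = np.where(miss, col_means[None, :], M)

        order = np.argsort(miss.sum(axis=0))
        cols = [j for j in order if miss[:, j].any()]
        rng = np.random.RandomState(self.random_state)
        seeds = rng.randint(0, 2**31 - 1, size=(self.max_rounds, len(cols)))

        prev_delta = np.inf
        best = filled.copy()
        n_rounds = 0
        for it in range(self.max_rounds):
            before = filled.copy()
            for k, j in enumerate(cols):
                obs = ~miss[:, j]
                others = np.delete(np.arange(M.shape[1]), j)
                rf = RandomForestRegressor(
                    n_estimators=self.n_trees,
                    random_state=int(seeds[it, k]),
                    n_jobs=1,
                )
                rf.fit(filled[obs][:, others], filled[obs, j])
                filled[~obs, j] = rf.predict(filled[~obs][:, others])
            num = float(np.sum((filled[miss] - before[miss]) ** 2))
            den = float(np.sum(filled[miss] ** 2)) or 1.0
            delta = num / den
            n_rounds = it + 1
            if delta >= prev_delta:
                filled = before  # difference increased: keep previous round
                n_rounds -= 1
                break
            prev_delta = delta
            best = filled.copy()

        out = pd.DataFrame(filled.T, index=data.index, columns=data.columns)
        return X.evolve(
            out, "imputed", "impute",
            max_rounds=self.max_rounds, n_trees=self.n_trees,
            random_state=self.random_state, rounds_run=n_rounds,
            imputed_cells=int(miss.sum()),
        )


class GroupMedianNormalizer(BaseEstimator, TransformerMixin):
    """Equalize sample medians within each treatment x timepoint group.

    On the log2 scale each sample in a group is shifted additively so its
    median equals the group's grand median of sample medians (equivalent to
    a multiplicative correction on the raw scale).  Offsets between groups
    are left untouched.
    """

    def __init__(self, grouping: Sequence[str] = ("treatment", "timepoint")):
        self.grouping = tuple(grouping)

    def fit(self, X: AbundanceMatrix, y=None, design: Optional[SampleDesign] = None):
        return self

    def transform(self, X: AbundanceMatrix,
                  design: Optional[SampleDesign] = None) -> AbundanceMatrix:
        X.require_state("imputed")
        if design is None:
            raise ValueError("GroupMedianNormalizer.transform requires a design")
        dt = design.table.set_index("sample_id")
        unknown = sorted(set(X.samples) - set(dt.index))
        if unknown:
            raise ValueError(f"samples absent from design: {unknown}")
        data = X.data.copy()
        groups = dt.loc[X.samples, list(self.grouping)].apply(tuple, axis=1)
        for key in groups.unique():
            cols = groups.index[groups == key]
            if len(cols) == 0:
                warnings.warn(f"empty normalization group {key}; skipped")
                continue
            medians = data[cols].median(axis=0)
            anchor = float(np.median(medians.to_numpy()))
            data[cols] = data[cols] + (anchor - medians)
        return X.evolve(data, "normalized", "median_normalize",
                        grouping=list(self.grouping))


class CellDensityNormalizer(BaseEstimator, TransformerMixin):
    """Divide raw symbiont intensities by per-sample cell abundance.

    Corrects symbiont protein signal for bleaching-driven loss of symbiont
    cells: division happens on the raw scale, before the intensity floor,
    so the standard floor -> log2 path resumes afterwards.  Samples with
    zero or missing abundance are excluded with a warning.
    """

    def __init__(self, cell_abundance: Optional[Mapping[str, float]] = None):
        self.cell_abundance = cell_abundance

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_state("raw")
        if self.cell_abundance is None:
            raise ValueError("cell_abundance mapping is required")
        ab = pd.Series(self.cell_abundance, dtype=float)
        missing = sorted(set(X.samples) - set(ab.index))
        if missing:
            raise ValueError(f"no cell abundance for samples: {missing}")
        ab = ab.loc[X.samples]
        bad = ab.index[(ab <= 0) | ab.isna()].tolist()
        if bad:
            warnings.warn(
                f"samples excluded from cell-density normalization (zero/absent "
                f"abundance): {bad}"
            )
        good = [s for s in X.samples if s not in set(bad)]
        data = X.data[good].div(ab.loc[good], axis=1)
        return X.evolve(data, "raw", "cell_density_normalize",
                        excluded_samples=list(bad))


# -- thin functional wrappers ------------------------------------------------

def apply_intensity_floor(matrix: AbundanceMatrix, floor: float = 5.0) -> AbundanceMatrix:
    return IntensityFloor(floor).transform(matrix)


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    return Log2Transform().transform(matrix)


def filter_missingness(matrix: AbundanceMatrix, min_presence: float = 0.80) -> AbundanceMatrix:
    return PresenceFilter(min_presence).transform(matrix)


def impute_missing(matrix: AbundanceMatrix, max_rounds: int = 10,
                   trees: int = 100, seed: int = 124) -> AbundanceMatrix:
    return ForestImputer(max_rounds, trees, seed).transform(matrix)


def median_normalize(matrix: AbundanceMatrix, design: SampleDesign,
                     grouping: Sequence[str] = ("treatment", "timepoint")) -> AbundanceMatrix:
    return GroupMedianNormalizer(grouping).transform(matrix, design=design)


def normalize_by_cell_density(matrix: AbundanceMatrix,
                              cell_abundance: Mapping[str, float]) -> AbundanceMatrix:
    return CellDensityNormalizer(cell_abundance).transform(matrix)


# ---------------------------------------------------------------------------
# Outlier QC


@dataclass
class QcReport:
    """Per-sample quality metrics plus advisory outlier flags."""

    completeness: Dict[str, float]
    pc_coordinates: Dict[str, Tuple[float, float]]
    median_log2: Dict[str, float]
    cv: Dict[str, float]
    flags: List[Dict[str, str]] = field(default_factory=list)

    @property
    def flagged_samples(self) -> List[str]:
        return sorted({f["sample"] for f in self.flags})

    def to_dict(self) -> dict:
        return {
            "completeness": self.completeness,
            "pc_coordinates": {k: list(v) for k, v in self.pc_coordinates.items()},
            "median_log2": self.median_log2,
            "cv": self.cv,
            "flags": self.flags,
        }


def flag_outlier_samples(
    matrix: AbundanceMatrix,
    min_completeness: float = 0.5,
    pca_mad_k: float = 3.0,
) -> QcReport:
    """Advisory outlier report: completeness and PCA distance rules.

    PCA runs on features complete across all samples, column-centered; a
    sample is flagged when its distance from the score centroid in the
    PC1/PC2 plane exceeds ``pca_mad_k`` robust (MAD-scaled) deviations above
    the median distance.  Flagging never removes anything — dropping is a
    separate, explicit call (:func:`drop_samples`).
    """
    data = matrix.data
    if data.shape[1] < 3:
        raise ValueError("outlier flagging requires at least 3 samples")
    completeness = data.notna().mean(axis=0)

    # CV on the raw scale regardless of current state.
    raw = np.exp2(data) if matrix.state not in ("raw", "floored") else data
    cv = raw.std(axis=0, ddof=1) / raw.mean(axis=0)

    complete = data.dropna(axis=0)
    coords: Dict[str, Tuple[float, float]] = {s: (0.0, 0.0) for s in data.columns}
    pca_flags: List[str] = []
    if len(complete) >= 2:
        X = complete.to_numpy(dtype=float).T  # samples x features
        X = X - X.mean(axis=0, keepdims=True)
        n_comp = min(2, min(X.shape))
        scores = PCA(n_components=n_comp).fit_transform(X)
        if scores.shape[1] < 2:
            scores = np.column_stack([scores, np.zeros(len(scores))])
        centroid = scores.mean(axis=0)
        dist = np.linalg.norm(scores - centroid, axis=1)
        med = float(np.median(dist))
        mad = float(np.median(np.abs(dist - med)))
        scale = 1.4826 * mad
        if scale > 0:
            cut = med + pca_mad_k * scale
        else:
            cut = med + 1e-8 * (1.0 + med)  # degenerate spread: flag only true leaps
        for s, (pc, d) in zip(data.columns, zip(scores, dist)):
            coords[s] = (float(pc[0]), float(pc[1]))
            if d > cut:
                pca_flags.append(s)

    flags = []
    for s in data.columns:
        if completeness[s] < min_completeness:
            flags.append({"sample": s, "reason": "completeness",
                          "value": f"{completeness[s]:.4f}"})
    for s in pca_flags:
        flags.append({"sample": s, "reason": "pca_distance"})

    return QcReport(
        completeness=completeness.round(12).to_dict(),
        pc_coordinates=coords,
        median_log2={
            s: float(v) for s, v in data.median(axis=0).items()
        },
        cv={s: float(v) for s, v in cv.items()},
        flags=flags,
    )


def drop_samples(matrix: AbundanceMatrix, sample_ids: Iterable[str]) -> AbundanceMatrix:
    drop = [s for s in sample_ids]
    unknown = sorted(set(drop) - set(matrix.samples))
    if unknown:
        raise ValueError(f"cannot drop unknown samples: {unknown}")
    keep = [s for s in matrix.samples if s not in set(drop)]
    return matrix.evolve(matrix.data[keep], matrix.state, "drop_samples",
                         dropped=sorted(drop))


# ---------------------------------------------------------------------------
# Whole-cascade convenience


@dataclass
class CleanResult:
    matrix: AbundanceMatrix
    report: QcReport
    tally: Dict[str, int]


def clean_proteome(
    table: ProteinGroupTable,
    design: SampleDesign,
    fraction: str = "host",
    floor: float = 5.0,
    min_presence: float = 0.80,
    min_completeness: float = 0.5,
    impute_seed: int = 124,
    impute_trees: int = 100,
    impute_rounds: int = 10,
    drop: Sequence[str] = (),
    cell_abundance: Optional[Mapping[str, float]] = None,
) -> CleanResult:
    """Run the full cascade for one species' samples.

    Order: identity filters -> (optional cell-density normalization for the
    symbiont fraction) -> intensity floor -> log2 -> explicit sample drops ->
    QC report -> presence filter -> forest imputation -> group-median
    normalization.
    """
    filtered, tally = filter_protein_groups(table, keep_fraction=fraction)
    matrix = filtered.to_matrix(design.sample_ids)
    if cell_abundance is not None:
        matrix = normalize_by_cell_density(matrix, cell_abundance)
    matrix = apply_intensity_floor(matrix, floor)
    matrix = log2_transform(matrix)
    if drop:
        matrix = drop_samples(matrix, drop)
    # Features entirely absent after the floor cannot inform QC or imputation.
    matrix = matrix.evolve(
        matrix.data.dropna(axis=0, how="all"), "log2", "drop_empty_features"
    )
    report = flag_outlier_samples(matrix, min_completeness=min_completeness)
    matrix = filter_missingness(matrix, min_presence)
    matrix = impute_missing(matrix, impute_rounds, impute_trees, impute_seed)
    matrix = median_normalize(matrix, design)
    tally["final_features"] = matrix.data.shape[0]
    return CleanResult(matrix, report, tally)
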