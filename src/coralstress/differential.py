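"""Per-feature stress-vs-ambient differential abundance.

For each species x timepoint contrast the log2 fold change is the difference
of group means on the log2 scale (stress minus ambient) and significance is
a two-sided t test — pooled-variance (Student) for proteins at n=3/group,
unequal-variance (Welch) for metabolites at n=6/group.  Features are called
``increased`` when FC > 0.5 with p < 0.05, ``decreased`` when FC < -0.5 with
p < 0.05 (strict inequalities), else ``unchanged``.  Benjamini-Hochberg
adjusted p-values are always computed across the features of a contrast;
protein classification deliberately uses the unadjusted p (at these sample
sizes no protein survives FDR control, and pathway-level voting provides the
error-rate backstop), whereas metabolite classification uses the adjusted p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .design import SampleDesign
from .matrix import AbundanceMatrix

#: Guard added to variances so zero-spread groups yield a finite statistic.
VARIANCE_EPS = 1e-12

RESULT_COLUMNS = [
    "feature_id", "species", "timepoint", "fc", "t_stat", "p", "adj_p",
    "class", "n_a", "n_b", "zero_variance",
]


@dataclass(frozen=True)
class Contrast:
    """Ambient (group a) vs stress (group b) for one species x timepoint."""

    species: str
    timepoint: str
    group_a: tuple  # ambient sample ids
    group_b: tuple  # stress sample ids

    def __post_init__(self):
        a, b = set(self.group_a), set(self.group_b)
        if a & b:
            raise ValueError(f"contrast groups overlap: {sorted(a & b)}")
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each contrast group needs at least 2 samples")

    @classmethod
    def from_design(cls, design: SampleDesign, species: str, timepoint: str) -> "Contrast":
        a = design.ids_for(species, "ambient", timepoint)
        b = design.ids_for(species, "stress", timepoint)
        return cls(species, timepoint, tuple(a), tuple(b))


def classify(fc: float, p: float, fc_thresh: float = 0.5,
             p_thresh: float = 0.05) -> str:
    """Directional call with strict thresholds on |FC| and p."""
    if not (np.isfinite(fc) and np.isfinite(p)):
        raise ValueError("classify requires finite fc and p")
    if p < p_thresh and fc > fc_thresh:
        return "increased"
    if p < p_thresh and fc < -fc_thresh:
        return "decreased"
    return "unchanged"


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Adjusted values are attached to the original indices, so shuffling the
    input permutes the output identically.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _t_test(a: np.ndarray, b: np.ndarray, test: str):
    """Two-sided t statistics for each row of a and b (group b minus a).

    Closed-form so the zero-variance epsilon guard can be applied; rows with
    a degenerate pooled variance are flagged.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    if test == "student":
        s2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        zero = s2 <= 0
        s2 = s2 + VARIANCE_EPS
        se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
        df = np.full(a.shape[0], na + nb - 2, dtype=float)
    elif test == "welch":
        va_g, vb_g = va + VARIANCE_EPS, vb + VARIANCE_EPS
        zero = (va <= 0) & (vb <= 0)
        se2 = va_g / na + vb_g / nb
        se = np.sqrt(se2)
        df = se2**2 / (
            (va_g / na) ** 2 / (na - 1) + (vb_g / nb) ** 2 / (nb - 1)
        )
    else:
        raise ValueError(f"unknown test family {test!r}")
    t = (mb - ma) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, zero


class DifferentialAbundance(BaseEstimator):
    """Estimator computing per-feature contrasts on an abundance matrix.

    Parameters follow the classification rule; ``fit`` computes and stores
    ``results_`` (a DataFrame in :data:`RESULT_COLUMNS` order).

    ``classify_on`` chooses which p-value feeds the directional call:
    ``"p"`` (proteins) or ``"adj_p"`` (metabolites).
    """

    def __init__(self, test: str = "student", fc_thresh: float = 0.5,
                 p_thresh: float = 0.05, classify_on: str = "p"):
        self.test = test
        self.fc_thresh = fc_thresh
        self.p_thresh = p_thresh
        self.classify_on = classify_on

    def fit(self, X: AbundanceMatrix, contrast: Contrast) -> "DifferentialAbundance":
        if self.classify_on not in ("p", "adj_p"):
            raise ValueError("classify_on must be 'p' or 'adj_p'")
        data = X.data
        missing = [s for s in (*contrast.group_a, *contrast.group_b)
                   if s not in data.columns]
        if missing:
            raise ValueError(f"contrast samples absent from matrix: {missing}")
        a = data[list(contrast.group_a)].to_numpy(dtype=float)
        b = data[list(contrast.group_b)].to_numpy(dtype=float)
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("matrix contains missing values; impute first")

        fc = b.mean(axis=1) - a.mean(axis=1)
        t, p, zero = _t_test(a, b, self.test)
        adj = bh_adjust(p)
        basis = p if self.classify_on == "p" else adj
        calls = [classify(f, q, self.fc_thresh, self.p_thresh)
                 for f, q in zip(fc, basis)]
        self.results_ = pd.DataFrame(
            {
                "feature_id": data.index,
                "species": contrast.species,
                "timepoint": contrast.timepoint,
                "fc": fc,
                "t_stat": t,
                "p": p,
                "adj_p": adj,
                "class": calls,
                "n_a": len(contrast.group_a),
                "n_b": len(contrast.group_b),
                "zero_variance": zero,
            },
            columns=RESULT_COLUMNS,
        ).reset_index(drop=True)
        self.contrast_ = contrast
        return self


def differential_features(
    matrix: AbundanceMatrix,
    contrast: Contrast,
    test: str = "student",
    fc_thresh: float = 0.5,
    p_thresh: float = 0.05,
    classify_on: str = "p",
) -> pd.DataFrame:
    """Per-feature differential results for one contrast (thin wrapper)."""
    est = DifferentialAbundance(test, fc_thresh, p_thresh, classify_on)
    return est.fit(matrix, contrast).results_


def differential_metabolites(
    table: pd.DataFrame,
    design: pd.DataFrame,
    species: str,
    timepoint: str,
    fc_thresh: float = 0.5,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Welch-test contrasts on a metabolite abundance table.

    ``table`` is metabolite x sample raw abundances; ``design`` maps
    sample_id to species/treatment/timepoint with n=6 per cell in the study
    layout.  Fold changes are computed on the log2 scale and significance is
    judged on the BH-adjusted p-value, mirroring how low-replicate
    metabolomics panels are reported.
    """
    d = design
    amb = d[(d["species"] == species) & (d["timepoint"] == timepoint)
            & (d["treatment"] == "ambient")]["sample_id"]
    hot = d[(d["species"] == species) & (d["timepoint"] == timepoint)
            & (d["treatment"] == "stress")]["sample_id"]
    contrast = Contrast(species, timepoint, tuple(amb), tuple(hot))
    log2_table = AbundanceMatrix(np.log2(table), state="imputed",
                                 lineage=[{"op": "log2_metabolites", "state": "imputed"}])
    return differential_features(
        log2_table, contrast, test="welch",
        fc_thresh=fc_thresh, p_thresh=p_thresh, classify_on="adj_p",
    )


def all_contrasts(design: SampleDesign) -> List[Contrast]:
    """Every species x timepoint cell with both treatment groups present."""
    out = []
    for sp in design.species:
        for tp in design.timepoints:
            a = design.ids_for(sp, "ambient", tp)
            b = design.ids_for(sp, "stress", tp)
            if len(a) >= 2 and len(b) >= 2:
                out.append(Contrast(sp, tp, tuple(a), tuple(b)))
    return out
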