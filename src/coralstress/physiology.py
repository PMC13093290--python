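"""Coral physiology: surface area, endosymbiont abundance, Fv/Fm statistics.

Surface area comes from the single wax-dip method: cylindrical standards of
known geometric area are dipped in paraffin and weighed, giving an OLS line
of area on wax mass; a fragment's area is predicted from its pre/post dip
mass difference.  Endosymbiont density (hemocytometer quadrat counts) is
normalized by surface area to give cell abundance in cells/ml/cm2, log2-
transformed for statistics.  Treatment effects are assessed with a one-way
ANOVA over the combined treatment x timepoint factor followed by Tukey HSD,
with Shapiro-Wilk and Levene assumption checks reported as advisory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: Standard Neubauer haemocytometer: one large-square count corresponds to
#: 1e4 cells per ml of slurry.
HEMOCYTOMETER_FACTOR = 1.0e4


@dataclass
class WaxCalibration:
    slope: float       # cm^2 per gram
    intercept: float   # cm^2
    r_squared: float
    n_standards: int

    def predict(self, wax_mass_g: float) -> float:
        return self.slope * wax_mass_g + self.intercept


def fit_wax_calibration(standards: Sequence[Tuple[float, float]]) -> WaxCalibration:
    """OLS of known area (cm^2) on wax mass (g) over calibration standards."""
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    mass = np.asarray([s[0] for s in standards], dtype=float)
    area = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(mass) == 0:
        raise ValueError("calibration standards have identical wax masses")
    res = stats.linregress(mass, area)
    return WaxCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0,
        n_standards=len(standards),
    )


def surface_area(mass_pre_g: float, mass_post_g: float,
                 calibration: WaxCalibration) -> float:
    """Fragment surface area from the wax-mass difference."""
    wax = mass_post_g - mass_pre_g
    if wax < 0:
        raise ValueError("post-dip mass below pre-dip mass (negative wax mass)")
    return calibration.predict(wax)


def cell_abundance(
    quadrat_counts: Sequence[float],
    surface_area_cm2: float,
    conversion: float = HEMOCYTOMETER_FACTOR,
) -> Tuple[float, float]:
    """Surface-area-normalized endosymbiont abundance.

    Density (cells/ml) is the mean quadrat count times the haemocytometer
    conversion; abundance divides density by fragment surface area, keeping
    the study's cells/ml/cm2 unit.  Returns ``(abundance, log2 abundance)``;
    the log2 value is NaN when abundance is zero.
    """
    counts = np.asarray(list(quadrat_counts), dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("quadrat counts must be non-negative and non-empty")
    if surface_area_cm2 <= 0:
        raise ValueError("surface area must be positive")
    density = counts.mean() * conversion
    abundance = density / surface_area_cm2
    log2_ab = math.log2(abundance) if abundance > 0 else float("nan")
    return abundance, log2_ab


# ---------------------------------------------------------------------------
# Statistics


@dataclass
class AssumptionReport:
    shapiro_p: Optional[float]
    levene_p: Optional[float]
    alpha: float = 0.05

    @property
    def normality_ok(self) -> Optional[bool]:
        return None if self.shapiro_p is None else self.shapiro_p > self.alpha

    @property
    def variance_ok(self) -> Optional[bool]:
        return None if self.levene_p is None else self.levene_p > self.alpha


def check_assumptions(values: Sequence[float], groups: Sequence) -> AssumptionReport:
    """Shapiro-Wilk on model residuals and Levene across groups.

    Advisory only: the caller proceeds regardless, logging a warning when a
    check fails.  Constant data make Shapiro undefined; both p-values are
    then reported as not applicable (None).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    uniq = pd.unique(groups)
    if len(uniq) < 2 or len(values) < 3:
        raise ValueError("need >=2 groups and >=3 values")
    resid = values - pd.Series(values).groupby(pd.Series(groups)).transform("mean").to_numpy()
    if np.ptp(values) == 0:
        return AssumptionReport(None, None)
    try:
        shapiro_p = float(stats.shapiro(resid).pvalue)
    except ValueError:
        shapiro_p = None
    samples = [values[groups == g] for g in uniq]
    levene_p = float(stats.levene(*samples).pvalue)
    report = AssumptionReport(shapiro_p, levene_p)
    if report.normality_ok is False:
        warnings.warn(f"residual normality check failed (Shapiro p={shapiro_p:.3g})")
    if report.variance_ok is False:
        warnings.warn(f"variance homogeneity check failed (Levene p={levene_p:.3g})")
    return report


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    adj_p: float


@dataclass
class AnovaResult:
    df_between: int
    df_within: int
    F: float
    p: float
    assumptions: AssumptionReport
    tukey: List[TukeyPair] = field(default_factory=list)
    within_timepoint: Dict[str, TukeyPair] = field(default_factory=dict)


def _parse_group(label: str) -> Optional[Tuple[str, str]]:
    """Split 'treatment_timepoint' labels; None if not parseable."""
    if not isinstance(label, str) or "_" not in label:
        return None
    treatment, timepoint = label.split("_", 1)
    if treatment not in ("ambient", "stress"):
        return None
    return treatment, timepoint


def anova_tukey(values: Sequence[float], groups: Sequence[str]) -> AnovaResult:
    """One-way ANOVA over the combined factor, then Tukey HSD on all pairs.

    Group labels of the form ``<treatment>_<timepoint>`` (e.g.
    ``stress_TP2``) additionally have their ambient-vs-stress pair within
    each timepoint extracted into ``within_timepoint`` — extracted from the
    full family, not refit, so the adjusted p-values keep the full-factor
    studentized-range correction.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    uniq = sorted(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    for g, s in zip(uniq, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    assumptions = check_assumptions(values, groups)
    F, p = stats.f_oneway(*samples)

    tukey_pairs: List[TukeyPair] = []
    if np.ptp(values) > 0:
        res = pairwise_tukeyhsd(values, groups)
        from itertools import combinations

        for (a, b), diff, adj in zip(
            combinations(res.groupsunique, 2), res.meandiffs, res.pvalues
        ):
            tukey_pairs.append(TukeyPair(str(a), str(b), float(diff), float(adj)))

    within: Dict[str, TukeyPair] = {}
    for pair in tukey_pairs:
        pa, pb = _parse_group(pair.group_a), _parse_group(pair.group_b)
        if pa and pb and pa[1] == pb[1] and {pa[0], pb[0]} == {"ambient", "stress"}:
            within[pa[1]] = pair

    return AnovaResult(
        df_between=len(uniq) - 1,
        df_within=len(values) - len(uniq),
        F=float(F),
        p=float(p),
        assumptions=assumptions,
        tukey=tukey_pairs,
        within_timepoint=within,
    )


def percent_change(ambient_values: Sequence[float],
                   stress_values: Sequence[float]) -> float:
    """Percent decline under stress: 100 * (mean_a - mean_s) / mean_a."""
    a = float(np.mean(ambient_values))
    s = float(np.mean(stress_values))
    if a == 0:
        raise ValueError("ambient mean is zero; percent change undefined")
    return 100.0 * (a - s) / a


def group_log2_fc(ambient_values: Sequence[float],
                  stress_values: Sequence[float]) -> float:
    """log2(mean stress) - log2(mean ambient) on the raw scale."""
    a = float(np.mean(ambient_values))
    s = float(np.mean(stress_values))
    if a <= 0 or s <= 0:
        raise ValueError("group means must be positive for a log2 fold change")
    return math.log2(s) - math.log2(a)


# ---------------------------------------------------------------------------
# Table-level deriving & species summaries


def derive_physiology(table: pd.DataFrame,
                      calibration: WaxCalibration,
                      conversion: float = HEMOCYTOMETER_FACTOR) -> pd.DataFrame:
    """Per-fragment derived quantities from a raw physiology table.

    Expects columns ``sample_id, species, treatment, timepoint,
    quadrat_count_1..8, mass_pre_g, mass_post_g, fvfm_1..3``; adds
    ``surface_area_cm2, cell_abundance, log2_cell_abundance, fvfm_mean``.
    """
    count_cols = [c for c in table.columns if c.startswith("quadrat_count_")]
    fvfm_cols = [c for c in table.columns if c.startswith("fvfm_")]
    if not count_cols or not fvfm_cols:
        raise ValueError("physiology table needs quadrat_count_* and fvfm_* columns")
    out = table.copy()
    areas, abundances, logs = [], [], []
    for _, row in table.iterrows():
        area = surface_area(row["mass_pre_g"], row["mass_post_g"], calibration)
        ab, lab = cell_abundance(row[count_cols].to_numpy(dtype=float), area,
                                 conversion)
        areas.append(area)
        abundances.append(ab)
        logs.append(lab)
    out["surface_area_cm2"] = areas
    out["cell_abundance"] = abundances
    out["log2_cell_abundance"] = logs
    out["fvfm_mean"] = table[fvfm_cols].mean(axis=1)
    return out


def species_statistics(derived: pd.DataFrame, species: str) -> dict:
    """ANOVA/Tukey, per-timepoint FC and percent change for one species.

    Cell abundance is analysed on the log2 scale; its per-timepoint fold
    change uses raw-scale group means.  Fv/Fm is analysed on its native
    scale and summarized as percent change under stress.
    """
    sub = derived[derived["species"] == species]
    if sub.empty:
        raise ValueError(f"no rows for species {species!r}")
    labels = (sub["treatment"].astype(str) + "_" + sub["timepoint"].astype(str)).to_numpy()

    result: dict = {"species": species}
    ok = sub["log2_cell_abundance"].notna()
    result["cell_abundance_anova"] = anova_tukey(
        sub.loc[ok, "log2_cell_abundance"].to_numpy(), labels[ok.to_numpy()]
    )
    result["fvfm_anova"] = anova_tukey(sub["fvfm_mean"].to_numpy(), labels)

    fc, pct = {}, {}
    for tp in sorted(sub["timepoint"].unique()):
        amb = sub[(sub["timepoint"] == tp) & (sub["treatment"] == "ambient")]
        hot = sub[(sub["timepoint"] == tp) & (sub["treatment"] == "stress")]
        if amb.empty or hot.empty:
            continue
        fc[tp] = group_log2_fc(amb["cell_abundance"], hot["cell_abundance"])
        pct[tp] = percent_change(amb["fvfm_mean"], hot["fvfm_mean"])
    result["cell_abundance_fc"] = fc
    result["fvfm_percent_change"] = pct
    return result
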