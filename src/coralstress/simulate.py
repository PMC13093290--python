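"""Synthetic study generator with planted ground truth.

Emulates the data shapes of a multi-species coral thermal-stress experiment:

* a search-engine protein-group table (log-normal raw intensities, planted
  log2 stress effects, structured missingness, contaminant and decoy rows,
  peptide-count and q-value metadata),
* a protein -> KEGG Orthology map plus a KO -> B-level hierarchy,
* per-fragment physiology (hemocytometer quadrat counts, wax-dip masses
  against a known calibration line, Fv/Fm triplicates),
* a polar-metabolite abundance table with n=6 replicates per group.

Every planted quantity is recorded in a :class:`GroundTruth` object so each
downstream stage can be checked for recovery.  One RNG stream is derived per
output table from the master seed by a fixed offset, so generating one table
never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import SampleDesign, generate_design

# Fixed per-table stream offsets off the master seed.
_STREAM = {"proteome": 0, "annotation": 1, "physiology": 2, "metabolome": 3}


def _rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _STREAM[table]])


EffectKey = Tuple[str, str, str]  # (feature, species, timepoint)


@dataclass
class SimulationParams:
    """Knobs of the proteome generator.

    ``group_effects`` maps ``(feature, species, timepoint)`` to a planted
    log2 shift applied multiplicatively (as ``2**shift``) to the stress
    samples of that species at that timepoint.  ``noise_sd`` is the residual
    log2 standard deviation between tank replicates.
    """

    n_proteins: int = 200
    baseline_log2_mean: float = 20.0
    baseline_log2_spread: float = 2.0
    noise_sd: float = 0.3
    group_effects: Dict[EffectKey, float] = field(default_factory=dict)
    missing_rate: float = 0.10
    missing_mode: str = "intensity"  # "random" or "intensity"
    contaminant_rate: float = 0.05
    reverse_rate: float = 0.05
    symbiont_fraction: float = 0.15
    low_q_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("missing_rate", "contaminant_rate", "reverse_rate",
                     "symbiont_fraction", "low_q_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.missing_mode not in ("random", "intensity"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything that was planted, keyed by generated identifiers."""

    effects: Dict[EffectKey, float] = field(default_factory=dict)
    pathway_truth: Dict[Tuple[str, str, str], str] = field(default_factory=dict)
    contaminants: List[str] = field(default_factory=list)
    decoys: List[str] = field(default_factory=list)
    low_completeness_samples: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "effects": [
                {"feature": f, "species": s, "timepoint": t, "shift": v}
                for (f, s, t), v in sorted(self.effects.items())
            ],
            "pathway_truth": [
                {"pathway": p, "species": s, "timepoint": t, "category": c}
                for (p, s, t), c in sorted(self.pathway_truth.items())
            ],
            "contaminants": self.contaminants,
            "decoys": self.decoys,
            "low_completeness_samples": self.low_completeness_samples,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _feature_ids(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"prot{i:0{width}d}" for i in range(1, n + 1)]


def simulate_proteome(
    design: SampleDesign, params: SimulationParams
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Generate a raw protein-group table in the search-engine dialect.

    Returns a DataFrame with metadata columns (``Protein IDs``, ``Fraction``,
    ``Unique peptides``, ``Razor + unique peptides``, ``Q-value``,
    ``Potential contaminant``, ``Reverse``) and one ``Intensity <sample>``
    column per design sample.  Missing observations are empty cells, never
    zero.  Identical (design, params) including seed reproduces the table
    bit for bit.
    """
    params.validate()
    if len(design) == 0:
        raise ValueError("design is empty")
    rng = _rng(params.seed, "proteome")

    features = _feature_ids(params.n_proteins)
    fset = set(features)
    for (f, sp, tp) in params.group_effects:
        if f not in fset:
            raise KeyError(f"planted effect references unknown feature {f!r}")

    samples = design.table
    n_feat, n_samp = params.n_proteins, len(samples)

    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_spread,
                          size=n_feat)
    log2_vals = baseline[:, None] + rng.normal(0.0, params.noise_sd,
                                               size=(n_feat, n_samp))

    # Planted effects: multiplicative 2**shift on stress samples of the cell.
    fidx = {f: i for i, f in enumerate(features)}
    for (f, sp, tp), shift in params.group_effects.items():
        mask = (
            (samples["species"] == sp)
            & (samples["timepoint"] == tp)
            & (samples["treatment"] == "stress")
        ).to_numpy()
        log2_vals[fidx[f], mask] += shift

    raw = np.exp2(log2_vals)

    # Missingness: completely at random, or intensity-dependent through a
    # logistic link (lower log2 intensity => higher odds of dropout),
    # rescaled so the expected overall rate matches missing_rate.
    if params.missing_rate > 0:
        if params.missing_mode == "random":
            p_miss = np.full_like(log2_vals, params.missing_rate)
        else:
            center = np.median(log2_vals)
            scale = max(params.baseline_log2_spread, 1e-6)
            w = 1.0 / (1.0 + np.exp((log2_vals - center) / scale))
            p_miss = params.missing_rate * w / w.mean()
            np.clip(p_miss, 0.0, 0.95, out=p_miss)
        missing = rng.random(size=log2_vals.shape) < p_miss
    else:
        missing = np.zeros_like(log2_vals, dtype=bool)

    # Metadata. Unique peptides: geometric with support {1,2,...} so the
    # ">1" filter has action; razor+unique adds a non-negative excess.
    unique = rng.geometric(0.25, size=n_feat)
    razor = unique + rng.geometric(0.6, size=n_feat) - 1
    # Target q-values concentrate below the 0.01 cutoff, with a minority of
    # low-confidence groups in [0.01, 0.05).
    low_q = rng.random(n_feat) < params.low_q_fraction
    q = np.where(
        low_q,
        rng.uniform(0.01, 0.05, size=n_feat),
        rng.uniform(0.0, 0.01, size=n_feat),
    )
    fraction = np.where(rng.random(n_feat) < params.symbiont_fraction,
                        "symbiont", "host")

    truth = GroundTruth(effects=dict(params.group_effects))

    def _meta_rows(ids, frac, uniq, raz, qv, cont, rev):
        return pd.DataFrame(
            {
                "Protein IDs": ids,
                "Fraction": frac,
                "Unique peptides": uniq,
                "Razor + unique peptides": raz,
                "Q-value": qv,
                "Potential contaminant": np.where(cont, "+", ""),
                "Reverse": np.where(rev, "+", ""),
            }
        )

    meta = _meta_rows(features, fraction, unique, razor, q,
                      np.zeros(n_feat, bool), np.zeros(n_feat, bool))
    intens = pd.DataFrame(
        np.where(missing, np.nan, raw),
        columns=[f"Intensity {s}" for s in samples["sample_id"]],
    )
    table = pd.concat([meta, intens], axis=1)

    # Contaminant and decoy rows ride along with plausible metadata; decoys
    # carry uniform q-values on [0, 1].
    n_cont = int(round(params.contaminant_rate * params.n_proteins))
    n_rev = int(round(params.reverse_rate * params.n_proteins))
    extra = []
    if n_cont:
        ids = [f"CON__{i:04d}" for i in range(1, n_cont + 1)]
        truth.contaminants = ids
        uq = rng.geometric(0.5, n_cont)
        m = _meta_rows(
            ids, "host",
            uq, uq + rng.geometric(0.5, n_cont) - 1,
            rng.uniform(0.0, 0.01, n_cont),
            np.ones(n_cont, bool), np.zeros(n_cont, bool),
        )
        vals = np.exp2(rng.normal(params.baseline_log2_mean, 1.0, (n_cont, n_samp)))
        extra.append(pd.concat([m, pd.DataFrame(vals, columns=intens.columns)], axis=1))
    if n_rev:
        ids = [f"REV__{i:04d}" for i in range(1, n_rev + 1)]
        truth.decoys = ids
        uq = rng.geometric(0.5, n_rev)
        m = _meta_rows(
            ids, "host",
            uq, uq + rng.geometric(0.5, n_rev) - 1,
            rng.uniform(0.0, 1.0, n_rev),
            np.zeros(n_rev, bool), np.ones(n_rev, bool),
        )
        vals = np.exp2(rng.normal(params.baseline_log2_mean - 4.0, 1.0, (n_rev, n_samp)))
        extra.append(pd.concat([m, pd.DataFrame(vals, columns=intens.columns)], axis=1))
    if extra:
        table = pd.concat([table, *extra], ignore_index=True)

    return table, truth


def simulate_annotation(
    features: Sequence[str],
    pathway_sizes: Mapping[str, int],
    seed: int = 0,
    shared_ko_pairs: int = 0,
) -> Tuple[Dict[str, str], Dict[str, List[str]]]:
    """Assign features to KOs and KOs to B-level pathways.

    Each annotated feature maps to exactly one KO; unannotated features are
    simply absent from the map (real annotators leave much of a coral
    proteome without a KO).  ``shared_ko_pairs`` KOs are additionally listed
    under a second pathway, so their features count in both memberships.
    """
    total = int(sum(pathway_sizes.values()))
    if total > len(features):
        raise ValueError(
            f"pathway sizes sum to {total} but only {len(features)} features exist"
        )
    rng = _rng(seed, "annotation")
    order = list(features)
    rng.shuffle(order)

    feat2ko: Dict[str, str] = {}
    ko2path: Dict[str, List[str]] = {}
    cursor = 0
    ko_counter = 1
    for pathway in pathway_sizes:  # insertion order: deterministic
        for _ in range(pathway_sizes[pathway]):
            ko = f"K{ko_counter:05d}"
            ko_counter += 1
            feat2ko[order[cursor]] = ko
            ko2path[ko] = [pathway]
            cursor += 1

    if shared_ko_pairs and len(pathway_sizes) >= 2:
        names = list(pathway_sizes)
        kos = sorted(ko2path)
        for i in range(min(shared_ko_pairs, len(kos))):
            ko = kos[i]
            home = ko2path[ko][0]
            other = names[(names.index(home) + 1) % len(names)]
            if other not in ko2path[ko]:
                ko2path[ko].append(other)
    return feat2ko, ko2path


@dataclass
class PhysiologyParams:
    """Planted physiology: bleaching factors scale endosymbiont density."""

    base_quadrat_mean: float = 50.0       # expected hemocytometer count per quadrat
    surface_area_range: Tuple[float, float] = (5.0, 15.0)  # cm^2
    wax_slope: float = 20.0               # cm^2 per gram of wax
    wax_intercept: float = 0.5            # cm^2
    slurry_volume_ml: float = 10.0
    base_fvfm: float = 0.65
    fvfm_noise_sd: float = 0.01
    # (species, timepoint) -> multiplicative factor on stress-sample density
    bleaching_factors: Dict[Tuple[str, str], float] = field(default_factory=dict)
    # (species, timepoint) -> additive Fv/Fm change on stress samples
    fvfm_effects: Dict[Tuple[str, str], float] = field(default_factory=dict)


def simulate_physiology(
    design: SampleDesign,
    params: Optional[PhysiologyParams] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fragment physiology table plus wax calibration standards.

    Quadrat counts are Poisson around a density mean scaled by the planted
    bleaching factor; wax masses are consistent with a known true surface
    area and the known calibration line; Fv/Fm triplicates get additive
    Gaussian noise (``fvfm_noise_sd=0`` recovers the truth exactly).
    """
    if len(design) == 0:
        raise ValueError("design is empty")
    params = params or PhysiologyParams()
    rng = _rng(seed, "physiology")
    rows = []
    for _, s in design.table.iterrows():
        key = (s["species"], s["timepoint"])
        factor = 1.0
        dfv = 0.0
        if s["treatment"] == "stress":
            factor = params.bleaching_factors.get(key, 1.0)
            dfv = params.fvfm_effects.get(key, 0.0)
        lo, hi = params.surface_area_range
        area = rng.uniform(lo, hi)
        wax_mass = (area - params.wax_intercept) / params.wax_slope
        mass_pre = rng.uniform(5.0, 20.0)
        counts = rng.poisson(params.base_quadrat_mean * factor, size=8)
        fvfm_true = np.clip(params.base_fvfm + dfv, 0.0, 1.0)
        fvfm = np.clip(
            fvfm_true + rng.normal(0.0, params.fvfm_noise_sd, size=3), 0.0, 1.0
        )
        row = {
            "sample_id": s["sample_id"],
            "species": s["species"],
            "tank": s["tank"],
            "treatment": s["treatment"],
            "timepoint": s["timepoint"],
            "replicate": s["replicate"],
            "slurry_volume_ml": params.slurry_volume_ml,
            "mass_pre_g": mass_pre,
            "mass_post_g": mass_pre + wax_mass,
            "true_surface_area_cm2": area,
        }
        row.update({f"quadrat_count_{i + 1}": int(c) for i, c in enumerate(counts)})
        row.update({f"fvfm_{i + 1}": float(v) for i, v in enumerate(fvfm)})
        rows.append(row)

    table = pd.DataFrame(rows)

    # Eight cylindrical standards on the same known line (exact by design;
    # calibration noise belongs to the fit, not the truth).
    wax = np.linspace(0.05, 0.75, 8)
    standards = pd.DataFrame(
        {"wax_mass_g": wax, "area_cm2": params.wax_intercept + params.wax_slope * wax}
    )
    return table, standards


METABOLITE_CLASSES = ("dipeptide", "amino_acid", "antioxidant", "other")
DIPEPTIDES = ("KQ", "RQ", "RA", "RV")


def simulate_metabolome(
    design: SampleDesign,
    effects: Optional[Mapping[Tuple[str, str, str], float]] = None,
    n_reps: int = 6,
    n_other: int = 20,
    noise_sd: float = 0.4,
    baseline_log2_mean: float = 16.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Polar-metabolite abundance table with its own replicate structure.

    Metabolomics assays more fragments than proteomics, so the table carries
    ``n_reps`` replicates per species x treatment x timepoint cell (default
    6), generated independently of the proteome design rows.  ``effects``
    maps ``(metabolite, species, timepoint)`` to a planted log2 shift on the
    stress samples.  Returns ``(abundance table, metabolite class table)``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    effects = dict(effects or {})
    rng = _rng(seed, "metabolome")

    amino = ["alanine", "arginine", "glycine", "leucine", "methionine",
             "proline", "serine", "valine"]
    anti = ["hypotaurine", "CDP-choline", "phosphocholine", "glutathione"]
    other = [f"met{i:03d}" for i in range(1, n_other + 1)]
    metabolites = list(DIPEPTIDES) + amino + anti + other
    classes = (["dipeptide"] * len(DIPEPTIDES) + ["amino_acid"] * len(amino)
               + ["antioxidant"] * len(anti) + ["other"] * len(other))
    mset = set(metabolites)
    for (m, sp, tp) in effects:
        if m not in mset:
            raise KeyError(f"planted effect references unknown metabolite {m!r}")

    cells = (
        design.table[["species", "treatment", "timepoint"]]
        .drop_duplicates()
        .sort_values(["species", "timepoint", "treatment"])
        .reset_index(drop=True)
    )
    sample_ids = []
    meta_rows = []
    for _, c in cells.iterrows():
        for r in range(1, n_reps + 1):
            sid = f"M_{c['species']}_{c['treatment']}_{c['timepoint']}_r{r}"
            sample_ids.append(sid)
            meta_rows.append((sid, c["species"], c["treatment"], c["timepoint"], r))

    baseline = rng.normal(baseline_log2_mean, 1.5, size=len(metabolites))
    log2_vals = baseline[:, None] + rng.normal(
        0.0, noise_sd, size=(len(metabolites), len(sample_ids))
    )
    midx = {m: i for i, m in enumerate(metabolites)}
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "species", "treatment", "timepoint", "replicate"]
    )
    for (m, sp, tp), shift in effects.items():
        mask = (
            (meta["species"] == sp)
            & (meta["timepoint"] == tp)
            & (meta["treatment"] == "stress")
        ).to_numpy()
        log2_vals[midx[m], mask] += shift

    abundance = pd.DataFrame(np.exp2(log2_vals), index=metabolites, columns=sample_ids)
    abundance.index.name = "metabolite"
    # Sample metadata travels as attrs; writers emit it as a sidecar design.
    abundance.attrs["design"] = meta
    class_table = pd.DataFrame({"metabolite": metabolites, "class": classes})
    return abundance, class_table


# ---------------------------------------------------------------------------
# Bundled study generation (used by the CLI `simulate` and the pipeline).


@dataclass
class StudyTruth:
    proteome: GroundTruth
    metabolite_effects: Dict[Tuple[str, str, str], float]
    physiology: PhysiologyParams


def default_study(
    seed: int = 0,
    n_proteins: int = 200,
    noise_sd: float = 0.3,
) -> dict:
    """One fully wired synthetic study with planted, recoverable signal.

    Plants a downregulated pathway (30% of its members shifted -2 log2 under
    stress at TP1 and TP2 in every species), an upregulated chaperone-like
    pathway, bleaching factors and Fv/Fm declines for the sensitive species,
    and dipeptide accumulation in the metabolome.
    """
    design = generate_design(3, 3, ("TP0", "TP1", "TP2"), 1, bailout_species="C")
    features = _feature_ids(n_proteins)
    pathway_sizes = {
        "Energy metabolism": max(12, n_proteins // 4),
        "Folding, sorting and degradation": max(12, n_proteins // 5),
        "Carbohydrate metabolism": max(12, n_proteins // 5),
    }
    feat2ko, ko2path = simulate_annotation(features, pathway_sizes, seed=seed)
    by_path: Dict[str, List[str]] = {}
    for f, ko in feat2ko.items():
        for p in ko2path[ko]:
            by_path.setdefault(p, []).append(f)
    for p in by_path:
        by_path[p].sort()

    effects: Dict[EffectKey, float] = {}
    truth_cats: Dict[Tuple[str, str, str], str] = {}
    down = by_path["Energy metabolism"]
    up = by_path["Folding, sorting and degradation"]
    for sp in ("A", "B", "C"):
        for tp in ("TP1", "TP2"):
            if sp == "C" and tp == "TP2":
                continue  # bail-out species has no stress samples there
            for f in down[: max(1, int(0.3 * len(down)))]:
                effects[(f, sp, tp)] = -2.0
            for f in up[: max(1, int(0.3 * len(up)))]:
                effects[(f, sp, tp)] = 2.0
            truth_cats[("Energy metabolism", sp, tp)] = "downregulated"
            truth_cats[("Folding, sorting and degradation", sp, tp)] = "upregulated"

    params = SimulationParams(
        n_proteins=n_proteins, noise_sd=noise_sd, group_effects=effects, seed=seed
    )
    proteome, truth = simulate_proteome(design, params)
    truth.pathway_truth = truth_cats

    phys_params = PhysiologyParams(
        bleaching_factors={("A", "TP1"): 0.5, ("A", "TP2"): 0.25,
                           ("B", "TP2"): 0.5, ("C", "TP1"): 0.4},
        fvfm_effects={("A", "TP2"): -0.125, ("B", "TP2"): -0.05, ("C", "TP1"): -0.13},
    )
    physiology, standards = simulate_physiology(design, phys_params, seed=seed)

    met_effects = {}
    for sp, tp in (("A", "TP1"), ("A", "TP2"), ("B", "TP2"), ("C", "TP1")):
        for dp in DIPEPTIDES:
            met_effects[(dp, sp, tp)] = 3.0
        met_effects[("alanine", sp, tp)] = 1.5
    metabolome, met_classes = simulate_metabolome(design, met_effects, seed=seed)

    return {
        "design": design,
        "proteome": proteome,
        "feat2ko": feat2ko,
        "ko2path": ko2path,
        "physiology": physiology,
        "standards": standards,
        "metabolome": metabolome,
        "metabolite_classes": met_classes,
        "truth": StudyTruth(truth, met_effects, phys_params),
    }


def planted_pathway_study(
    seed: int,
    n_proteins: int = 200,
    focal_size: int = 100,
    background_size: int = 60,
    planted_fraction: float = 0.3,
    shift: float = -2.0,
    missing_rate: float = 0.0,
    noise_sd: float = 0.3,
) -> dict:
    """Benchmark scenario: one large pathway with a planted directional shift.

    A fraction of the focal pathway's members is shifted by ``shift`` log2
    units under stress at TP1 and TP2 in every species (the bail-out species
    only at TP1), against a null background pathway and unannotated
    proteins.  Used to measure end-to-end recovery of the expected
    conservation category.
    """
    design = generate_design(3, 3, ("TP0", "TP1", "TP2"), 1, bailout_species="C")
    features = _feature_ids(n_proteins)
    focal = "Focal pathway"
    feat2ko, ko2path = simulate_annotation(
        features, {focal: focal_size, "Background pathway": background_size},
        seed=seed,
    )
    members = sorted(f for f, ko in feat2ko.items() if focal in ko2path[ko])
    planted = members[: int(planted_fraction * len(members))]
    effects: Dict[EffectKey, float] = {}
    for sp in ("A", "B", "C"):
        for tp in ("TP1", "TP2"):
            if sp == "C" and tp == "TP2":
                continue
            for f in planted:
                effects[(f, sp, tp)] = shift
    params = SimulationParams(
        n_proteins=n_proteins, noise_sd=noise_sd, missing_rate=missing_rate,
        group_effects=effects, seed=seed,
    )
    frame, truth = simulate_proteome(design, params)
    return {
        "design": design, "proteome": frame, "feat2ko": feat2ko,
        "ko2path": ko2path, "focal_pathway": focal, "planted": planted,
        "truth": truth,
    }


# -- writers (plain-text formats only) --------------------------------------

def write_ko_map(feat2ko: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for f in sorted(feat2ko):
            fh.write(f"{f}\t{feat2ko[f]}\n")


def write_hierarchy(ko2path: Mapping[str, List[str]], path,
                    a_level: str = "Metabolism") -> None:
    with open(path, "w") as fh:
        for ko in sorted(ko2path):
            for b in ko2path[ko]:
                fh.write(f"{ko}\t{b}\t{a_level}\n")


def write_study(study: dict, outdir) -> None:
    """Serialize a generated study to plain-text files under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study["design"].to_csv(out / "design.csv")
    study["proteome"].to_csv(out / "protein_groups.tsv", sep="\t", index=False)
    write_ko_map(study["feat2ko"], out / "ko_map.tsv")
    write_hierarchy(study["ko2path"], out / "hierarchy.tsv")
    study["physiology"].to_csv(out / "physiology.csv", index=False)
    study["standards"].to_csv(out / "wax_standards.csv", index=False)
    met = study["metabolome"]
    met.to_csv(out / "metabolites.csv")
    met.attrs["design"].to_csv(out / "metabolite_design.csv", index=False)
    study["metabolite_classes"].to_csv(out / "metabolite_classes.csv", index=False)
    study["truth"].proteome.to_json(out / "ground_truth.json")
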