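"""Run configuration, orchestration, provenance and summary exports."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .design import SampleDesign
from .differential import all_contrasts, differential_features, differential_metabolites
from .pathways import (PathwayVoteClassifier, build_membership, calls_to_frame,
                       conservation_table, load_annotations)
from .physiology import derive_physiology, fit_wax_calibration, species_statistics
from .qc import clean_proteome, read_protein_groups

log = logging.getLogger("coralstress")


@dataclass
class RunConfig:
    """All thresholds and seeds of a pipeline run, serializable to YAML.

    Defaults mirror the analysis the package implements: peptide-evidence
    and q-value identity filters, intensity floor 5, 80% presence, forest
    imputation seeded at 124, FC/p thresholds 0.5/0.05, 5% pathway vote,
    >10-protein pathway retention.
    """

    # inputs
    outdir: str = "results"
    design_path: Optional[str] = None
    protein_groups_path: Optional[str] = None
    ko_path: Optional[str] = None
    hierarchy_path: Optional[str] = None
    physiology_path: Optional[str] = None
    calibration_path: Optional[str] = None
    metabolite_path: Optional[str] = None
    metabolite_design_path: Optional[str] = None
    simulate: bool = False
    # thresholds
    fraction: str = "host"
    floor: float = 5.0
    min_presence: float = 0.80
    min_completeness: float = 0.5
    fc_thresh: float = 0.5
    p_thresh: float = 0.05
    pathway_frac: float = 0.05
    min_detected: int = 10
    test: str = "student"
    impute_trees: int = 100
    impute_rounds: int = 10
    impute_seed: int = 124
    drop_samples: List[str] = field(default_factory=list)
    seed: int = 0
    sim_n_proteins: int = 200

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def summarize_counts(differential_table: pd.DataFrame) -> pd.DataFrame:
    """Class tallies per species x timepoint, plus the responding fraction."""
    if differential_table.empty:
        return pd.DataFrame(
            columns=["species", "timepoint", "n_tested", "n_increased",
                     "n_decreased", "prop_responding"]
        )
    rows = []
    for (sp, tp), sub in differential_table.groupby(["species", "timepoint"]):
        inc = int((sub["class"] == "increased").sum())
        dec = int((sub["class"] == "decreased").sum())
        n = len(sub)
        rows.append(
            {
                "species": sp, "timepoint": tp, "n_tested": n,
                "n_increased": inc, "n_decreased": dec,
                "prop_responding": (inc + dec) / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values(["species", "timepoint"]).reset_index(drop=True)


def analyze_study(
    design: SampleDesign,
    proteome_frame: pd.DataFrame,
    feat2ko=None,
    ko2path=None,
    *,
    impute_trees: int = 100,
    impute_rounds: int = 10,
    impute_seed: int = 124,
    pathway_frac: float = 0.05,
    min_detected: int = 10,
) -> Dict[str, object]:
    """In-memory pipeline over a generated (or loaded) protein-group frame.

    Runs the per-species cleaning cascade, every available stress-vs-ambient
    contrast, and — when annotation maps are given — the pathway vote and
    conservation call.  Returns cleaned matrices, the concatenated
    differential table, pathway calls and the conservation table.
    """
    import io

    table = read_protein_groups(
        io.StringIO(proteome_frame.to_csv(sep="\t", index=False)), design=design
    )
    cleaned = {}
    for sp in design.species:
        sub = design.subset(species=sp)
        cleaned[sp] = clean_proteome(
            table, sub, impute_trees=impute_trees, impute_rounds=impute_rounds,
            impute_seed=impute_seed,
        ).matrix
    frames = [differential_features(cleaned[c.species], c)
              for c in all_contrasts(design)]
    diff = pd.concat(frames, ignore_index=True)
    out: Dict[str, object] = {"cleaned": cleaned, "differential": diff}
    if feat2ko is not None and ko2path is not None:
        memberships = build_membership(
            {sp: cleaned[sp].features for sp in cleaned}, feat2ko, ko2path
        )
        clf = PathwayVoteClassifier(frac=pathway_frac,
                                    min_detected=min_detected)
        clf.fit(memberships, diff)
        out["pathway_calls"] = clf.calls_
        out["conservation"] = conservation_table(clf.calls_, species=sorted(cleaned))
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the study pipeline and write its artifact bundle.

    Stages: simulate (or load) -> qc -> differential -> pathways ->
    conservation -> physiology -> metabolites.  Every stage failure aborts
    with the stage name; a manifest with input hashes, the resolved config
    and the package version is written next to the outputs, and a rerun
    from the same config and inputs reproduces them byte for byte.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: List[str] = []
    bundle: Dict[str, object] = {}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            stages.append(name)
            log.info("stage %s done", name)
            return result
        return deco

    if config.simulate:
        @stage("simulate")
        def _sim():
            from .simulate import default_study, write_study

            study = default_study(seed=config.seed,
                                  n_proteins=config.sim_n_proteins)
            write_study(study, out / "inputs")
            for key, name in [
                ("design_path", "design.csv"),
                ("protein_groups_path", "protein_groups.tsv"),
                ("ko_path", "ko_map.tsv"),
                ("hierarchy_path", "hierarchy.tsv"),
                ("physiology_path", "physiology.csv"),
                ("calibration_path", "wax_standards.csv"),
                ("metabolite_path", "metabolites.csv"),
                ("metabolite_design_path", "metabolite_design.csv"),
            ]:
                setattr(config, key, str(out / "inputs" / name))

    if config.design_path is None or config.protein_groups_path is None:
        raise RuntimeError("pipeline stage 'qc' failed: missing design or "
                           "protein-group input")
    design = SampleDesign.from_csv(config.design_path)

    @stage("qc")
    def cleaned():
        table = read_protein_groups(config.protein_groups_path, design=design)
        per_species = {}
        for sp in design.species:
            sub = design.subset(species=sp)
            res = clean_proteome(
                table, sub,
                fraction=config.fraction, floor=config.floor,
                min_presence=config.min_presence,
                min_completeness=config.min_completeness,
                impute_seed=config.impute_seed, impute_trees=config.impute_trees,
                impute_rounds=config.impute_rounds,
                drop=[s for s in config.drop_samples if s in sub.sample_ids],
            )
            res.matrix.to_tsv(out / f"cleaned_matrix_{sp}.tsv")
            with open(out / f"qc_report_{sp}.json", "w") as fh:
                json.dump(res.report.to_dict(), fh, indent=1, sort_keys=True)
            with open(out / f"filter_tally_{sp}.json", "w") as fh:
                json.dump(res.tally, fh, indent=1, sort_keys=True)
            per_species[sp] = res
        return per_species

    @stage("differential")
    def diff_table():
        frames = []
        for contrast in all_contrasts(design):
            matrix = cleaned[contrast.species].matrix
            frames.append(
                differential_features(
                    matrix, contrast, test=config.test,
                    fc_thresh=config.fc_thresh, p_thresh=config.p_thresh,
                )
            )
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(out / "differential.tsv", sep="\t", index=False)
        summarize_counts(table).to_csv(out / "summary_counts.tsv", sep="\t", index=False)
        return table

    bundle["differential"] = diff_table
    bundle["summary_counts"] = summarize_counts(diff_table)

    if config.ko_path and config.hierarchy_path:
        @stage("pathways")
        def calls():
            feat2ko, ko2b = load_annotations(config.ko_path, config.hierarchy_path)
            memberships = build_membership(
                {sp: cleaned[sp].matrix.features for sp in cleaned},
                feat2ko, ko2b,
            )
            clf = PathwayVoteClassifier(
                frac=config.pathway_frac, min_detected=config.min_detected
            ).fit(memberships, diff_table)
            calls_to_frame(clf.calls_).to_csv(out / "pathway_calls.tsv", sep="\t",
                                              index=False)
            return clf.calls_

        @stage("conservation")
        def conservation():
            table = conservation_table(calls, species=sorted(cleaned))
            table.to_csv(out / "conservation.tsv", sep="\t", index=False)
            matrix = {
                row["pathway"]: {
                    sp: row[f"direction_{sp}"] for sp in sorted(cleaned)
                    if f"direction_{sp}" in row
                }
                for row in table.to_dict("records")
            }
            with open(out / "pathway_matrix.json", "w") as fh:
                json.dump(matrix, fh, indent=1, sort_keys=True)
            return table

        bundle["pathway_calls"] = calls
        bundle["conservation"] = conservation
    elif config.ko_path or config.hierarchy_path:
        raise RuntimeError(
            "pipeline stage 'pathways' failed: both ko_path and hierarchy_path "
            "are required"
        )

    if config.physiology_path and config.calibration_path:
        @stage("physiology")
        def physio():
            table = pd.read_csv(config.physiology_path)
            standards = pd.read_csv(config.calibration_path)
            cal = fit_wax_calibration(
                list(zip(standards["wax_mass_g"], standards["area_cm2"]))
            )
            derived = derive_physiology(table, cal)
            derived.to_csv(out / "physiology_derived.csv", index=False)
            stats = {}
            for sp in sorted(derived["species"].unique()):
                s = species_statistics(derived, sp)
                stats[sp] = {
                    "cell_abundance_anova": {
                        "df_between": s["cell_abundance_anova"].df_between,
                        "F": s["cell_abundance_anova"].F,
                        "p": s["cell_abundance_anova"].p,
                    },
                    "fvfm_anova": {
                        "df_between": s["fvfm_anova"].df_between,
                        "F": s["fvfm_anova"].F,
                        "p": s["fvfm_anova"].p,
                    },
                    "cell_abundance_fc": s["cell_abundance_fc"],
                    "fvfm_percent_change": s["fvfm_percent_change"],
                }
            with open(out / "physiology_stats.json", "w") as fh:
                json.dump(stats, fh, indent=1, sort_keys=True)
            return derived

        bundle["physiology"] = physio

    if config.metabolite_path and config.metabolite_design_path:
        @stage("metabolites")
        def metabolites():
            table = pd.read_csv(config.metabolite_path, index_col=0)
            mdesign = pd.read_csv(config.metabolite_design_path)
            frames = []
            for (sp, tp), sub in mdesign.groupby(["species", "timepoint"]):
                if sub["treatment"].nunique() < 2:
                    continue
                frames.append(
                    differential_metabolites(
                        table, mdesign, sp, tp,
                        fc_thresh=config.fc_thresh, p_thresh=config.p_thresh,
                    )
                )
            met = pd.concat(frames, ignore_index=True)
            met.to_csv(out / "metabolite_differential.tsv", sep="\t", index=False)
            return met

        bundle["metabolites"] = metabolites

    config.to_yaml(out / "config.yaml")
    inputs = {}
    for key in ("design_path", "protein_groups_path", "ko_path", "hierarchy_path",
                "physiology_path", "calibration_path", "metabolite_path",
                "metabolite_design_path"):
        value = getattr(config, key)
        if value:
            inputs[key] = {"path": value, "sha256": _sha256(Path(value))}
    manifest = {
        "version": __version__,
        "stages": stages,
        "inputs": inputs,
        "config": asdict(config),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
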