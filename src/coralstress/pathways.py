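"""KEGG B-level pathway voting and cross-species conservation calls.

With only ~5-11% of a coral proteome detected, set-enrichment statistics
are underpowered, so pathway response is scored by a percentage vote over
the proteins actually detected: a pathway is upregulated at a timepoint
when >= 5% of its detected proteins are classified increased, downregulated
when >= 5% are decreased, mixed when both, stable when neither.  Pathways
are retained only when strictly more than ``min_detected`` proteins are
detected in every species.  Conservation across species collapses each
species' timepoint calls (TP0 excluded by default as the tank-effect
baseline) into a direction set; a pathway is conserved when all species
agree on a single direction, even if it emerges at different timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from sklearn.base import BaseEstimator

PATHWAY_CATEGORIES = ("upregulated", "downregulated", "mixed", "stable")
CONSERVATION_CATEGORIES = (
    "conserved_up", "conserved_down", "divergent", "species_specific", "none",
)


# ---------------------------------------------------------------------------
# Annotation loading


def _parse_flat_hierarchy(lines: Iterable[str], path: str) -> Dict[str, List[str]]:
    ko2b: Dict[str, List[str]] = {}
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{i}: expected >=2 tab-separated fields")
        ko, b_level = parts[0].strip(), parts[1].strip()
        if not ko or not b_level:
            raise ValueError(f"{path}:{i}: empty KO or B-level name")
        ko2b.setdefault(ko, [])
        if b_level not in ko2b[ko]:
            ko2b[ko].append(b_level)
    return ko2b


def parse_brite(lines: Iterable[str], path: str = "<brite>") -> Dict[str, List[str]]:
    """Parse the KEGG ko00001.keg BRITE text dialect into KO -> B-levels.

    Record lines are prefixed ``A``/``B``/``C``/``D``; B lines carry the
    B-level name after a numeric code (``B  09101 Carbohydrate metabolism``)
    and D lines carry KO identifiers (``D      K00844  HK; hexokinase``).
    A KO listed under several B records maps to all of them.
    """
    ko2b: Dict[str, List[str]] = {}
    current_b: Optional[str] = None
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "!", "+")):
            continue
        tag, body = line[0], line[1:].strip()
        if tag == "B":
            if not body:
                current_b = None
                continue
            parts = body.split(None, 1)
            current_b = parts[1].strip() if parts[0].isdigit() and len(parts) > 1 else body
        elif tag == "D":
            if not body:
                raise ValueError(f"{path}:{i}: empty D record")
            ko = body.split()[0]
            if not (ko.startswith("K") and ko[1:].isdigit()):
                continue  # gene lines without a KO
            if current_b is None:
                raise ValueError(f"{path}:{i}: KO record before any B-level header")
            ko2b.setdefault(ko, [])
            if current_b not in ko2b[ko]:
                ko2b[ko].append(current_b)
        elif tag in ("A", "C"):
            continue
        else:
            raise ValueError(f"{path}:{i}: unrecognized BRITE record {line[:20]!r}")
    return ko2b


def load_annotations(ko_path, hierarchy_path) -> Tuple[Dict[str, str], Dict[str, List[str]]]:
    """Load the feature -> KO map and the KO -> B-level hierarchy.

    The KO map is a 2-column TSV (feature_id, KO); duplicate feature rows
    are rejected.  The hierarchy may be a flat 3-column TSV (KO, B-level,
    A-level) or a KEGG BRITE ``ko00001.keg`` text file, detected from the
    first record line.
    """
    feat2ko: Dict[str, str] = {}
    with open(ko_path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{ko_path}:{i}: expected 'feature<TAB>KO'")
            feat = parts[0].strip()
            if feat in feat2ko:
                raise ValueError(f"{ko_path}:{i}: duplicate feature id {feat!r}")
            feat2ko[feat] = parts[1].strip()

    with open(hierarchy_path) as fh:
        lines = fh.readlines()
    first = next((l for l in lines if l.strip()), "")
    if first[:1] in "ABCD" and "\t" not in first:
        ko2b = parse_brite(lines, str(hierarchy_path))
    else:
        ko2b = _parse_flat_hierarchy(lines, str(hierarchy_path))
    return feat2ko, ko2b


# ---------------------------------------------------------------------------
# Membership


@dataclass
class PathwayMembership:
    """Detected features of one pathway in one species."""

    pathway: str
    species: str
    detected_features: Set[str] = field(default_factory=set)

    @property
    def n_detected(self) -> int:
        return len(self.detected_features)


def build_membership(
    features_by_species: Mapping[str, Iterable[str]],
    feat2ko: Mapping[str, str],
    ko2b: Mapping[str, Sequence[str]],
) -> List[PathwayMembership]:
    """Intersect cleaned-matrix features with the annotation per species.

    A feature whose KO maps to several B-level pathways is counted in every
    one of them.  Pathways with no detected members in a species still get
    an (empty) membership so retention can see the zero.
    """
    pathways = sorted({b for bs in ko2b.values() for b in bs})
    out: List[PathwayMembership] = []
    for species in sorted(features_by_species):
        detected: Dict[str, Set[str]] = {p: set() for p in pathways}
        for f in features_by_species[species]:
            ko = feat2ko.get(f)
            if ko is None:
                continue
            for b in ko2b.get(ko, ()):
                detected[b].add(f)
        for p in pathways:
            out.append(PathwayMembership(p, species, detected[p]))
    return out


def retain_pathways(
    memberships: Sequence[PathwayMembership],
    min_detected: int = 10,
    require_all_species: bool = True,
) -> List[str]:
    """Pathways with strictly more than ``min_detected`` detected proteins.

    With ``require_all_species`` the bound must hold in every species;
    otherwise one qualifying species suffices.
    """
    counts: Dict[str, List[int]] = {}
    for m in memberships:
        counts.setdefault(m.pathway, []).append(m.n_detected)
    keep = []
    for pathway, ns in counts.items():
        ok = all(n > min_detected for n in ns) if require_all_species else any(
            n > min_detected for n in ns
        )
        if ok:
            keep.append(pathway)
    return sorted(keep)


# ---------------------------------------------------------------------------
# Percentage vote


@dataclass
class PathwayCall:
    pathway: str
    species: str
    timepoint: str
    n_detected: int
    n_up: int
    n_down: int
    category: str

    @property
    def frac_up(self) -> float:
        return self.n_up / self.n_detected if self.n_detected else 0.0

    @property
    def frac_down(self) -> float:
        return self.n_down / self.n_detected if self.n_detected else 0.0


def classify_pathway(
    membership: PathwayMembership,
    differential_results: pd.DataFrame,
    frac: float = 0.05,
) -> PathwayCall:
    """Directional vote over one pathway's detected proteins at one contrast.

    ``differential_results`` must carry a row (feature_id, class) for every
    detected feature of this species at this contrast; the ``frac``
    threshold is inclusive (>=).
    """
    res = differential_results
    sub = res[res["feature_id"].isin(membership.detected_features)]
    missing = membership.detected_features - set(sub["feature_id"])
    if missing:
        raise ValueError(
            f"no differential result for detected features: {sorted(missing)}"
        )
    timepoints = sub["timepoint"].unique() if len(sub) else ["NA"]
    if len(timepoints) > 1:
        raise ValueError("differential results span multiple timepoints")
    n = membership.n_detected
    n_up = int((sub["class"] == "increased").sum())
    n_down = int((sub["class"] == "decreased").sum())
    up = n > 0 and n_up / n >= frac
    down = n > 0 and n_down / n >= frac
    if up and down:
        category = "mixed"
    elif up:
        category = "upregulated"
    elif down:
        category = "downregulated"
    else:
        category = "stable"
    return PathwayCall(membership.pathway, membership.species, str(timepoints[0]),
                       n, n_up, n_down, category)


class PathwayVoteClassifier(BaseEstimator):
    """Estimator form of the percentage vote over many pathways/contrasts.

    ``fit`` takes memberships plus a concatenated differential table (one
    row per feature x species x timepoint) and stores ``calls_``.
    """

    def __init__(self, frac: float = 0.05, min_detected: int = 10,
                 require_all_species: bool = True):
        self.frac = frac
        self.min_detected = min_detected
        self.require_all_species = require_all_species

    def fit(self, memberships: Sequence[PathwayMembership],
            differential_results: pd.DataFrame) -> "PathwayVoteClassifier":
        self.retained_ = retain_pathways(
            memberships, self.min_detected, self.require_all_species
        )
        retained = set(self.retained_)
        calls: List[PathwayCall] = []
        res = differential_results
        for m in memberships:
            if m.pathway not in retained:
                continue
            species_res = res[res["species"] == m.species]
            for tp in sorted(species_res["timepoint"].unique()):
                calls.append(
                    classify_pathway(m, species_res[species_res["timepoint"] == tp],
                                     self.frac)
                )
        self.calls_ = calls
        return self


# ---------------------------------------------------------------------------
# Conservation


@dataclass
class ConservationCall:
    pathway: str
    directions: Dict[str, Set[str]]  # species -> subset of {"up", "down"}
    category: str


_DIRECTION = {"upregulated": {"up"}, "downregulated": {"down"},
              "mixed": {"up", "down"}, "stable": set()}


def conservation_call(
    pathway: str,
    calls: Sequence[PathwayCall],
    species: Optional[Sequence[str]] = None,
    exclude_timepoints: Sequence[str] = ("TP0",),
) -> ConservationCall:
    """Collapse per-timepoint calls into one cross-species category.

    Each species' calls (outside the excluded baseline timepoints) collapse
    to a direction set: mixed contributes both directions, stable none.
    ``conserved_up``/``conserved_down`` require every species to hold
    exactly that one direction; any up-vs-down opposition (across species or
    within one) is ``divergent``; a single responding species is
    ``species_specific``; no response anywhere is ``none``.
    """
    relevant = [c for c in calls
                if c.pathway == pathway and c.timepoint not in set(exclude_timepoints)]
    if species is None:
        species = sorted({c.species for c in relevant})
    if not species:
        raise ValueError(f"no calls for pathway {pathway!r}")
    by_species: Dict[str, Set[str]] = {s: set() for s in species}
    for c in relevant:
        if c.species not in by_species:
            raise ValueError(f"call for unexpected species {c.species!r}")
        by_species[c.species] |= _DIRECTION[c.category]
    missing = [s for s in species if not any(c.species == s for c in relevant)]
    if missing:
        raise ValueError(f"pathway {pathway!r} lacks calls for species: {missing}")

    sets = list(by_species.values())
    nonempty = [d for d in sets if d]
    has_up = any("up" in d for d in sets)
    has_down = any("down" in d for d in sets)
    if not nonempty:
        category = "none"
    elif has_up and has_down:
        category = "divergent"
    elif all(d == {"up"} for d in sets):
        category = "conserved_up"
    elif all(d == {"down"} for d in sets):
        category = "conserved_down"
    else:
        # One direction, but only in a subset of the species.
        category = "species_specific"
    return ConservationCall(pathway, by_species, category)


def conservation_table(
    calls: Sequence[PathwayCall],
    species: Optional[Sequence[str]] = None,
    exclude_timepoints: Sequence[str] = ("TP0",),
) -> pd.DataFrame:
    """One conservation category per pathway present in ``calls``."""
    rows = []
    for pathway in sorted({c.pathway for c in calls}):
        cc = conservation_call(pathway, calls, species, exclude_timepoints)
        row = {"pathway": pathway, "category": cc.category}
        for sp, dirs in sorted(cc.directions.items()):
            row[f"direction_{sp}"] = "+".join(sorted(dirs)) or "-"
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["pathway", "category"])
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[PathwayCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": c.pathway, "species": c.species, "timepoint": c.timepoint,
                "n_detected": c.n_detected, "n_up": c.n_up, "n_down": c.n_down,
                "frac_up": c.frac_up, "frac_down": c.frac_down,
                "category": c.category,
            }
            for c in calls
        ]
    )
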