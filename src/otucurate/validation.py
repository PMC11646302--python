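"""Multi-criteria species validation.

Each named species is checked against (1) an expert-accepted species
list, (2) occurrence records falling inside a buffered convex hull
around the traps where the species was detected, and (3) a regional
checklist.  A species is validated when at least ``min_criteria`` of the
enabled criteria hold (default two of three).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

from ._geo import AzimuthalEquidistant
from .filtering import is_clean_binomial

logger = logging.getLogger(__name__)

__all__ = [
    "TrapSite",
    "OccurrenceDB",
    "Checklist",
    "ValidationConfig",
    "ValidationResult",
    "SearchRegion",
    "check_checklist",
    "check_expert",
    "build_search_region",
    "check_occurrences",
    "validate_species",
    "validate_all",
    "agreement_matrix",
]

CRITERIA = ("expert", "occurrence", "checklist")


@dataclass(frozen=True)
class TrapSite:
    trap_id: str
    latitude: float
    longitude: float

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"trap {self.trap_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"trap {self.trap_id}: longitude {self.longitude} out of range")


class OccurrenceDB:
    """Occurrence records (species, latitude, longitude), indexed by species."""

    def __init__(self, records: pd.DataFrame):
        required = {"species", "latitude", "longitude"}
        if not required.issubset(records.columns):
            raise ValueError(f"occurrence records need columns {sorted(required)}")
        lat = records["latitude"].to_numpy(dtype=float)
        lon = records["longitude"].to_numpy(dtype=float)
        if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
            raise ValueError("occurrence record with out-of-range coordinates")
        self.records = records.reset_index(drop=True)
        self._by_species = {sp: grp for sp, grp in records.groupby("species")}

    def __len__(self) -> int:
        return len(self.records)

    def for_species(self, species: str) -> pd.DataFrame:
        return self._by_species.get(species, self.records.iloc[0:0])


class Checklist:
    """Canonical names plus a synonym -> canonical resolution table."""

    def __init__(self, canonical: set[str], synonyms: dict[str, str] | None = None):
        synonyms = dict(synonyms or {})
        bad = [n for n in canonical if not is_clean_binomial(n)]
        if bad:
            raise ValueError(f"checklist names failing hygiene: {sorted(bad)[:5]}")
        targets = set(synonyms.values()) - set(canonical)
        if targets:
            raise ValueError(f"synonym targets not canonical: {sorted(targets)[:5]}")
        self.canonical = set(canonical)
        self.synonyms = synonyms

    def resolve(self, name: str) -> str:
        return self.synonyms.get(name, name)

    def __contains__(self, name: str) -> bool:
        return self.resolve(name) in self.canonical

    def __len__(self) -> int:
        return len(self.canonical)


@dataclass
class ValidationConfig:
    radius_km: float = 200.0
    min_criteria: int = 2
    enabled: tuple[str, ...] = CRITERIA

    def __post_init__(self):
        if self.radius_km <= 0:
            raise ValueError("radius_km must be > 0")
        unknown = set(self.enabled) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        if not 1 <= self.min_criteria <= len(self.enabled):
            raise ValueError("min_criteria must be between 1 and the number of enabled criteria")


@dataclass(frozen=True)
class ValidationResult:
    species: str
    criteria: dict[str, bool]  # enabled criteria only
    validated: bool
    evidence: dict[str, object] = field(default_factory=dict)


def check_checklist(species: str, checklist: Checklist) -> bool:
    """True iff the name is canonical in, or a synonym resolving into, the list."""
    return species in checklist


def check_expert(species: str, expert_list: Checklist) -> bool:
    """Membership in the expert-accepted list (same resolution path)."""
    return species in expert_list


class SearchRegion:
    """Convex hull of detection traps buffered by a radius, in a local
    azimuthal-equidistant km plane centred on the traps' centroid."""

    def __init__(self, traps: list[TrapSite], radius_km: float):
        if not traps:
            raise ValueError("cannot build a search region from zero traps")
        if radius_km <= 0:
            raise ValueError("radius_km must be > 0")
        self.traps = list(traps)
        self.radius_km = float(radius_km)
        lat0 = float(np.mean([t.latitude for t in traps]))
        lon0 = float(np.mean([t.longitude for t in traps]))
        self.projection = AzimuthalEquidistant(lat0, lon0)
        xs, ys = self.projection.forward([t.latitude for t in traps], [t.longitude for t in traps])
        hull = MultiPoint(list(zip(np.atleast_1d(xs), np.atleast_1d(ys)))).convex_hull
        self.geometry = hull.buffer(radius_km, quad_segs=256)

    def contains(self, latitude: float, longitude: float) -> bool:
        x, y = self.projection.forward(latitude, longitude)
        return self.geometry.covers(Point(float(x), float(y)))


def build_search_region(detection_traps: list[TrapSite], radius_km: float = 200.0) -> SearchRegion:
    """Buffered convex hull (disc for one trap, stadium for a collinear set)."""
    return SearchRegion(detection_traps, radius_km)


def check_occurrences(species: str, detection_traps: list[TrapSite],
                      db: OccurrenceDB, cfg: ValidationConfig) -> tuple[bool, int]:
    """(any record inside the search region, number of records inside)."""
    recs = db.for_species(species)
    if len(recs) == 0:
        return False, 0
    region = build_search_region(detection_traps, cfg.radius_km)
    n_inside = sum(
        1 for lat, lon in zip(recs["latitude"].to_numpy(), recs["longitude"].to_numpy())
        if region.contains(float(lat), float(lon))
    )
    return n_inside > 0, n_inside


def validate_species(criteria: dict[str, bool], cfg: ValidationConfig) -> bool:
    """Consensus verdict: at least ``min_criteria`` enabled criteria true."""
    missing = set(cfg.enabled) - set(criteria)
    if missing:
        raise ValueError(f"criteria not evaluated: {sorted(missing)}")
    return sum(bool(criteria[c]) for c in cfg.enabled) >= cfg.min_criteria


def validate_all(species_names: list[str], detections: dict[str, list[TrapSite]],
                 db: OccurrenceDB, checklist: Checklist, expert_list: Checklist,
                 cfg: ValidationConfig | None = None,
                 synonyms: dict[str, str] | None = None) -> list[ValidationResult]:
    """Run all enabled criteria for every species.

    ``synonyms`` is an optional shared resolution table applied before
    the occurrence lookup (checklist/expert carry their own).
    """
    cfg = cfg or ValidationConfig()
    results = []
    resolve = (lambda n: synonyms.get(n, n)) if synonyms else (lambda n: n)
    for sp in species_names:
        traps = detections.get(sp, [])
        if "occurrence" in cfg.enabled and not traps:
            logger.warning("species %s has no detection traps; skipped", sp)
            continue
        criteria: dict[str, bool] = {}
        evidence: dict[str, object] = {}
        if "expert" in cfg.enabled:
            criteria["expert"] = check_expert(sp, expert_list)
        if "checklist" in cfg.enabled:
            criteria["checklist"] = check_checklist(sp, checklist)
        if "occurrence" in cfg.enabled:
            ok, n = check_occurrences(resolve(sp), traps, db, cfg)
            criteria["occurrence"] = ok
            evidence["n_occurrence_records_inside"] = n
            evidence["n_detection_traps"] = len(traps)
        results.append(ValidationResult(sp, criteria, validate_species(criteria, cfg), evidence))
    return results


def agreement_matrix(results: list[ValidationResult]) -> pd.DataFrame:
    """Pairwise percent agreement (both booleans equal) between criteria."""
    if not results:
        raise ValueError("agreement_matrix needs at least one result")
    names = [c for c in CRITERIA if all(c in r.criteria for r in results)]
    vecs = {c: np.array([r.criteria[c] for r in results]) for c in names}
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            mat.loc[a, b] = 100.0 * float(np.mean(vecs[a] == vecs[b]))
    return mat
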