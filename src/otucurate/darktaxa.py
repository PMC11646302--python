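"""Plausible-species and dark-taxa estimation.

Unnamed OTU counts are normalized by the mean number of OTUs per
validated species within each order (or family), yielding "plausible"
species behind the unnamed OTUs.  Regional known/barcoded species
counts then split the plausible species into those merely lacking a
reference barcode and potential dark taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .filtering import OtuAnnotation, SpeciesTable

logger = logging.getLogger(__name__)

__all__ = [
    "OrderEstimate",
    "ReferenceCounts",
    "otus_per_species_ratio",
    "plausible_species",
    "partition_dark",
    "total_species",
    "estimate_orders",
]


@dataclass(frozen=True)
class ReferenceCounts:
    """Regionally known and barcoded species counts for one taxon."""

    taxon: str
    known_species: int
    barcoded_species: int

    def __post_init__(self):
        if self.known_species < 0 or self.barcoded_species < 0:
            raise ValueError(f"{self.taxon}: counts must be >= 0")


@dataclass
class OrderEstimate:
    taxon: str
    n_otus_total: int
    n_otus_named: int
    n_validated_species: int
    mean_otus_per_species: float
    ratio_is_fallback: bool
    n_plausible: int
    n_known_in_region: int
    n_barcoded_in_region: int
    n_missing_reference: int
    n_potential_dark: int
    excluded: bool = False

    def __post_init__(self):
        if self.n_plausible != self.n_missing_reference + self.n_potential_dark:
            raise ValueError(f"{self.taxon}: plausible != missing_reference + potential_dark")


def otus_per_species_ratio(species_table: SpeciesTable, annotations: dict[str, OtuAnnotation],
                           validated: set[str], level: str = "order") -> tuple[dict[str, float], set[str]]:
    """Mean OTUs per validated species by taxon at ``level``.

    Returns (ratios, fallback_taxa).  Taxa present among the annotations
    but without any validated species receive the global mean ratio and
    are flagged in ``fallback_taxa``.
    """
    if level not in ("order", "family"):
        raise ValueError("level must be 'order' or 'family'")
    otus_by_taxon: dict[str, int] = {}
    species_by_taxon: dict[str, int] = {}
    for sp, n_otus in species_table.otus_per_species.items():
        if sp not in validated:
            continue
        members = species_table.otu_members.get(sp, [])
        taxon = annotations[members[0]].taxonomy.get(level, "") if members else ""
        otus_by_taxon[taxon] = otus_by_taxon.get(taxon, 0) + n_otus
        species_by_taxon[taxon] = species_by_taxon.get(taxon, 0) + 1
    ratios = {t: otus_by_taxon[t] / species_by_taxon[t] for t in species_by_taxon}
    total_otus = sum(otus_by_taxon.values())
    total_species_ = sum(species_by_taxon.values())
    global_ratio = total_otus / total_species_ if total_species_ else 1.0
    all_taxa = {ann.taxonomy.get(level, "") for ann in annotations.values()}
    fallback = {t for t in all_taxa if t not in ratios}
    for t in fallback:
        ratios[t] = global_ratio
        logger.warning("taxon %r has no validated species; using global ratio %.3f", t, global_ratio)
    return ratios, fallback


def plausible_species(n_unnamed_otus: dict[str, int], ratios: dict[str, float],
                      exclusions: set[str] | None = None) -> dict[str, int]:
    """Per-taxon plausible species: round(unnamed OTUs / ratio).

    Rounding is round-half-even per taxon.  Excluded taxa contribute 0.
    """
    exclusions = exclusions or set()
    out = {}
    for taxon, n in n_unnamed_otus.items():
        if taxon in exclusions:
            out[taxon] = 0
            continue
        ratio = ratios.get(taxon)
        if ratio is None:
            raise KeyError(f"no OTU/species ratio for taxon {taxon!r}")
        if ratio <= 0:
            raise ValueError(f"taxon {taxon!r}: ratio must be > 0")
        out[taxon] = round(n / ratio)
    return out


def partition_dark(plausible: int, known_species: int, barcoded_species: int) -> tuple[int, int]:
    """(missing_reference, potential_dark) for one taxon.

    Capacity is known-but-unbarcoded species; plausible species beyond
    that capacity are potential dark taxa.
    """
    if barcoded_species > known_species:
        logger.warning("barcoded (%d) > known (%d); clamping", barcoded_species, known_species)
        barcoded_species = known_species
    capacity = known_species - barcoded_species
    missing_reference = min(plausible, capacity)
    return missing_reference, plausible - missing_reference


def total_species(validated_count: int, plausible_counts) -> int:
    """Grand total = validated species + sum of per-taxon plausible species."""
    if isinstance(plausible_counts, dict):
        plausible_counts = plausible_counts.values()
    return int(validated_count) + int(sum(plausible_counts))


def estimate_orders(species_table: SpeciesTable, annotations: dict[str, OtuAnnotation],
                    validated: set[str], otu_ids: list[str],
                    reference: dict[str, ReferenceCounts] | None = None,
                    level: str = "order",
                    exclusions: set[str] | None = None,
                    mode: str = "unnamed") -> list[OrderEstimate]:
    """Full per-taxon accounting over the given (insect) OTU set.

    ``mode='unnamed'`` normalizes only OTUs without a species name;
    ``mode='all'`` normalizes every OTU and subtracts the validated
    species count (floored at 0).
    """
    if mode not in ("unnamed", "all"):
        raise ValueError("mode must be 'unnamed' or 'all'")
    exclusions = exclusions or set()
    reference = reference or {}
    ratios, fallback = otus_per_species_ratio(species_table, annotations, validated, level)

    named_otus = {o for members in species_table.otu_members.values() for o in members}
    totals: dict[str, int] = {}
    named: dict[str, int] = {}
    val_by_taxon: dict[str, int] = {}
    for otu in otu_ids:
        taxon = annotations[otu].taxonomy.get(level, "")
        totals[taxon] = totals.get(taxon, 0) + 1
        if otu in named_otus:
            named[taxon] = named.get(taxon, 0) + 1
    for sp in validated:
        members = species_table.otu_members.get(sp, [])
        if members:
            taxon = annotations[members[0]].taxonomy.get(level, "")
            val_by_taxon[taxon] = val_by_taxon.get(taxon, 0) + 1

    if mode == "unnamed":
        numerators = {t: totals[t] - named.get(t, 0) for t in totals}
    else:
        numerators = dict(totals)
    plaus = plausible_species(numerators, ratios, exclusions)
    if mode == "all":
        plaus = {t: max(p - val_by_taxon.get(t, 0), 0) for t, p in plaus.items()}

    estimates = []
    for taxon in sorted(totals):
        p = plaus[taxon]
        ref = reference.get(taxon)
        if ref is None:
            if p > 0:
                logger.warning("taxon %r absent from reference counts; capacity 0", taxon)
            known, barcoded = 0, 0
        else:
            known, barcoded = ref.known_species, ref.barcoded_species
        miss, dark = partition_dark(p, known, barcoded)
        estimates.append(OrderEstimate(
            taxon=taxon,
            n_otus_total=totals[taxon],
            n_otus_named=named.get(taxon, 0),
            n_validated_species=val_by_taxon.get(taxon, 0),
            mean_otus_per_species=ratios[taxon],
            ratio_is_fallback=taxon in fallback,
            n_plausible=p,
            n_known_in_region=known,
            n_barcoded_in_region=barcoded,
            n_missing_reference=miss,
            n_potential_dark=dark,
            excluded=taxon in exclusions,
        ))
    return estimates
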