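"""Seeded, ground-truthed synthetic datasets.

Emulates the statistical structure the downstream stages assume: a
samples x OTUs read table with duplicate libraries and negative
controls, per-species OTU inflation with a pseudogene fraction carrying
stop codons, partial reference coverage (only some species receive
names), regional checklists, and occurrence records spatially clustered
around the traps where each species occurs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .darktaxa import ReferenceCounts
from .filtering import INVERTEBRATE_MITO_TABLE, OtuAnnotation, OtuTable
from .validation import Checklist, OccurrenceDB, TrapSite

from Bio.Data import CodonTable

__all__ = ["CommunitySpec", "GroundTruth", "SyntheticDataset", "generate_dataset", "write_fixture"]

# Germany-like bounding box for trap placement
_LAT_RANGE = (47.5, 54.5)
_LON_RANGE = (6.5, 14.5)
_KM_PER_DEG_LAT = 111.32

_SENSE_CODONS = sorted(
    set("".join(c) for c in itertools.product("ACGT", repeat=3))
    - set(CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE].stop_codons)
)
# 11-mer with a stop codon in every forward reading frame regardless of
# where it lands in the sequence (stops at offsets 0, 4 and 8).
_TRIPLE_STOP_MOTIF = "TAAATAAATAA"

SEQUENCE_LENGTH = 205


class CommunitySpec(BaseModel):
    """Parameters of a synthetic monitoring community."""

    n_orders: int = Field(default=5, ge=1)
    species_per_order: int | list[int] = 40
    otu_inflation_mean: float = Field(default=1.3, ge=1.0)
    pseudogene_rate: float = Field(default=0.35, ge=0.0, le=1.0)
    reference_coverage: float = Field(default=0.7, ge=0.0, le=1.0)
    checklist_coverage: float = Field(default=0.9, ge=0.0, le=1.0)
    occurrence_density: float = Field(default=3.0, ge=0.0)
    occurrence_radius_km: float = Field(default=100.0, gt=0.0)
    n_traps: int = Field(default=6, ge=1)
    samples_per_trap: int = Field(default=10, ge=1)
    occupancy: float = Field(default=0.2, ge=0.0, le=1.0)
    read_abundance_mu: float = 5.0
    read_abundance_sigma: float = Field(default=1.0, ge=0.0)
    contamination_reads_mean: float = Field(default=0.2, ge=0.0)
    replicate_dropout: float = Field(default=0.05, ge=0.0, le=1.0)
    synonym_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_species_counts(self):
        spo = self.species_per_order
        if isinstance(spo, list):
            if len(spo) != self.n_orders:
                raise ValueError("species_per_order list length must equal n_orders")
            if any(s < 1 for s in spo):
                raise ValueError("species_per_order entries must be positive")
        elif spo < 1:
            raise ValueError("species_per_order must be positive")
        return self

    def species_counts(self) -> list[int]:
        if isinstance(self.species_per_order, list):
            return list(self.species_per_order)
        return [self.species_per_order] * self.n_orders


@dataclass
class GroundTruth:
    """What the generator actually put into the dataset."""

    true_species_total: int
    true_named_species: int
    true_dark_species: int
    species_to_otus: dict[str, list[str]]
    species_presence: dict[str, list[str]]  # species id -> occupied sample ids
    species_order: dict[str, str] = field(default_factory=dict)
    named_species: dict[str, str] = field(default_factory=dict)  # species id -> binomial

    def __post_init__(self):
        n_unnamed = self.true_species_total - self.true_named_species
        if n_unnamed < 0:
            raise ValueError("more named species than species total")


@dataclass
class SyntheticDataset:
    table: OtuTable
    annotations: dict[str, OtuAnnotation]
    traps: list[TrapSite]
    occurrences: OccurrenceDB
    checklist: Checklist
    expert_list: Checklist
    reference_counts: dict[str, ReferenceCounts]
    library_map: pd.DataFrame  # library_id, sample_id, trap_id, group, role
    truth: GroundTruth
    spec: CommunitySpec


def _alpha(index: int, width: int = 3) -> str:
    """Letters-only base-26 rendering of an index (keeps names digit-free)."""
    chars = []
    for _ in range(width):
        index, r = divmod(index, 26)
        chars.append(chr(ord("a") + r))
    return "".join(reversed(chars))


def _random_coding_sequence(rng: np.random.Generator) -> str:
    n_codons = SEQUENCE_LENGTH // 3
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
    seq = "".join(_SENSE_CODONS[i] for i in codons)
    tail = SEQUENCE_LENGTH - 3 * n_codons
    if tail:
        seq += "".join(rng.choice(list("ACGT"), size=tail))
    return seq


def _pseudogenize(seq: str, rng: np.random.Generator) -> str:
    """Overwrite a window with a motif that puts a stop in all 3 frames."""
    pos = int(rng.integers(0, len(seq) - len(_TRIPLE_STOP_MOTIF) + 1))
    return seq[:pos] + _TRIPLE_STOP_MOTIF + seq[pos + len(_TRIPLE_STOP_MOTIF):]


def generate_dataset(spec: CommunitySpec) -> SyntheticDataset:
    """Deterministically generate a full fixture from a community spec."""
    rng = np.random.default_rng(spec.seed)
    counts_per_order = spec.species_counts()

    # ---- traps and samples -------------------------------------------------
    traps = [
        TrapSite(
            trap_id=f"trap_{_alpha(i, 2)}",
            latitude=float(rng.uniform(*_LAT_RANGE)),
            longitude=float(rng.uniform(*_LON_RANGE)),
        )
        for i in range(spec.n_traps)
    ]
    samples: list[tuple[str, str, str]] = []  # (sample_id, trap_id, group)
    for t_i, trap in enumerate(traps):
        for s_i in range(spec.samples_per_trap):
            group = "yearone" if s_i < spec.samples_per_trap / 2 else "yeartwo"
            samples.append((f"s_{_alpha(t_i, 2)}_{_alpha(s_i, 2)}", trap.trap_id, group))
    n_samples = len(samples)
    n_plates = max(1, math.ceil(2 * n_samples / 84))
    n_negatives = 12 * n_plates

    # ---- species, OTUs, sequences -----------------------------------------
    species_ids: list[str] = []
    species_order: dict[str, str] = {}
    species_family: dict[str, str] = {}
    named: dict[str, str] = {}  # species id -> binomial
    unnamed_known: set[str] = set()  # unnamed but regionally known (not dark)
    species_to_otus: dict[str, list[str]] = {}
    annotations: dict[str, OtuAnnotation] = {}
    otu_ids: list[str] = []

    k = 0
    for o_i, n_species in enumerate(counts_per_order):
        order = f"Order{_alpha(o_i, 2)}"
        for s_i in range(n_species):
            sid = f"sp_{_alpha(k)}"
            species_ids.append(sid)
            species_order[sid] = order
            species_family[sid] = f"Fam{_alpha(o_i, 2)}{_alpha(s_i % 2, 1)}idae"
            is_named = rng.random() < spec.reference_coverage
            if is_named:
                named[sid] = f"Gen{_alpha(k)} species{_alpha(k)}"
            elif rng.random() < spec.checklist_coverage:
                unnamed_known.add(sid)
            n_otus = 1 + int(rng.poisson(spec.otu_inflation_mean - 1.0))
            members = []
            for v in range(n_otus):
                otu = f"otu_{_alpha(k)}{_alpha(v, 1)}"
                seq = _random_coding_sequence(rng)
                is_extra = v > 0
                if is_extra and rng.random() < spec.pseudogene_rate:
                    seq = _pseudogenize(seq, rng)
                tax = {
                    "phylum": "Arthropoda",
                    "class": "Insecta",
                    "order": order,
                    "family": species_family[sid],
                }
                # every OTU of a reference-covered species hits the same
                # barcode and receives the binomial; unnamed species
                # contribute their whole OTU cluster to the unnamed pool
                if is_named:
                    tax["genus"] = named[sid].split(" ")[0]
                    tax["species"] = named[sid]
                else:
                    tax["genus"] = ""
                    tax["species"] = ""
                annotations[otu] = OtuAnnotation(otu, seq, tax)
                members.append(otu)
                otu_ids.append(otu)
            species_to_otus[sid] = members
            k += 1

    # ---- occupancy and reads ----------------------------------------------
    presence: dict[str, list[str]] = {sid: [] for sid in species_ids}
    lib_ids: list[str] = []
    lib_rows: list[dict] = []
    counts = np.zeros((len(otu_ids), 2 * n_samples + n_negatives), dtype=np.int64)
    otu_index = {o: i for i, o in enumerate(otu_ids)}

    replicate_pairs: dict[str, tuple[str, str]] = {}
    for s_i, (sample_id, trap_id, group) in enumerate(samples):
        lib_a, lib_b = f"{sample_id}_A", f"{sample_id}_B"
        replicate_pairs[sample_id] = (lib_a, lib_b)
        for lib, role in ((lib_a, "A"), (lib_b, "B")):
            lib_ids.append(lib)
            lib_rows.append({"library_id": lib, "sample_id": sample_id,
                             "trap_id": trap_id, "group": group, "role": role})
    negative_ids = []
    for n_i in range(n_negatives):
        lib = f"neg_{_alpha(n_i, 2)}"
        negative_ids.append(lib)
        lib_ids.append(lib)
        lib_rows.append({"library_id": lib, "sample_id": "", "trap_id": "",
                         "group": "", "role": "negative"})
    col_index = {lib: j for j, lib in enumerate(lib_ids)}

    for sid in species_ids:
        occ = rng.random(n_samples) < spec.occupancy
        for s_i in np.nonzero(occ)[0]:
            sample_id = samples[s_i][0]
            presence[sid].append(sample_id)
            lib_a, lib_b = replicate_pairs[sample_id]
            for otu in species_to_otus[sid]:
                reads = max(1, int(round(rng.lognormal(spec.read_abundance_mu,
                                                       spec.read_abundance_sigma))))
                reads_b = max(1, int(round(rng.lognormal(spec.read_abundance_mu,
                                                         spec.read_abundance_sigma))))
                if rng.random() < spec.replicate_dropout:
                    if rng.random() < 0.5:
                        reads = 0
                    else:
                        reads_b = 0
                counts[otu_index[otu], col_index[lib_a]] = reads
                counts[otu_index[otu], col_index[lib_b]] = reads_b

    if spec.contamination_reads_mean > 0:
        for lib in negative_ids:
            counts[:, col_index[lib]] = rng.poisson(spec.contamination_reads_mean, size=len(otu_ids))

    table = OtuTable(
        pd.DataFrame(counts, index=otu_ids, columns=lib_ids),
        replicate_pairs,
        negative_ids,
    )

    # ---- occurrence records ------------------------------------------------
    trap_by_id = {t.trap_id: t for t in traps}
    sample_trap = {s: t for s, t, _ in samples}
    occ_rows = []
    for sid, binomial in named.items():
        occupied_traps = sorted({sample_trap[s] for s in presence[sid]})
        candidates = occupied_traps or [t.trap_id for t in traps]
        n_rec = int(rng.poisson(spec.occurrence_density))
        for _ in range(n_rec):
            trap = trap_by_id[candidates[int(rng.integers(0, len(candidates)))]]
            r = spec.occurrence_radius_km * math.sqrt(rng.random())
            theta = rng.random() * 2.0 * math.pi
            dlat = (r * math.cos(theta)) / _KM_PER_DEG_LAT
            dlon = (r * math.sin(theta)) / (_KM_PER_DEG_LAT * math.cos(math.radians(trap.latitude)))
            occ_rows.append({"species": binomial,
                             "latitude": trap.latitude + dlat,
                             "longitude": trap.longitude + dlon})
    occurrences = OccurrenceDB(pd.DataFrame(occ_rows, columns=["species", "latitude", "longitude"]))

    # ---- checklist / expert list / reference counts -----------------------
    checklist_names = {b for sid, b in named.items() if rng.random() < spec.checklist_coverage}
    synonyms = {}
    for b in sorted(checklist_names):
        if rng.random() < spec.synonym_rate:
            gen, epi = b.split(" ")
            synonyms[f"{gen} syn{epi}"] = b
    checklist = Checklist(checklist_names, synonyms)
    expert_list = Checklist(set(named.values()))

    reference_counts = {}
    for o_i in range(len(counts_per_order)):
        order = f"Order{_alpha(o_i, 2)}"
        members = [sid for sid in species_ids if species_order[sid] == order]
        n_named = sum(1 for sid in members if sid in named)
        n_known = n_named + sum(1 for sid in members if sid in unnamed_known)
        reference_counts[order] = ReferenceCounts(order, n_known, n_named)

    truth = GroundTruth(
        true_species_total=len(species_ids),
        true_named_species=len(named),
        true_dark_species=len(species_ids) - len(named) - len(unnamed_known),
        species_to_otus=species_to_otus,
        species_presence=presence,
        species_order=species_order,
        named_species=named,
    )
    return SyntheticDataset(table, annotations, traps, occurrences, checklist,
                            expert_list, reference_counts,
                            pd.DataFrame(lib_rows), truth, spec)


def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, str]:
    """Write the fixture file set consumed by the CLI readers.

    Returns a mapping of logical name -> path.  The ground-truth JSON is
    emitted for tests only and is not read by the pipeline.
    """
    from . import io as ocio

    return ocio.write_dataset(dataset, directory)
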