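"""OTU-table curation: replicate consensus, negative-control subtraction,
stop-codon screening, dataset splitting, binomial name hygiene and
species-level merging.

The fixed stage order is: merge_replicates -> subtract_negatives ->
screen_stop_codons -> split_datasets -> clean_species_names ->
merge_by_species.  Negative subtraction must see replicate-merged counts
because negatives are consensus-merged alongside the samples.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "OtuAnnotation",
    "SpeciesTable",
    "merge_replicates",
    "subtract_negatives",
    "screen_stop_codons",
    "has_stop_free_frame",
    "split_datasets",
    "clean_species_names",
    "is_clean_binomial",
    "merge_by_species",
    "drop_empty_otus",
    "ConfigurationError",
]

INVERTEBRATE_MITO_TABLE = 5

TAXONOMIC_RANKS = ("phylum", "class", "order", "family", "genus", "species")


class ConfigurationError(ValueError):
    """Raised when a table's replicate/negative structure is inconsistent."""


@dataclass
class OtuTable:
    """Read counts for OTUs (rows) across libraries (columns).

    ``counts`` is an integer DataFrame indexed by OTU id with one column
    per library.  ``replicate_pairs`` maps sample id -> (library A,
    library B).  ``negative_ids`` flags negative-control libraries.
    """

    counts: pd.DataFrame
    replicate_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    negative_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        paired = [lib for pair in self.replicate_pairs.values() for lib in pair]
        if len(set(paired)) != len(paired):
            raise ConfigurationError("a library appears in more than one replicate pair")
        known = set(paired) | set(self.negative_ids)
        cols = set(self.counts.columns)
        stray = cols - known
        if self.replicate_pairs and stray:
            raise ConfigurationError(f"libraries neither paired nor negative: {sorted(stray)}")
        missing = known - cols
        if missing:
            raise ConfigurationError(f"declared libraries missing from table: {sorted(missing)}")
        for sample, (a, b) in self.replicate_pairs.items():
            if a == b:
                raise ConfigurationError(f"sample {sample!r} pairs a library with itself")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.counts.columns if c not in set(self.negative_ids)]

    def copy(self) -> "OtuTable":
        return OtuTable(self.counts.copy(), dict(self.replicate_pairs), list(self.negative_ids))


@dataclass(frozen=True)
class OtuAnnotation:
    """Per-OTU taxonomy and nucleotide sequence."""

    otu_id: str
    sequence: str
    taxonomy: dict[str, str]

    def __post_init__(self):
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            logger.warning("OTU %s: non-nucleotide characters %s", self.otu_id, sorted(bad))
        if self.species and not self.taxonomy.get("genus"):
            raise ValueError(f"OTU {self.otu_id}: species set without genus")

    @property
    def species(self) -> str:
        return self.taxonomy.get("species", "") or ""

    @property
    def assignment_flag(self) -> str:
        return "named" if self.species else "unnamed"


@dataclass
class SpeciesTable:
    """Per-species summed counts plus the number of contributing OTUs."""

    counts: pd.DataFrame  # species x sample
    otus_per_species: dict[str, int]
    otu_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 1 for v in self.otus_per_species.values()):
            raise ValueError("otus_per_species must be >= 1")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)


def merge_replicates(table: OtuTable) -> OtuTable:
    """Collapse technical replicate pairs into one library per sample.

    A merged cell is ``a + b`` when both replicates are non-zero and 0
    otherwise.  Negatives without a pair pass through untouched.
    """
    if not table.replicate_pairs:
        raise ConfigurationError("no replicate pairs declared")
    neg = set(table.negative_ids)
    paired = {lib for pair in table.replicate_pairs.values() for lib in pair}
    unpaired_samples = [c for c in table.counts.columns if c not in paired and c not in neg]
    if unpaired_samples:
        raise ConfigurationError(f"unpaired sample libraries: {sorted(unpaired_samples)}")

    cols = {}
    for sample, (a, b) in table.replicate_pairs.items():
        va = table.counts[a].to_numpy()
        vb = table.counts[b].to_numpy()
        cols[sample] = np.where((va > 0) & (vb > 0), va + vb, 0)
    merged = pd.DataFrame(cols, index=table.counts.index)

    new_negatives = []
    for n in table.negative_ids:
        if n in paired:
            continue  # a paired negative was merged above under its sample id
        merged[n] = table.counts[n].to_numpy()
        new_negatives.append(n)
    for sample, (a, b) in table.replicate_pairs.items():
        if a in neg or b in neg:
            new_negatives.append(sample)
    return OtuTable(merged.astype(np.int64), {}, new_negatives)


def subtract_negatives(table: OtuTable) -> OtuTable:
    """Subtract, per OTU, the maximum negative-control read count from
    every sample; floor at zero and drop the negative libraries."""
    if not table.negative_ids:
        logger.warning("subtract_negatives: no negative controls; returning table unchanged")
        return table.copy()
    neg = table.counts[table.negative_ids]
    m = neg.max(axis=1).to_numpy()[:, None]
    samples = [c for c in table.counts.columns if c not in set(table.negative_ids)]
    adjusted = np.maximum(table.counts[samples].to_numpy() - m, 0)
    out = pd.DataFrame(adjusted, index=table.counts.index, columns=samples)
    return OtuTable(out.astype(np.int64), dict(table.replicate_pairs), [])


_STOP_CODONS = frozenset(CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE].stop_codons)


def _frame_has_stop(seq: str, offset: int, stop_codons: frozenset[str]) -> bool:
    for i in range(offset, len(seq) - 2, 3):
        if seq[i:i + 3] in stop_codons:
            return True
    return False


def has_stop_free_frame(sequence: str, genetic_code: int = INVERTEBRATE_MITO_TABLE,
                        check_reverse: bool = False) -> bool:
    """True iff at least one reading frame translates without a stop codon.

    Codons containing N (or any other ambiguity) never count as stops.
    """
    stops = frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)
    seq = sequence.upper()
    frames = [seq]
    if check_reverse:
        comp = str.maketrans("ACGTN", "TGCAN")
        frames.append(seq.translate(comp)[::-1])
    for s in frames:
        for offset in (0, 1, 2):
            if not _frame_has_stop(s, offset, stops):
                return True
    return False


def screen_stop_codons(annotations: list[OtuAnnotation],
                       genetic_code: int = INVERTEBRATE_MITO_TABLE,
                       check_reverse: bool = False) -> tuple[list[OtuAnnotation], list[OtuAnnotation]]:
    """Partition OTUs into (kept, removed) by the stop-codon screen."""
    kept, removed = [], []
    for ann in annotations:
        if not ann.sequence:
            raise ValueError(f"OTU {ann.otu_id}: empty sequence")
        if has_stop_free_frame(ann.sequence, genetic_code, check_reverse):
            kept.append(ann)
        else:
            removed.append(ann)
    logger.info("stop-codon screen: kept %d, removed %d", len(kept), len(removed))
    return kept, removed


def split_datasets(table: OtuTable, annotations: dict[str, OtuAnnotation],
                   insect_class: str = "Insecta") -> tuple[OtuTable, OtuTable]:
    """Split into (species-assigned dataset, insect dataset)."""
    missing = [o for o in table.otu_ids if o not in annotations]
    if missing:
        raise KeyError(f"OTUs without annotation: {missing}")
    named = [o for o in table.otu_ids if annotations[o].species]
    insect = [o for o in table.otu_ids if annotations[o].taxonomy.get("class", "") == insect_class]
    if not insect:
        logger.warning("split_datasets: no OTUs assigned to %s", insect_class)
    mk = lambda ids: OtuTable(table.counts.loc[ids], dict(table.replicate_pairs), list(table.negative_ids))
    return mk(named), mk(insect)


def is_clean_binomial(name: str, allow_hyphen: bool = False) -> bool:
    """``Genus epithet``: two single-space-separated tokens of letters only."""
    tokens = name.split(" ")
    if len(tokens) != 2:
        return False
    for tok in tokens:
        parts = tok.split("-") if allow_hyphen else [tok]
        if not all(p.isalpha() and p for p in parts):
            return False
    return True


def clean_species_names(names: list[str], allow_hyphen: bool = False) -> tuple[list[str], list[str]]:
    """Split names into (kept, dropped) under the binomial hygiene rule."""
    kept, dropped = [], []
    for n in names:
        (kept if is_clean_binomial(n, allow_hyphen) else dropped).append(n)
    return kept, dropped


def merge_by_species(table: OtuTable, annotations: dict[str, OtuAnnotation]) -> SpeciesTable:
    """Sum reads over all OTUs sharing a species name; record OTU counts."""
    members: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        sp = annotations[otu].species
        if sp:
            members.setdefault(sp, []).append(otu)
    if not members:
        return SpeciesTable(pd.DataFrame(columns=table.counts.columns), {}, {})
    rows = {sp: table.counts.loc[otus].sum(axis=0) for sp, otus in members.items()}
    counts = pd.DataFrame(rows).T.astype(np.int64)
    counts.index.name = "species"
    return SpeciesTable(counts, {sp: len(otus) for sp, otus in members.items()}, members)


def drop_empty_otus(table: OtuTable) -> OtuTable:
    """Remove OTU rows whose reads are zero in every library."""
    keep = table.counts.sum(axis=1) > 0
    return OtuTable(table.counts.loc[keep], dict(table.replicate_pairs), list(table.negative_ids))
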