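"""File formats: OTU table TSV with a library-map sidecar, FASTA
sequences, taxonomy TSV, trap/occurrence CSVs, checklist/expert TSVs,
reference-count TSV and the ground-truth JSON used by tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .darktaxa import ReferenceCounts
from .filtering import TAXONOMIC_RANKS, OtuAnnotation, OtuTable
from .validation import Checklist, OccurrenceDB, TrapSite

__all__ = [
    "FormatError",
    "Dataset",
    "read_otu_table",
    "write_otu_table",
    "read_annotations",
    "write_annotations",
    "read_traps",
    "write_traps",
    "read_occurrences",
    "write_occurrences",
    "read_name_list",
    "write_name_list",
    "read_reference_counts",
    "write_reference_counts",
    "read_inputs",
    "write_dataset",
    "FIXTURE_FILES",
]

FIXTURE_FILES = {
    "otu_table": "otu_table.tsv",
    "library_map": "libraries.tsv",
    "fasta": "otus.fasta",
    "taxonomy": "taxonomy.tsv",
    "traps": "traps.csv",
    "occurrences": "occurrences.csv",
    "checklist": "checklist.tsv",
    "expert": "expert.tsv",
    "reference_counts": "reference_counts.tsv",
    "ground_truth": "ground_truth.json",
}


class FormatError(ValueError):
    def __init__(self, path, message: str, line: int | None = None, column: str | None = None):
        loc = f"{path}"
        if line is not None:
            loc += f":{line}"
        if column is not None:
            loc += f" (column {column!r})"
        super().__init__(f"{loc}: {message}")
        self.path, self.line, self.column = str(path), line, column


@dataclass
class Dataset:
    """Everything the pipeline consumes, cross-validated."""

    table: OtuTable
    annotations: dict[str, OtuAnnotation]
    traps: list[TrapSite]
    occurrences: OccurrenceDB
    checklist: Checklist
    expert_list: Checklist
    reference_counts: dict[str, ReferenceCounts]
    library_map: pd.DataFrame


# ---------------------------------------------------------------- OTU table

def read_otu_table(table_path, library_map_path) -> tuple[OtuTable, pd.DataFrame]:
    try:
        counts = pd.read_csv(table_path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(table_path, f"cannot parse OTU table: {exc}") from exc
    if counts.index.name != "otu_id":
        raise FormatError(table_path, f"first column must be 'otu_id', got {counts.index.name!r}", line=1)
    if counts.isna().any().any() or not all(np.issubdtype(d, np.integer) for d in counts.dtypes):
        raise FormatError(table_path, "counts must be integers with no missing cells")

    lib_map = pd.read_csv(library_map_path, sep="\t", dtype=str).fillna("")
    required = {"library_id", "sample_id", "trap_id", "group", "role"}
    if not required.issubset(lib_map.columns):
        raise FormatError(library_map_path, f"need columns {sorted(required)}", line=1)
    pairs: dict[str, tuple[str, str]] = {}
    negatives: list[str] = []
    halves: dict[str, dict[str, str]] = {}
    for i, row in lib_map.iterrows():
        role = row["role"]
        if role == "negative":
            negatives.append(row["library_id"])
        elif role in ("A", "B"):
            halves.setdefault(row["sample_id"], {})[role] = row["library_id"]
        else:
            raise FormatError(library_map_path, f"bad role {role!r}", line=i + 2, column="role")
    for sample, h in halves.items():
        if set(h) != {"A", "B"}:
            raise FormatError(library_map_path, f"sample {sample!r} lacks both replicates")
        pairs[sample] = (h["A"], h["B"])
    table = OtuTable(counts.astype(np.int64), pairs, negatives)
    return table, lib_map


def write_otu_table(table: OtuTable, table_path, library_map: pd.DataFrame, library_map_path):
    out = table.counts.copy()
    out.index.name = "otu_id"
    out.to_csv(table_path, sep="\t")
    library_map.to_csv(library_map_path, sep="\t", index=False)


# ------------------------------------------------------------- annotations

def read_annotations(fasta_path, taxonomy_path) -> dict[str, OtuAnnotation]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
    if "otu_id" not in tax.columns:
        raise FormatError(taxonomy_path, "need an 'otu_id' column", line=1)
    missing_ranks = [r for r in TAXONOMIC_RANKS if r not in tax.columns]
    if missing_ranks:
        raise FormatError(taxonomy_path, f"missing rank columns {missing_ranks}", line=1)
    annotations = {}
    for i, row in tax.iterrows():
        otu = row["otu_id"]
        if otu not in seqs:
            raise FormatError(taxonomy_path, f"OTU {otu!r} has no FASTA sequence", line=i + 2)
        annotations[otu] = OtuAnnotation(otu, seqs[otu], {r: row[r] for r in TAXONOMIC_RANKS})
    extra = set(seqs) - set(annotations)
    if extra:
        raise FormatError(fasta_path, f"sequences without taxonomy rows: {sorted(extra)[:5]}")
    return annotations


def write_annotations(annotations: dict[str, OtuAnnotation], fasta_path, taxonomy_path):
    records = [SeqRecord(Seq(a.sequence), id=a.otu_id, description="") for a in annotations.values()]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [{"otu_id": a.otu_id, **{r: a.taxonomy.get(r, "") for r in TAXONOMIC_RANKS}}
            for a in annotations.values()]
    pd.DataFrame(rows).to_csv(taxonomy_path, sep="\t", index=False)


# -------------------------------------------------------- geographic files

def read_traps(path) -> list[TrapSite]:
    df = pd.read_csv(path)
    for col in ("trap_id", "latitude", "longitude"):
        if col not in df.columns:
            raise FormatError(path, f"need column {col!r}", line=1, column=col)
    return [TrapSite(str(r.trap_id), float(r.latitude), float(r.longitude)) for r in df.itertuples()]


def write_traps(traps: list[TrapSite], path):
    pd.DataFrame([{"trap_id": t.trap_id, "latitude": t.latitude, "longitude": t.longitude}
                  for t in traps]).to_csv(path, index=False)


def read_occurrences(path) -> OccurrenceDB:
    df = pd.read_csv(path)
    if df.empty and not {"species", "latitude", "longitude"}.issubset(df.columns):
        df = pd.DataFrame(columns=["species", "latitude", "longitude"])
    try:
        return OccurrenceDB(df)
    except ValueError as exc:
        raise FormatError(path, str(exc)) from exc


def write_occurrences(db: OccurrenceDB, path):
    db.records.to_csv(path, index=False)


# ------------------------------------------------------------- name lists

def read_name_list(path) -> Checklist:
    """TSV with columns ``name`` and optional ``canonical`` (synonym target)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "name" not in df.columns:
        raise FormatError(path, "need a 'name' column", line=1, column="name")
    canonical, synonyms = set(), {}
    for r in df.itertuples():
        target = getattr(r, "canonical", "") if "canonical" in df.columns else ""
        if target:
            synonyms[r.name] = target
        else:
            canonical.add(r.name)
    try:
        return Checklist(canonical, synonyms)
    except ValueError as exc:
        raise FormatError(path, str(exc)) from exc


def write_name_list(checklist: Checklist, path):
    rows = [{"name": n, "canonical": ""} for n in sorted(checklist.canonical)]
    rows += [{"name": s, "canonical": c} for s, c in sorted(checklist.synonyms.items())]
    pd.DataFrame(rows, columns=["name", "canonical"]).to_csv(path, sep="\t", index=False)


def read_reference_counts(path) -> dict[str, ReferenceCounts]:
    df = pd.read_csv(path, sep="\t")
    for col in ("taxon", "known_species", "barcoded_species"):
        if col not in df.columns:
            raise FormatError(path, f"need column {col!r}", line=1, column=col)
    return {str(r.taxon): ReferenceCounts(str(r.taxon), int(r.known_species), int(r.barcoded_species))
            for r in df.itertuples()}


def write_reference_counts(reference: dict[str, ReferenceCounts], path):
    pd.DataFrame([{"taxon": r.taxon, "known_species": r.known_species,
                   "barcoded_species": r.barcoded_species}
                  for r in reference.values()]).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ full dataset

def read_inputs(directory, files: dict[str, str] | None = None) -> Dataset:
    """Load and cross-validate a fixture directory."""
    d = Path(directory)
    f = {**FIXTURE_FILES, **(files or {})}
    table, lib_map = read_otu_table(d / f["otu_table"], d / f["library_map"])
    annotations = read_annotations(d / f["fasta"], d / f["taxonomy"])
    traps = read_traps(d / f["traps"])
    occurrences = read_occurrences(d / f["occurrences"])
    checklist = read_name_list(d / f["checklist"])
    expert = read_name_list(d / f["expert"])
    reference = read_reference_counts(d / f["reference_counts"])

    missing = [o for o in table.otu_ids if o not in annotations]
    if missing:
        raise FormatError(d / f["otu_table"], f"OTUs without annotation: {missing[:10]}")
    trap_ids = {t.trap_id for t in traps}
    bad_traps = sorted(set(lib_map.loc[lib_map["trap_id"] != "", "trap_id"]) - trap_ids)
    if bad_traps:
        raise FormatError(d / f["library_map"], f"unknown trap ids: {bad_traps}")
    return Dataset(table, annotations, traps, occurrences, checklist, expert, reference, lib_map)


def write_dataset(dataset, directory) -> dict[str, str]:
    """Write a SyntheticDataset as the fixture file set (plus truth JSON)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    f = FIXTURE_FILES
    write_otu_table(dataset.table, d / f["otu_table"], dataset.library_map, d / f["library_map"])
    write_annotations(dataset.annotations, d / f["fasta"], d / f["taxonomy"])
    write_traps(dataset.traps, d / f["traps"])
    write_occurrences(dataset.occurrences, d / f["occurrences"])
    write_name_list(dataset.checklist, d / f["checklist"])
    write_name_list(dataset.expert_list, d / f["expert"])
    write_reference_counts(dataset.reference_counts, d / f["reference_counts"])
    truth = dataset.truth
    (d / f["ground_truth"]).write_text(json.dumps({
        "true_species_total": truth.true_species_total,
        "true_named_species": truth.true_named_species,
        "true_dark_species": truth.true_dark_species,
        "species_to_otus": truth.species_to_otus,
        "species_presence": truth.species_presence,
        "species_order": truth.species_order,
        "named_species": truth.named_species,
    }, indent=1, sort_keys=True))
    return {k: str(d / v) for k, v in f.items()}
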