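"""End-to-end orchestration and the summary report.

Stage order: replicate merge -> negative subtraction -> empty-OTU drop
-> stop-codon screen -> dataset split -> name hygiene -> species merge
-> validation -> rarefaction -> plausible/dark-taxa estimation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import darktaxa, filtering, richness, validation
from .io import Dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SummaryReport", "PipelineResult", "run_pipeline", "year_overlap", "write_outputs"]


class RunConfig(BaseModel):
    """Settings of one reproducible run (paths are handled by the CLI)."""

    radius_km: float = Field(default=200.0, gt=0)
    min_criteria: int = Field(default=2, ge=1)
    step_fraction: float = Field(default=0.001, gt=0, le=1)
    iterations: int = Field(default=50, ge=1)
    sample_step: int = Field(default=5, ge=1)
    level: str = "order"
    exclusions: list[str] = ["Orthoptera"]
    plausible_mode: str = "unnamed"
    seed: int = 0
    run_read_rarefaction: bool = True
    run_sample_rarefaction: bool = True
    check_reverse_frames: bool = False
    allow_hyphenated_names: bool = False


@dataclass
class SummaryReport:
    """Table-1-style counts, pooled and per year-group."""

    raw_otus: int
    insect_otus: int
    named_species: int
    validated_per_criterion: dict[str, int]
    validated_species: int
    plausible_species: int
    plausible_species_family: int
    total_species: int
    per_group: dict[str, dict[str, int]] = field(default_factory=dict)
    otu_overlap: dict | None = None
    species_overlap: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.validated_species > self.named_species:
            raise ValueError("validated cannot exceed named species")
        if self.total_species != self.validated_species + self.plausible_species:
            raise ValueError("total != validated + plausible")

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "raw_otus": self.raw_otus,
            "insect_otus": self.insect_otus,
            "named_species": self.named_species,
            "validated_per_criterion": self.validated_per_criterion,
            "validated_species": self.validated_species,
            "plausible_species": self.plausible_species,
            "plausible_species_family_level": self.plausible_species_family,
            "total_species": self.total_species,
            "per_group": self.per_group,
            "otu_overlap": self.otu_overlap,
            "species_overlap": self.species_overlap,
        }


@dataclass
class PipelineResult:
    report: SummaryReport
    species_table: filtering.SpeciesTable
    validation_results: list[validation.ValidationResult]
    agreement: pd.DataFrame
    order_estimates: list[darktaxa.OrderEstimate]
    family_estimates: list[darktaxa.OrderEstimate]
    stage_log: list[dict]
    read_curves: dict[str, richness.RichnessCurve] = field(default_factory=dict)
    doubling_gains: dict[str, float] = field(default_factory=dict)
    sample_curve: richness.RichnessCurve | None = None


def year_overlap(sets_by_group: dict[str, set]) -> dict:
    """Shared/unique counts and percentages of the union across groups."""
    if len(sets_by_group) < 2:
        raise ValueError("need >= 2 groups")
    groups = list(sets_by_group)
    shared = set.intersection(*sets_by_group.values())
    union = set.union(*sets_by_group.values())
    pct = (lambda n: 100.0 * n / len(union)) if union else (lambda n: 0.0)
    return {
        "groups": groups,
        "union": len(union),
        "shared": len(shared),
        "shared_pct": pct(len(shared)),
        "unique": {g: len(s - set.union(*(o for h, o in sets_by_group.items() if h != g)))
                   for g, s in sets_by_group.items()},
    }


def run_pipeline(dataset: Dataset, config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    log: list[dict] = []

    def stage(name, n_otus_in, n_otus_out, reads_in, reads_out):
        entry = {"stage": name, "otus_in": int(n_otus_in), "otus_out": int(n_otus_out),
                 "reads_in": int(reads_in), "reads_out": int(reads_out)}
        log.append(entry)
        logger.info("stage %(stage)s: OTUs %(otus_in)d -> %(otus_out)d, reads %(reads_in)d -> %(reads_out)d", entry)

    table = dataset.table
    raw_otus = len(table.otu_ids)
    reads0 = int(table.counts.to_numpy().sum())

    merged = filtering.merge_replicates(table)
    stage("merge_replicates", raw_otus, len(merged.otu_ids), reads0, merged.counts.to_numpy().sum())

    cleaned = filtering.subtract_negatives(merged)
    cleaned = filtering.drop_empty_otus(cleaned)
    stage("subtract_negatives", len(merged.otu_ids), len(cleaned.otu_ids),
          merged.counts.to_numpy().sum(), cleaned.counts.to_numpy().sum())

    anns = [dataset.annotations[o] for o in cleaned.otu_ids]
    kept, removed = filtering.screen_stop_codons(anns, check_reverse=config.check_reverse_frames)
    keep_ids = [a.otu_id for a in kept]
    screened = filtering.OtuTable(cleaned.counts.loc[keep_ids], {}, [])
    stage("stop_codon_screen", len(cleaned.otu_ids), len(keep_ids),
          cleaned.counts.to_numpy().sum(), screened.counts.to_numpy().sum())

    named_table, insect_table = filtering.split_datasets(screened, dataset.annotations)
    stage("split_species_dataset", len(screened.otu_ids), len(named_table.otu_ids),
          screened.counts.to_numpy().sum(), named_table.counts.to_numpy().sum())
    stage("split_insect_dataset", len(screened.otu_ids), len(insect_table.otu_ids),
          screened.counts.to_numpy().sum(), insect_table.counts.to_numpy().sum())

    all_names = sorted({dataset.annotations[o].species for o in named_table.otu_ids})
    kept_names, dropped_names = filtering.clean_species_names(all_names, config.allow_hyphenated_names)
    clean_set = set(kept_names)
    clean_otu_ids = [o for o in named_table.otu_ids if dataset.annotations[o].species in clean_set]
    clean_table = filtering.OtuTable(named_table.counts.loc[clean_otu_ids], {}, [])
    stage("name_hygiene", len(named_table.otu_ids), len(clean_otu_ids),
          named_table.counts.to_numpy().sum(), clean_table.counts.to_numpy().sum())

    species_table = filtering.merge_by_species(clean_table, dataset.annotations)

    # detections: species -> traps with >= 1 read in any of the trap's samples
    lib_map = dataset.library_map
    sample_trap = {r.sample_id: r.trap_id for r in lib_map.itertuples() if r.role in ("A", "B")}
    trap_by_id = {t.trap_id: t for t in dataset.traps}
    detections: dict[str, list[validation.TrapSite]] = {}
    present = species_table.counts > 0
    for sp in species_table.species:
        traps = sorted({sample_trap[s] for s in species_table.counts.columns if present.loc[sp, s] and s in sample_trap})
        detections[sp] = [trap_by_id[t] for t in traps]

    cfg = validation.ValidationConfig(radius_km=config.radius_km, min_criteria=config.min_criteria)
    results = validation.validate_all(species_table.species, detections, dataset.occurrences,
                                      dataset.checklist, dataset.expert_list, cfg,
                                      synonyms=dataset.checklist.synonyms)
    agreement = validation.agreement_matrix(results) if results else pd.DataFrame()
    validated = {r.species for r in results if r.validated}
    per_criterion = {c: sum(1 for r in results if r.criteria.get(c)) for c in validation.CRITERIA}

    read_curves: dict[str, richness.RichnessCurve] = {}
    gains: dict[str, float] = {}
    if config.run_read_rarefaction:
        for i, sample in enumerate(insect_table.counts.columns):
            col = insect_table.counts[sample].to_numpy()
            if col.sum() < 10:
                continue
            curve = richness.rarefy_reads(col, config.step_fraction, config.iterations,
                                          seed=config.seed + i)
            fit = richness.fit_mm(curve)
            read_curves[sample] = curve
            gains[sample] = richness.doubling_gain(fit, float(col.sum()))

    sample_curve = None
    if config.run_sample_rarefaction and insect_table.counts.shape[1] >= config.sample_step:
        incidence = richness.IncidenceMatrix(insect_table.counts.to_numpy() > 0)
        sample_curve = richness.rarefy_samples(incidence, config.sample_step,
                                               config.iterations, seed=config.seed)

    exclusions = set(config.exclusions)
    order_est = darktaxa.estimate_orders(species_table, dataset.annotations, validated,
                                         insect_table.otu_ids, dataset.reference_counts,
                                         level="order", exclusions=exclusions,
                                         mode=config.plausible_mode)
    family_est = darktaxa.estimate_orders(species_table, dataset.annotations, validated,
                                          insect_table.otu_ids, dataset.reference_counts,
                                          level="family", exclusions=exclusions,
                                          mode=config.plausible_mode)
    plaus_order = sum(e.n_plausible for e in order_est)
    plaus_family = sum(e.n_plausible for e in family_est)
    plausible = plaus_order if config.level == "order" else plaus_family
    total = darktaxa.total_species(len(validated), [plausible])

    # per year-group accounting on the filtered insect table
    groups = sorted({g for g in lib_map["group"] if g})
    per_group: dict[str, dict[str, int]] = {}
    otu_sets: dict[str, set] = {}
    species_sets: dict[str, set] = {}
    for g in groups:
        g_samples = [r.sample_id for r in lib_map.itertuples() if r.group == g and r.role == "A"]
        g_samples = [s for s in g_samples if s in insect_table.counts.columns]
        if not g_samples:
            continue
        otu_sets[g] = set(insect_table.counts.index[(insect_table.counts[g_samples] > 0).any(axis=1)])
        sp_present = set(species_table.counts.index[(species_table.counts[g_samples] > 0).any(axis=1)])
        species_sets[g] = sp_present & validated
        per_group[g] = {"insect_otus": len(otu_sets[g]), "validated_species": len(species_sets[g])}

    otu_ov = year_overlap(otu_sets) if len(otu_sets) >= 2 else None
    sp_ov = year_overlap(species_sets) if len(species_sets) >= 2 else None

    report = SummaryReport(
        raw_otus=raw_otus,
        insect_otus=len(insect_table.otu_ids),
        named_species=len(species_table.species),
        validated_per_criterion=per_criterion,
        validated_species=len(validated),
        plausible_species=plausible,
        plausible_species_family=plaus_family,
        total_species=total,
        per_group=per_group,
        otu_overlap=otu_ov,
        species_overlap=sp_ov,
        seed=config.seed,
    )
    return PipelineResult(report, species_table, results, agreement, order_est, family_est,
                          log, read_curves, gains, sample_curve)


def write_outputs(result: PipelineResult, outdir, config: RunConfig | None = None):
    """Serialize the report and stage artifacts as TSV + JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()

    payload = {"config": config.model_dump(), "report": result.report.as_dict()}
    (out / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    pd.DataFrame(result.stage_log).to_csv(out / "filtering_log.tsv", sep="\t", index=False)

    rows = [{"species": r.species, **{c: r.criteria.get(c, "") for c in validation.CRITERIA},
             "validated": r.validated,
             "n_occurrence_records_inside": r.evidence.get("n_occurrence_records_inside", "")}
            for r in result.validation_results]
    pd.DataFrame(rows).to_csv(out / "validation.tsv", sep="\t", index=False)
    if not result.agreement.empty:
        result.agreement.to_csv(out / "agreement_matrix.tsv", sep="\t")

    for name, ests in (("order_estimates.tsv", result.order_estimates),
                       ("family_estimates.tsv", result.family_estimates)):
        pd.DataFrame([vars(e) for e in ests]).to_csv(out / name, sep="\t", index=False)

    if result.sample_curve is not None:
        c = result.sample_curve
        pd.DataFrame({"effort": c.effort, "mean_richness": c.mean_richness,
                      "sd_richness": c.sd_richness,
                      "estimator_mean": c.estimator_mean, "estimator_sd": c.estimator_sd,
                      "n_iter": c.iterations}).to_csv(out / "sample_rarefaction.tsv", sep="\t", index=False)
    if result.doubling_gains:
        pd.DataFrame([{"sample": s, "doubling_gain": g,
                       "sufficient": g < richness.SUFFICIENCY_THRESHOLD}
                      for s, g in result.doubling_gains.items()]).to_csv(
            out / "sequencing_sufficiency.tsv", sep="\t", index=False)
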