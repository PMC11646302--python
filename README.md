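# otucurate

Post-clustering curation and analysis for DNA-metabarcoding OTU tables from
large-scale Malaise-trap insect monitoring. The package takes a raw OTU read
table (with technical replicates and negative controls), per-OTU taxonomy and
sequences, trap coordinates, occurrence records and regional species lists, and
produces:

- **Filtering** — technical-replicate consensus (reads kept only when present in
  both replicates), per-OTU subtraction of the maximum negative-control reads,
  stop-codon screening under the invertebrate mitochondrial code, splitting into
  species-assigned and insect datasets, binomial name hygiene, and species-level
  merging.
- **Validation** — three criteria per named species (expert-accepted list,
  regional checklist with synonym resolution, and occurrence records inside a
  200-km buffered convex hull around the detection traps), combined by a
  two-of-three consensus, plus pairwise agreement statistics.
- **Richness** — read-based rarefaction (exact without-replacement sampling in
  0.1 % increments, 50 iterations per step), a Michaelis–Menten fit with a
  <5 %-gain-on-doubling sufficiency rule, and sample-based rarefaction with the
  Chao2 / iChao2 incidence estimators.
- **Dark taxa** — per-order (and per-family) mean OTUs per validated species,
  normalization of unnamed OTU counts into "plausible" species (with taxon
  exclusions, Orthoptera by default), and a split into species lacking a
  reference barcode vs. potential dark taxa using regional known/barcoded
  counts.
- **Cost model** — cent-exact aggregation of a per-step cost/time ledger
  (a reference 1815-sample workflow ledger ships with the package).
- **Synthetic data** — a seeded generator producing ground-truthed fixtures with
  the full structure above (duplicate libraries, negatives with contamination,
  OTU inflation with pseudogenes, partial reference coverage, spatially
  clustered occurrences), so the whole pipeline is testable offline.

## CLI

```sh
otucurate simulate fixtures/ --seed 1            # write a synthetic fixture set
otucurate filter --inputs fixtures/ --out out/   # filtering stages + species table
otucurate validate --inputs fixtures/ --out out/ --radius-km 200 --min-criteria 2
otucurate rarefy --inputs fixtures/ --out out/ --step-fraction 0.001 --iterations 50
otucurate estimate-dark --inputs fixtures/ --out out/ --level order --exclude-taxon Orthoptera
otucurate cost                                   # aggregate the reference cost ledger
otucurate run --inputs fixtures/ --out out/ --seed 1   # end-to-end summary report
```

Input formats: OTU table TSV (first column `otu_id`, one column per library)
with a `libraries.tsv` sidecar (`library_id`, `sample_id`, `trap_id`, `group`,
`role` ∈ A/B/negative), FASTA sequences, taxonomy TSV (ranks phylum…species),
traps/occurrences CSV (WGS84 decimal degrees), checklist/expert TSV
(`name`, optional `canonical` for synonyms) and a per-taxon
`reference_counts.tsv` (`taxon`, `known_species`, `barcoded_species`). Reports
are written as TSV + JSON with the seed and configuration echoed.

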