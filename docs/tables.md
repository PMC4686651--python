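# Table dialects

TSV (tab-separated, header row) is the canonical interchange format for
every table in the pipeline. VCF ingestion maps onto the variant dialect
(see `clonearch.io.read_vcf_variants`). Booleans serialise as
`True`/`False`; coordinates are 1-based inclusive except BED exports.

## Variant table (`read_variant_table` / `write_variant_table`)

Required columns:

| column | type | meaning |
|---|---|---|
| sample_id | str | sample the observation comes from |
| mutation_id | str | stable mutation identifier |
| chrom | str | chromosome |
| pos | int | 1-based position |
| ref / alt | str | alleles |
| alt_reads | int | reads supporting the mutant allele |
| total_reads | int | total depth at the locus |

Optional columns (defaults applied when absent): `source_class`
(primary_CD34, HEC, LTC, CFC, compartment, normal_skin, normal_tcell,
WGA-control), `replicate_id`, `experiment_id`, `gene`, `fwd_alt_reads` /
`rev_alt_reads` (must sum to `alt_reads` when non-zero),
`mean_align_score`, `mean_base_quality`, `flank_left` / `flank_right`
(>=5 bases each side; required for WGA records), `wga`, `pop_known`,
`pop_af`, `dup_region`, `known_mutation`, `bias_flag`.

Simulator output adds a `true_mab` ground-truth column that analysis
operations never read.

Row invariants enforced on read: `0 <= alt_reads <= total_reads`,
`pos >= 1`, strand counts sum to `alt_reads`. Violating rows go to the
rejection report with a reason; accepted + rejected = input.

## Colony read table (`read_colony_table`)

`colony_id`, `mutation_id`, `alt_reads`, `total_reads` — one row per
colony per panel mutation. Duplicate (colony, mutation) pairs are an
error; missing panel mutations become no-calls.

## Genotype matrix export

Colonies x mutations grid of entry codes `M` (mutant), `W` (wild type),
`N` (no call), with `colony_id` as the index column. A long-format audit
table (`ColonyGenotypeMatrix.long_audit`) carries the per-entry alt
fraction and depth.

## SNP table for LOH (`read_snp_table`)

`chrom`, `pos`, `alt_fraction`, `depth`, `pop_known`, `pop_af`,
`somatic`, `dup_region`; optional `normal_fraction` (paired-normal allele
fraction used for the heterozygosity check).

## Other outputs

* MAB table: `mutation_id`, `sample_id`, `mab`, `ci_low`, `ci_high`,
  `n_replicates`, `detected`.
* Trajectory table: `mutation_id`, `primary_mab`, `followup_mab`,
  `category` (same / changed_lt2fold / decreased_ge2fold /
  increased_ge2fold / not_detected), `note`.
* Clone tree: JSON with `clones` (full mutation sets), `parents`,
  `edge_mutations`, per-clone `meta` (colony counts).
* LOH segments: BED (0-based half-open) with the affected-cell fraction
  in the score column.
* Run manifest: JSON with tool version, config snapshot, seed, per-stage
  record counts and output SHA-256 digests.
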