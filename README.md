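# clonearch

Clonal-architecture analysis for myeloid neoplasms — built around the kind
of study that asks where in the haematopoietic hierarchy a founder mutation
(such as a heterozygous *SF3B1* splicing-factor mutation in MDS with ring
sideroblasts) arises, how its subclones are organised, and how they evolve
across sorted compartments, xenografts and sequential patient samples.

It is a library first: the importable API does the work, `examples/` shows
one short narrative script per capability, and a thin `clonearch` CLI
wraps the same functions for shell use.

## What it computes

* **Somatic-variant filtering** (`clonearch.filtering`) — the ordered
  cascade used on paired tumour/normal calls: read-level exclusions
  (alignment score < 10, base quality < 15, fold strand bias > 10), the
  somatic rules (Fisher exact p < 0.01 by exact hypergeometric
  enumeration, ≥ 3 supporting reads, normal contamination < 20% skin /
  < 50% T cell, tumour burden > 5%, population allele frequency,
  duplicated regions), whole-genome-amplification artifact filters
  (flanking homopolymer runs ≥ 5, control-WGA sets, bias flags), and the
  xenograft concordance rules across engraftment experiments. Every record
  gets a verdict naming the rules that fired.
* **Mutant allele burden** (`clonearch.quantify`) — MAB = alt/total with
  Wilson intervals; replicate pooling by unweighted averaging; the
  heterozygous conversion *prevalence = min(2·MAB, 1)* (a MAB of 50%
  means 100% of cells carry the mutation); the detection floor
  max(1%, min_alt_reads/coverage), equal to 1% at the 800× reference
  amplicon coverage; compartment-maintenance t-tests.
* **Colony genotyping** (`clonearch.colonies`) — per-colony calls
  (mutant when > 30% of reads carry the mutant allele; no-call below the
  depth floor) and the colonies × mutations matrix.
* **Clone trees** (`clonearch.architecture`) — subclone census,
  the directed three-gamete tree-compatibility test, tree reconstruction
  over observed signatures by set containment, founder identification and
  mutual-exclusivity detection, and a burden-based mutation hierarchy.
* **Clonal dynamics** (`clonearch.dynamics`) — five-category MAB
  trajectories (same / <2-fold / ≥2-fold down / ≥2-fold up / not
  detected), exact shift tests, xenograft-vs-patient recapitulation
  scores, and lesion acquisition order across time points.
* **LOH scanning** (`clonearch.loh`) — sliding-window segmentation of
  germline-SNP allele-fraction profiles with the affected-cell fraction
  recovered from the deviation model d = f/(2(2−f)).
* **Synthetic data** (`clonearch.simulate`) — clone trees, compartment
  mixtures, 800× amplicon counts, single-founder colonies and WGA
  artifacts with ground-truth side channels, so every stage above is
  testable without patient data.

See `docs/methods.md` for the model, assumptions and parameter choices,
and `docs/tables.md` for the TSV dialects.

## Worked example

`examples/03_colony_architecture.py` builds a 30-colony cohort with one
founder mutation and two mutually exclusive daughter subclones, and prints:

```
SF3B1-mutant colonies: 87% of 30 evaluable
tree-compatible: True
distinct subclones: 4 (+4 wild-type colonies)

Inferred clone tree:
WT [wild type]
  SF3B1 [SF3B1]
    DNMT3A+SF3B1 [DNMT3A]
      DNMT3A+SF3B1+TLL2 [TLL2]
    JAK2+SF3B1 [JAK2]

founder mutation(s): ['SF3B1']
mutually exclusive pairs: [('JAK2', 'DNMT3A'), ('JAK2', 'TLL2')]
```

The founder labels the edge out of the wild-type root because it is the
one mutation present in every mutant colony; JAK2 and DNMT3A sit on
sibling branches — they never co-occur in a colony, the signature of
branching multi-clonal evolution. The other examples cover simulation
(`01`), filtering (`02`), trajectory tracking and recapitulation (`04`)
and LOH scanning (`05`); each prints the numbers it computes and one line
on what they mean.

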