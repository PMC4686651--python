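# Methods

`clonearch` implements the analysis stack used to dissect the clonal
architecture of splicing-factor-mutant myelodysplastic syndromes from
targeted amplicon and exome-style allele counts: filtering somatic variants
out of paired tumour/normal calls (including whole-genome-amplification
artifacts), quantifying mutant allele burdens (MAB) across sorted
haematopoietic compartments, calling single-colony genotypes and
reconstructing the clone tree, tracking clonal dynamics across xenografts
and sequential samples, and scanning for loss of heterozygosity. A
synthetic clone simulator stands in for patient data throughout.

## Model and assumptions

**Mutations are heterozygous point mutations under infinite sites.** Every
somatic mutation is assumed heterozygous (true of all splicing-factor
mutations reported in this disease setting) and acquired exactly once on
one edge of a rooted clone tree whose root is the wild-type clone.
Consequences used everywhere:

* MAB = (fraction of cells carrying the mutation) / 2, so cellular
  prevalence is `min(2·MAB, 1)`; `2·MAB > 1` is flagged as a possible
  copy-number event rather than silently clipped.
* Mutation sets along any root-to-leaf path are nested, and a colony
  genotype matrix is consistent with some clone tree exactly when no
  mutation pair shows all three patterns {A only, B only, A and B} across
  colonies (the directed two-character / three-gamete test with known
  all-zero ancestral state).

**Colonies are single-founder samples.** A colony-forming-cell colony grows
from one cell, so all its cells share the founder's genotype and carried
mutations sequence at an expected 50% read fraction. Founders are sampled
i.i.d. from compartment clone fractions — no plating bias is modelled.

**Tree inference never invents unobserved clones.** The inferred tree is
over observed genotype signatures ordered by strict set containment; the
parent of a signature is its largest observed proper subset (the wild type
if none). An edge may therefore gain several mutations at once when colony
data cannot resolve their order. For a tree-compatible matrix the parent is
provably unique: two incomparable maximal proper subsets would themselves
form a three-gamete violation.

## Filter cascade

Filters run in a fixed order — read-level, somatic, WGA-artifact (WGA
records only), xenograft concordance (engrafted-cell records only) — and
each record's verdict lists every rule that fired, so tightening any
threshold can only shrink the passed set (monotonicity is a tested
property). Comparison directions follow the published operating point
exactly as printed: somatic Fisher p `< 0.01`, supporting reads `>= 3`,
normal contamination `< 20%` (skin) / `< 50%` (T cells), tumour burden
`> 5%`, alignment score `< 10` / base quality `< 15` / fold strand bias
`> 10` exclude reads, homopolymer runs `>= 5`, population allele frequency
`> 0.001` excludes known variants.

Choices where the published description is underspecified:

* **Fold strand bias** is undefined at source; defined here as
  `max(fwd_alt, rev_alt) / max(1, min(fwd_alt, rev_alt))` — simple,
  symmetric, and on the same ">10" scale.
* **Normal contamination**: the source sentence is garbled ("at <20% … at
  <20% of the paired tumour tissue"); implemented as skin-paired normals
  <20% and T-cell-paired normals <50%, with the trailing clause ignored.
  Both thresholds are config values.
* **Positional / read-length bias** of WGA calls is consumed as a
  precomputed boolean flag; no formula is published and raw reads are out
  of scope.
* **Homopolymer rule**: a run of >=5 identical bases immediately adjacent
  to the variant on either flank triggers the filter; runs interrupted by
  the variant base itself are not joined across it.
* **Xenograft concordance**: with non-WGA engrafted-cell data, a candidate
  passes when seen in >1 engrafted-cell sample or concurrently in an
  engrafted-cell experiment and a long-term-culture or primary CD34+
  sample. When WGA data are involved, the stricter disjunction applies:
  (1) WGA plus an independent non-WGA engrafted-cell experiment, (2) two
  distinct WGA samples concurring (repeat preparations from one experiment
  being the weakest accepted case), or (3) WGA plus any non-WGA
  LTC/CD34/engrafted-cell sample. The `mds3_like` flag additionally
  requires detection in >=2 animals, matching the three-animal WGA design
  it models; reading rule (2) as "any two distinct WGA samples" is what
  makes that two-of-three-animals criterion coherent with the base rules.

## Quantification

MAB is alt reads / total reads with a Wilson-score interval (Wilson rather
than Wald because small alt counts are routine near the detection floor;
level configurable, default 95%). Replicates are pooled by the unweighted
mean of replicate MABs — the replicate PCR/sequencing experiment, not the
read, is the unit of validation; read-weighted pooling is available as an
option. The pooled interval uses the replicate spread (t-based) at >=3
replicates and pooled counts otherwise.

The detection floor is `max(0.01, min_alt_reads / coverage)` with
`min_alt_reads = 8` by default, so the floor equals the published 1%
operating point exactly at the 800x reference coverage and degrades
gracefully below it. Compartment maintenance of a burden is declared when a
two-tailed two-sample t-test on replicate MABs does not reject at 0.05; the
replicate grouping (PCR replicates vs sequencing runs) is the caller's
choice, since the published analysis does not fix it.

## Trajectory classification

Five mutually exclusive categories per (mutation, sample pair): *not
detected* (follow-up below the detection floor, identified with the
"background noise level", which is never quantified separately at source),
*same* (absolute change <= 0.05 — an absolute band, because a 43%→46%
shift counts as unchanged), *increased >=2-fold*, *decreased >=2-fold*,
and *changed <2-fold*. The published legend's "<=2-fold / >=2-fold" classes
overlap at exactly 2-fold; boundaries here go to the >=2-fold classes. Fold
change is follow-up/primary with the primary clamped at the floor so
emergent clones do not divide by ~0. The recapitulation score is the
fraction of mutations with identical categories in two comparisons
(symmetric), with a direction-only variant (up / down-or-lost / flat).

## LOH segmentation

A heterozygous deletion in a fraction *f* of cells shifts a germline
heterozygous SNP's allele fraction to `(1-f)/(2-f)` (or its mirror), a
deviation `d = f/(2(2-f))` from 0.5. Informative SNPs are population-known,
non-somatic, outside duplicated regions, depth >= 20, and heterozygous in
the paired normal when one is supplied. (The published selection clause
"population allele frequency <0.001 were selected" contradicts the evident
intent of using common polymorphisms; the default keeps AF >= 0.001 and the
comparison direction is a config value.)

Segmentation is a transparent sliding window rather than an HMM or
changepoint model: windows of 25 SNPs are LOH-shifted when mean
`|fraction - 0.5| > 0.15`; runs of >=2 shifted windows merge into segments;
overlapping spans are merged so output segments are disjoint and sorted.
The affected-cell fraction inverts the deviation model, `f = 2d/(0.5+d)`,
using the segment core (excluding one window width at each end, which
straddles the true boundary and dilutes the deviation). Boundaries are
therefore accurate to about one window of SNPs. The default threshold
implies a sensitivity floor around f ≈ 0.3; a 7%-of-cells deletion clone
(deviation ≈ 0.018) is invisible to this method by design — consistent
with such clones being detectable by FISH but not by exome allele
fractions. Coordinates are 1-based inclusive internally; BED export is
0-based half-open.

## Synthetic data generator

The simulator emulates exactly the structure the analysis assumes: a clone
tree grown by sequential acquisition (branch probability per new mutation;
0 gives a linear chain), one shared Dirichlet base mixture perturbed per
compartment by log-normal drift (drift 0 reproduces the
"burden maintained across compartments" regime), binomial read counts at a
fixed per-amplicon coverage with a symmetric per-read error flip, single-
founder colonies, and WGA overlays (spurious variants at a per-locus rate,
a configurable fraction carrying homopolymer flanks and/or bias flags, and
allele dropout zeroing the alt or ref reads). Ground truth (true MAB,
founders, artifact labels) travels in side channels that analysis
operations never read.

Defaults are the study conditions: coverage 800x, 6 mutations, branching
probability 0.4, drift 0.02. Error magnitudes are not published anywhere in
the source setting, so the package fixes its own: per-read error 0.002
(typical Illumina amplicon substitution scale), WGA artifact rate 0.05 per
locus, allele-dropout probability 0.05 — large enough to exercise every
filter, small enough that true clones dominate. All randomness derives from
one seed through a named generator per stage, so identical seed and config
give byte-identical outputs at every stage.

What the simulator deliberately does not reproduce: indels, alignment and
capture artifacts beyond the boolean bias flags, plating bias in colony
founding, overdispersion beyond binomial sampling, and correlated errors
between replicates. Passing recovery tests on this generator therefore
demonstrates correctness of the analysis logic under its stated model, not
robustness to every failure mode of real amplicon data.

## Verification scales

The checks are desk-scale by design: the Fisher test is compared against an
independent exhaustive hypergeometric enumeration on every 2x2 table with
both row margins <= 50 (~1.8 million tables, about ten seconds thanks to
cached weight vectors), and against scipy's implementation on random larger
tables; tree compatibility against a brute-force pattern scan on 1,000
random matrices up to 12 colonies x 6 mutations; pooled-MAB recovery over
1,000 seeded runs of 3 replicates at 800x; trajectory recovery for injected
folds {0.3x, 1x, 3x} at a base burden of 20% — an operating point chosen
from binomial power, since at a 10% base the 0.3x class lands within the
+-5-point "same" band more than 5% of the time for any classifier at 800x;
clone-tree round-trips at error 0 conditional on every clone being sampled;
and LOH boundary recovery on noise-free deletion profiles.

## Known limitations

* No copy-number-aware prevalence correction beyond the heterozygous
  doubling rule; deletion vs copy-neutral LOH is not distinguished.
* No probabilistic phylogeny: genotype calls are hard, and a single
  miscalled colony can render a matrix tree-incompatible (the violating
  mutation pair is reported for triage).
* No doublet/mixed-colony deconvolution; colonies are assumed
  single-founder.
* The acquisition-order procedure is a heuristic over first-detection time
  points and interval-separated prevalences, mirroring how such orders are
  argued from sequential samples; it is not a formal ordering test.
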