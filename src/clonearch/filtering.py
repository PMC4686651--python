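"""Somatic-variant filter cascade.

Implements the ordered filter stack used to distil somatic mutations from
paired tumour/normal exome calls in a whole-genome-amplification-heavy
setting:

1. read-level filters (alignment score, base quality, fold strand bias);
2. somatic filters (Fisher exact p, supporting reads, normal contamination,
   tumour burden, population-database membership, duplicated regions);
3. WGA-artifact filters (flanking homopolymer runs, control-WGA variant
   set, positional/read-length bias flags);
4. xenograft (HEC) concordance rules across engraftment experiments.

Every record receives a :class:`FilterVerdict` listing exactly which rules
fired, so filter behaviour is auditable per variant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from functools import lru_cache
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .config import FilterConfig

__all__ = [
    "AlleleCountRecord",
    "FilterVerdict",
    "Detection",
    "UnpairedInputError",
    "fisher_somatic_test",
    "apply_read_filters",
    "pass_somatic_filters",
    "wga_artifact_filters",
    "hec_concordance_pass",
    "filter_cascade",
]


class UnpairedInputError(ValueError):
    """A tumour record has no paired normal at the same locus."""


@dataclass
class AlleleCountRecord:
    """One variant observation in one sample, with read-level evidence."""

    sample_id: str
    mutation_id: str
    alt_reads: int
    total_reads: int
    source_class: str = "compartment"
    replicate_id: str = "r1"
    experiment_id: str = "exp1"
    gene: str = ""
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "T"
    fwd_alt_reads: int = 0
    rev_alt_reads: int = 0
    mean_align_score: float = 60.0
    mean_base_quality: float = 35.0
    flank_left: str = ""
    flank_right: str = ""
    wga: bool = False
    pop_known: bool = False
    pop_af: float = 0.0
    dup_region: bool = False
    known_mutation: bool = False
    bias_flag: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= self.total_reads):
            raise ValueError(f"alt_reads must satisfy 0 <= alt <= total, got "
                             f"{self.alt_reads}/{self.total_reads}")
        if self.pos < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if self.fwd_alt_reads or self.rev_alt_reads:
            if self.fwd_alt_reads + self.rev_alt_reads != self.alt_reads:
                raise ValueError("per-strand alt counts must sum to alt_reads")

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.total_reads if self.total_reads else float("nan")

    @classmethod
    def from_mapping(cls, row: Mapping) -> "AlleleCountRecord":
        names = {f.name for f in dc_fields(cls)}
        return cls(**{k: v for k, v in dict(row).items() if k in names})


@dataclass
class FilterVerdict:
    """Outcome of the cascade for one record: pass iff no rule fired."""

    record: AlleleCountRecord | None
    fired: list[str] = field(default_factory=list)
    stage: str | None = None

    @property
    def passed(self) -> bool:
        return not self.fired

    def merge(self, other: "FilterVerdict") -> "FilterVerdict":
        fired = self.fired + [r for r in other.fired if r not in self.fired]
        stage = self.stage if self.fired else other.stage
        return FilterVerdict(self.record, fired, stage)


# ---------------------------------------------------------------------------
# Fisher's exact somatic test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=300_000)
def _hypergeom_weights(n1: int, n2: int, k: int) -> tuple[int, tuple[int, ...]]:
    """Exact integer hypergeometric weights C(n1,x)*C(n2,k-x) over the support."""
    lo = max(0, k - n2)
    hi = min(k, n1)
    return lo, tuple(math.comb(n1, x) * math.comb(n2, k - x) for x in range(lo, hi + 1))


def fisher_somatic_test(tumor_alt: int, tumor_ref: int,
                        normal_alt: int, normal_ref: int) -> float:
    """Two-sided Fisher's exact p for the tumour/normal alt-ref 2x2 table.

    Computed by exact hypergeometric enumeration with integer arithmetic:
    the p-value is the total probability of all tables (at fixed margins)
    whose point probability does not exceed that of the observed table.
    An all-zero table is defined to return 1.0 with a warning.
    """
    for v in (tumor_alt, tumor_ref, normal_alt, normal_ref):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n1 = tumor_alt + tumor_ref
    n2 = normal_alt + normal_ref
    k = tumor_alt + normal_alt
    if n1 + n2 == 0:
        warnings.warn("all-zero 2x2 table; Fisher p defined as 1.0", stacklevel=2)
        return 1.0
    lo, weights = _hypergeom_weights(n1, n2, k)
    w_obs = weights[tumor_alt - lo]
    num = sum(w for w in weights if w <= w_obs)
    return min(1.0, num / math.comb(n1 + n2, k))


# ---------------------------------------------------------------------------
# rule stages
# ---------------------------------------------------------------------------

def fold_strand_bias(fwd_alt: int, rev_alt: int) -> float:
    """max/min ratio of per-strand alt counts, with the min clamped at 1."""
    return max(fwd_alt, rev_alt) / max(1, min(fwd_alt, rev_alt))


def apply_read_filters(record: AlleleCountRecord, config: FilterConfig) -> FilterVerdict:
    """Read-level exclusions: alignment score, base quality, strand bias."""
    fired = []
    if record.mean_align_score < config.min_alignment_score:
        fired.append("alignment_score")
    if record.mean_base_quality < config.min_base_quality:
        fired.append("base_quality")
    if fold_strand_bias(record.fwd_alt_reads, record.rev_alt_reads) > config.max_fold_strand_bias:
        fired.append("strand_bias")
    return FilterVerdict(record, fired, "read" if fired else None)


def pass_somatic_filters(
    record: AlleleCountRecord,
    paired_normal_record: AlleleCountRecord | None,
    config: FilterConfig,
) -> FilterVerdict:
    """Somatic pass rules against the paired normal.

    A variant passes only when the somatic Fisher p is below the threshold,
    it has enough supporting reads, the paired normal carries it below the
    contamination bound (skin vs T-cell), the tumour burden exceeds the
    floor, it is not a common population variant, and it does not fall in a
    genomic duplicated region (unless flagged as a known mutation).
    """
    if paired_normal_record is None:
        raise UnpairedInputError(
            f"no paired normal for {record.mutation_id} in {record.sample_id}"
        )
    if (record.chrom, record.pos) != (paired_normal_record.chrom, paired_normal_record.pos):
        raise UnpairedInputError("tumour and normal records refer to different loci")
    fired = []
    p = fisher_somatic_test(
        record.alt_reads,
        record.total_reads - record.alt_reads,
        paired_normal_record.alt_reads,
        paired_normal_record.total_reads - paired_normal_record.alt_reads,
    )
    if not (p < config.somatic_p_max):
        fired.append("somatic_p")
    if not (record.alt_reads >= config.min_supporting_reads):
        fired.append("min_supporting_reads")
    if paired_normal_record.source_class == "normal_tcell":
        bound = config.normal_max_fraction_tcell
    else:
        bound = config.normal_max_fraction_skin
    if not (paired_normal_record.allele_fraction < bound):
        fired.append("normal_contamination")
    if not (record.allele_fraction > config.tumour_min_burden):
        fired.append("tumour_min_burden")
    if record.pop_known and record.pop_af > config.pop_af_max:
        fired.append("population_variant")
    if record.dup_region and not record.known_mutation:
        fired.append("duplicated_region")
    return FilterVerdict(record, fired, "somatic" if fired else None)


def _adjacent_run(flank: str, side: str) -> int:
    """Length of the homopolymer run immediately adjacent to the variant.

    ``side='left'`` inspects the suffix of the left flank, ``side='right'``
    the prefix of the right flank. Runs interrupted by the variant base are
    not joined across the two sides.
    """
    if not flank:
        return 0
    seq = flank[::-1] if side == "left" else flank
    base = seq[0]
    run = 0
    for ch in seq:
        if ch != base:
            break
        run += 1
    return run


def wga_artifact_filters(
    record: AlleleCountRecord,
    config: FilterConfig,
    control_wga_variant_set: frozenset | set = frozenset(),
) -> FilterVerdict:
    """WGA false-positive filters: homopolymer context, control set, bias flags."""
    if not record.flank_left and not record.flank_right:
        raise ValueError("flanking sequence required for WGA records")
    fired = []
    if (
        _adjacent_run(record.flank_left, "left") >= config.homopolymer_min_run
        or _adjacent_run(record.flank_right, "right") >= config.homopolymer_min_run
    ):
        fired.append("homopolymer")
    key = (record.chrom, record.pos, record.alt)
    if key in control_wga_variant_set or record.mutation_id in control_wga_variant_set:
        fired.append("wga_control")
    if record.bias_flag:
        fired.append("wga_bias")
    return FilterVerdict(record, fired, "wga" if fired else None)


# ---------------------------------------------------------------------------
# xenograft concordance
# ---------------------------------------------------------------------------

class Detection(NamedTuple):
    """One piece of evidence for a mutation in one sample."""

    experiment: str        # engraftment experiment / mouse identifier
    sample: str            # sample identifier (distinguishes repeat WGA preps)
    source: str            # HEC | LTC | CD34 | ...
    wga: bool
    detected: bool


def hec_concordance_pass(
    mutation: str,
    evidence: Iterable[Detection],
    config: FilterConfig,
    *,
    mds3_like: bool = False,
) -> bool:
    """Concordance rules for mutations called in human engrafted cells (HEC).

    When non-WGA HEC data exist, a candidate passes if it is present in more
    than one HEC sample, or concurrently in an HEC experiment and an
    LTC-derived or primary CD34+ sample. When WGA HEC data are involved the
    stricter disjunction applies: (1) WGA HEC plus an independent non-WGA
    HEC experiment; (2) repeat WGA samples from the same experiment; (3)
    WGA HEC plus any non-WGA LTC/CD34/HEC sample. A patient flagged
    ``mds3_like`` (WGA data across three animals) additionally requires
    detection in at least ``mds3_min_animals`` animals.
    """
    ev = list(evidence)
    if not ev:
        raise ValueError("evidence map must be non-empty")
    det = [d for d in ev if d.detected]
    hec_det = [d for d in det if d.source == "HEC"]

    wga_involved = any(d.wga for d in ev if d.source == "HEC")
    if not wga_involved:
        rule_multi_hec = len({(d.experiment, d.sample) for d in hec_det}) > 1
        rule_hec_plus = bool(hec_det) and any(d.source in ("LTC", "CD34") for d in det)
        ok = rule_multi_hec or rule_hec_plus
    else:
        wga_hec = [d for d in hec_det if d.wga]
        nonwga_hec = [d for d in hec_det if not d.wga]
        r1 = any(
            w.experiment != n.experiment for w in wga_hec for n in nonwga_hec
        )
        # two distinct WGA HEC samples concur (repeat preparations from the
        # same engraftment experiment are the weakest accepted case)
        r2 = len({(d.experiment, d.sample) for d in wga_hec}) >= 2
        r3 = bool(wga_hec) and any(
            (not d.wga) and d.source in ("LTC", "CD34", "HEC") for d in det
        )
        ok = r1 or r2 or r3

    if mds3_like:
        animals = {d.experiment for d in hec_det}
        ok = ok and len(animals) >= config.mds3_min_animals
    return ok


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def filter_cascade(
    records: Sequence[AlleleCountRecord],
    config: FilterConfig,
    *,
    normals: Mapping[str, AlleleCountRecord] | None = None,
    control_wga_variant_set: frozenset | set = frozenset(),
    hec_evidence: Mapping[str, Sequence[Detection]] | None = None,
    mds3_like: bool = False,
) -> tuple[list[AlleleCountRecord], list[FilterVerdict]]:
    """Apply read -> somatic -> WGA -> HEC-concordance filters in order.

    ``normals`` maps mutation identifier to the paired-normal record.
    Per-record errors (e.g. a missing paired normal) are recorded in the
    verdict log without aborting the batch. Returns the passed records and
    one verdict per input record, in input order.
    """
    normals = normals or {}
    verdicts: list[FilterVerdict] = []
    passed: list[AlleleCountRecord] = []
    for rec in records:
        verdict = apply_read_filters(rec, config)
        try:
            verdict = verdict.merge(
                pass_somatic_filters(rec, normals.get(rec.mutation_id), config)
            )
        except UnpairedInputError:
            verdict = verdict.merge(FilterVerdict(rec, ["unpaired_normal"], "somatic"))
        if rec.wga:
            try:
                verdict = verdict.merge(
                    wga_artifact_filters(rec, config, control_wga_variant_set)
                )
            except ValueError:
                verdict = verdict.merge(FilterVerdict(rec, ["missing_flank"], "wga"))
        if rec.source_class == "HEC" and hec_evidence is not None:
            ev = hec_evidence.get(rec.mutation_id, ())
            if not ev or not hec_concordance_pass(rec.mutation_id, ev, config,
                                                  mds3_like=mds3_like):
                verdict = verdict.merge(FilterVerdict(rec, ["hec_concordance"], "hec"))
        verdicts.append(verdict)
        if verdict.passed:
            passed.append(rec)
    return passed, verdicts


def verdicts_to_frame(verdicts: Sequence[FilterVerdict]) -> pd.DataFrame:
    """Tabular audit log: one row per record with the rules that fired."""
    rows = []
    for v in verdicts:
        rec = v.record
        rows.append(
            {
                "sample_id": rec.sample_id if rec else "",
                "mutation_id": rec.mutation_id if rec else "",
                "passed": v.passed,
                "fired_rules": ";".join(v.fired),
                "stage": v.stage or "",
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "mutation_id", "passed",
                                       "fired_rules", "stage"])
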