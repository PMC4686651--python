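"""Mutant allele burden (MAB) quantification.

MAB is the proportion of sequencing reads at a locus carrying the mutant
allele. For a heterozygous mutation, twice the MAB estimates the fraction of
cells carrying the mutation (cellular prevalence), so a MAB of 50% implies
100% mutant cells. Replicate estimates are pooled by unweighted averaging of
replicate MABs — the replicate, not the read, is the unit of validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .config import FilterConfig

__all__ = [
    "MabEstimate",
    "Prevalence",
    "mab_from_counts",
    "pool_mab",
    "cellular_prevalence",
    "detection_limit",
    "compare_compartments",
]


@dataclass
class MabEstimate:
    """Mutant allele burden with replicate structure and detection status."""

    mutation_id: str
    sample_id: str
    mab: float
    alt_reads: int
    total_reads: int
    ci_low: float
    ci_high: float
    n_replicates: int = 1
    detected: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.mab <= 1.0):
            raise ValueError("MAB must lie in [0, 1]")
        if not (self.ci_low - 1e-12 <= self.mab <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must contain the point estimate")


class Prevalence(NamedTuple):
    """Cellular prevalence with an over-unity flag (possible LOH/CNV)."""

    fraction: float
    over_unity: bool

    def __float__(self) -> float:  # convenience for arithmetic
        return self.fraction


def mab_from_counts(
    alt: int,
    total: int,
    *,
    mutation_id: str = "",
    sample_id: str = "",
    ci_level: float = 0.95,
    detection_floor: float = 0.01,
    min_alt_reads: int = 3,
) -> MabEstimate:
    """MAB point estimate with a Wilson-score confidence interval.

    The Wilson interval behaves sensibly at small counts (it never collapses
    to a zero-width interval at alt=0). Raises on total=0, where the MAB is
    undefined.
    """
    if total <= 0:
        raise ValueError("MAB undefined for total read count 0")
    if not (0 <= alt <= total):
        raise ValueError("alt must satisfy 0 <= alt <= total")
    mab = alt / total
    lo, hi = proportion_confint(alt, total, alpha=1.0 - ci_level, method="wilson")
    lo = min(max(0.0, float(lo)), mab)
    hi = max(min(1.0, float(hi)), mab)
    return MabEstimate(
        mutation_id, sample_id, mab, alt, total, lo, hi,
        n_replicates=1,
        detected=(mab >= detection_floor and alt >= min_alt_reads),
    )


def pool_mab(
    replicates: Sequence[MabEstimate],
    *,
    ci_level: float = 0.95,
    detection_floor: float = 0.01,
    weight_by_reads: bool = False,
) -> MabEstimate:
    """Pool replicate MABs by unweighted averaging.

    The point estimate is the plain mean of replicate MABs (replicates, not
    reads, are averaged; ``weight_by_reads=True`` switches to read-pooled
    alt/total). The interval comes from the replicate spread (t-based) when
    three or more replicates exist, and from the pooled counts (Wilson)
    otherwise.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    mut_ids = {r.mutation_id for r in replicates}
    if len(mut_ids) > 1:
        raise ValueError(f"mixed mutation identifiers in replicate list: {sorted(mut_ids)}")
    alt = sum(r.alt_reads for r in replicates)
    total = sum(r.total_reads for r in replicates)
    vals = np.sort(np.array([r.mab for r in replicates]))  # order-insensitive
    if weight_by_reads:
        mab = alt / total
    else:
        mab = float(np.mean(vals))
    n = len(replicates)
    if n >= 3:
        se = vals.std(ddof=1) / math.sqrt(n)
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
        lo, hi = mab - tcrit * se, mab + tcrit * se
    else:
        lo, hi = proportion_confint(alt, total, alpha=1.0 - ci_level, method="wilson")
    lo = min(max(0.0, float(lo)), mab)
    hi = max(min(1.0, float(hi)), mab)
    return MabEstimate(
        replicates[0].mutation_id,
        replicates[0].sample_id,
        mab, alt, total, lo, hi,
        n_replicates=n,
        detected=(mab >= detection_floor),
    )


def cellular_prevalence(mab: float, zygosity: str = "heterozygous") -> Prevalence:
    """Convert MAB to the fraction of cells carrying the mutation.

    Heterozygous mutations double: prevalence = min(2*MAB, 1), flagging
    over-unity inputs (2*MAB > 1 suggests LOH or copy-number change).
    Hemizygous/homozygous loci map one-to-one.
    """
    if not (0.0 <= mab <= 1.0):
        raise ValueError("MAB must lie in [0, 1]")
    if zygosity == "heterozygous":
        doubled = 2.0 * mab
        return Prevalence(min(doubled, 1.0), doubled > 1.0)
    if zygosity in ("hemizygous", "homozygous"):
        return Prevalence(mab, False)
    raise ValueError(f"unknown zygosity {zygosity!r}")


def detection_limit(
    coverage: int,
    min_alt_reads: int | None = None,
    config: FilterConfig | None = None,
) -> float:
    """Smallest reliably detectable MAB at the given amplicon coverage.

    The floor is the maximum of the configured operating floor (1% at the
    reference coverage of 800x) and the read-count floor
    ``min_alt_reads / coverage``; it is monotone non-increasing in coverage.
    """
    cfg = config or FilterConfig()
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    m = cfg.min_detection_alt_reads if min_alt_reads is None else min_alt_reads
    return max(cfg.detection_floor, m / coverage)


def compare_compartments(
    groups: Mapping[str, Sequence[float]],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-tailed t-tests of replicate MABs between compartments.

    A mutation's burden is called "maintained" between two compartments when
    the two-sample t-test does not reject at ``alpha`` (p > 0.05 with the
    default). Pairs where both groups have fewer than two replicates are
    reported descriptively with no p-value. Two identical constant groups
    are defined to give p = 1.0 (no evidence of any shift).
    """
    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va = np.asarray(groups[a], dtype=float)
            vb = np.asarray(groups[b], dtype=float)
            diff = float(va.mean() - vb.mean())
            if len(va) < 2 and len(vb) < 2:
                rows.append({"compartment_a": a, "compartment_b": b,
                             "mean_diff": diff, "statistic": np.nan,
                             "p_value": np.nan, "maintained": None})
                continue
            if va.std(ddof=0) == 0 and vb.std(ddof=0) == 0:
                p = 1.0 if va.mean() == vb.mean() else 0.0
                t = 0.0 if p == 1.0 else np.inf
            else:
                t, p = stats.ttest_ind(va, vb, equal_var=True)
            rows.append({"compartment_a": a, "compartment_b": b,
                         "mean_diff": diff, "statistic": float(t),
                         "p_value": float(p), "maintained": bool(p > alpha)})
    return pd.DataFrame(rows)
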