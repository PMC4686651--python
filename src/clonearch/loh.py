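"""Loss-of-heterozygosity (LOH) scanning from germline SNP allele fractions.

Germline heterozygous SNPs sequence near a 50% allele fraction; a deletion
(or copy-neutral loss) present in a cell fraction *f* pulls the fraction of
the affected allele to (1-f)/(2-f), i.e. a deviation d = f/(2(2-f)) from
0.5. Scanning the position-ordered deviation profile with a sliding window
turns the visual chromosome plot into an explicit segmentation, and
inverting the deviation model (f = 2d/(0.5+d)) estimates the affected-cell
fraction of each segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FilterConfig

__all__ = [
    "LohSegment",
    "select_informative_snps",
    "allele_fraction_profile",
    "detect_loh_segments",
    "affected_fraction_from_deviation",
    "deviation_from_affected_fraction",
    "segments_to_bed",
]

SNP_COLUMNS = ["chrom", "pos", "alt_fraction", "depth", "pop_known",
               "pop_af", "somatic", "dup_region"]


@dataclass
class LohSegment:
    """One LOH segment (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    mean_deviation: float
    affected_fraction: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")


def deviation_from_affected_fraction(f: float) -> float:
    """Expected |allele fraction - 0.5| for a heterozygous deletion in fraction f."""
    return f / (2.0 * (2.0 - f))


def affected_fraction_from_deviation(d: float) -> float:
    """Invert the deviation model: f = 2d/(0.5+d), clipped to [0, 1]."""
    return float(min(1.0, max(0.0, 2.0 * d / (0.5 + d))))


def select_informative_snps(
    records: pd.DataFrame,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Keep SNPs informative for LOH mapping.

    Retains population-known, non-somatic variants outside duplicated
    regions with read depth >= the floor; when a ``normal_fraction`` column
    is present, additionally requires the paired normal to look heterozygous
    (fraction within the configured band, [0.25, 0.75] by default). Output
    is position-sorted per chromosome.
    """
    cfg = config or FilterConfig()
    df = records.copy()
    keep = (
        df["pop_known"].astype(bool)
        & ~df["somatic"].astype(bool)
        & ~df["dup_region"].astype(bool)
        & (df["depth"] >= cfg.loh_min_depth)
    )
    if cfg.loh_pop_af_direction == "ge":
        keep &= df["pop_af"] >= cfg.loh_pop_af_cut
    else:
        keep &= df["pop_af"] < cfg.loh_pop_af_cut
    if "normal_fraction" in df.columns:
        keep &= df["normal_fraction"].between(cfg.loh_normal_het_low,
                                              cfg.loh_normal_het_high)
    return df[keep].sort_values(["chrom", "pos"]).reset_index(drop=True)


def allele_fraction_profile(records: pd.DataFrame, chromosome: str) -> pd.DataFrame:
    """Position-sorted (pos, fraction) series for one chromosome; no smoothing."""
    sub = records[records["chrom"].astype(str) == str(chromosome)]
    if sub.empty:
        warnings.warn(f"no informative SNPs on chromosome {chromosome}", stacklevel=2)
        return pd.DataFrame(columns=["pos", "fraction"])
    out = sub.sort_values("pos")[["pos", "alt_fraction"]].rename(
        columns={"alt_fraction": "fraction"}
    )
    return out.reset_index(drop=True)


def detect_loh_segments(
    profile: pd.DataFrame,
    *,
    chrom: str = "",
    window: int = 25,
    delta: float = 0.15,
    min_consecutive: int = 2,
    config: FilterConfig | None = None,
) -> list[LohSegment]:
    """Sliding-window LOH segmentation of an allele-fraction profile.

    Windows of ``window`` consecutive SNPs (step 1) are LOH-shifted when the
    mean |fraction - 0.5| exceeds ``delta``; maximal runs of at least
    ``min_consecutive`` shifted windows merge into segments spanning from
    the first SNP of the first window to the last SNP of the last. The
    affected-cell fraction is estimated from the segment's mean deviation.
    A small deletion clone (e.g. ~7% of cells, deviation ~0.018) sits far
    below any workable ``delta`` — the method's documented floor.
    """
    if config is not None:
        window = config.loh_window
        delta = config.loh_delta
        min_consecutive = config.loh_min_consecutive
    if profile.empty:
        raise ValueError("profile must be non-empty")
    pos = profile["pos"].to_numpy()
    frac = profile["fraction"].to_numpy(dtype=float)
    n = len(pos)
    if window > n:
        warnings.warn(
            f"window ({window}) exceeds profile length ({n}); no segments",
            stacklevel=2,
        )
        return []
    dev = np.abs(frac - 0.5)
    # rolling mean over `window` SNPs
    csum = np.concatenate([[0.0], np.cumsum(dev)])
    win_mean = (csum[window:] - csum[:-window]) / window
    shifted = win_mean > delta
    # maximal runs of shifted windows, as SNP index spans
    spans: list[list[int]] = []
    i = 0
    n_win = len(shifted)
    while i < n_win:
        if not shifted[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_win and shifted[j + 1]:
            j += 1
        if j - i + 1 >= min_consecutive:
            spans.append([i, j + window - 1])
        i = j + 1
    # merge SNP spans that overlap (runs separated by < window SNPs)
    merged: list[list[int]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    segments: list[LohSegment] = []
    for lo_snp, hi_snp in merged:
        # the outer window-width flanks straddle the true boundary and dilute
        # the deviation; estimate the affected fraction from the segment core
        core_lo, core_hi = lo_snp + window - 1, hi_snp - window + 1
        if core_lo > core_hi:
            core_lo, core_hi = lo_snp, hi_snp
        seg_dev = float(dev[core_lo:core_hi + 1].mean())
        segments.append(
            LohSegment(
                chrom=chrom,
                start=int(pos[lo_snp]),
                end=int(pos[hi_snp]),
                n_snps=hi_snp - lo_snp + 1,
                mean_deviation=seg_dev,
                affected_fraction=affected_fraction_from_deviation(seg_dev),
            )
        )
    return segments


def segments_to_bed(segments: list[LohSegment]) -> str:
    """BED text (0-based half-open) for the called segments."""
    lines = [
        f"{s.chrom}\t{s.start - 1}\t{s.end}\tLOH\t{s.affected_fraction:.3f}"
        for s in segments
    ]
    return "\n".join(lines) + ("\n" if lines else "")
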