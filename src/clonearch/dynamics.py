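"""Clonal dynamics between paired samples.

Tracks per-mutation MAB changes between a primary sample and a follow-up
(xenograft-derived cells, or a later patient time point), classifies each
trajectory into one of five categories (same / changed <2-fold / decreased
>=2-fold / increased >=2-fold / not detected), tests burden shifts, scores
how well xenograft dynamics recapitulate patient follow-up dynamics, and
orders lesion acquisition across sequential time points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import fisher_somatic_test

__all__ = [
    "TrajectoryCategory",
    "classify_mab_change",
    "test_mab_shift",
    "test_mab_shift_replicates",
    "clone_trajectory_table",
    "RecapitulationResult",
    "recapitulation_score",
    "infer_acquisition_order",
]


class TrajectoryCategory(str, enum.Enum):
    """Per-mutation MAB trajectory class between a primary and a follow-up."""

    SAME = "same"
    CHANGED_LT2FOLD = "changed_lt2fold"
    DECREASED_GE2FOLD = "decreased_ge2fold"
    INCREASED_GE2FOLD = "increased_ge2fold"
    NOT_DETECTED = "not_detected"


def classify_mab_change(
    primary_mab: float,
    followup_mab: float,
    *,
    detection_floor: float = 0.01,
    same_tolerance: float = 0.05,
) -> TrajectoryCategory:
    """Classify one mutation's MAB change between paired samples.

    Checked in order: *not detected* when the follow-up burden falls below
    the detection floor; *same* when the absolute change is within
    ``same_tolerance`` (an absolute band — a 43%→46% shift is unchanged);
    otherwise the fold change follow-up/primary (primary clamped at the
    floor, so emergent clones do not divide by ~0) assigns *increased* at
    >=2-fold, *decreased* at <=0.5-fold, and *changed <2-fold* in between.
    """
    for v in (primary_mab, followup_mab):
        if not (0.0 <= v <= 1.0):
            raise ValueError("MABs must lie in [0, 1]")
    if followup_mab < detection_floor:
        return TrajectoryCategory.NOT_DETECTED
    if abs(followup_mab - primary_mab) <= same_tolerance:
        return TrajectoryCategory.SAME
    fold = followup_mab / max(primary_mab, detection_floor)
    if fold >= 2.0:
        return TrajectoryCategory.INCREASED_GE2FOLD
    if fold <= 0.5:
        return TrajectoryCategory.DECREASED_GE2FOLD
    return TrajectoryCategory.CHANGED_LT2FOLD


def test_mab_shift(alt1: int, total1: int, alt2: int, total2: int) -> float:
    """Exact two-proportion test of a burden shift between two samples.

    Two-sided Fisher's exact p on the alt/ref 2x2 table across the two
    samples (shares the exact enumeration with the somatic test).
    """
    if total1 <= 0 or total2 <= 0:
        raise ValueError("total read counts must be positive")
    return fisher_somatic_test(alt1, total1 - alt1, alt2, total2 - alt2)


def test_mab_shift_replicates(mabs1: Sequence[float], mabs2: Sequence[float]) -> float:
    """Two-tailed two-sample t-test on replicate MAB vectors."""
    a = np.asarray(mabs1, dtype=float)
    b = np.asarray(mabs2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 replicates for a t-test")
    if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def clone_trajectory_table(
    primary: Mapping[str, float],
    followup: Mapping[str, float],
    *,
    detection_floor: float = 0.01,
    same_tolerance: float = 0.05,
) -> pd.DataFrame:
    """Per-mutation trajectory categories for one sample pair.

    Mutations of the primary panel missing from the follow-up table are
    treated as not detected, with an audit note.
    """
    rows = []
    for mut in primary:
        p = float(primary[mut])
        if mut in followup:
            f = float(followup[mut])
            note = ""
        else:
            f, note = 0.0, "missing_in_followup"
        cat = classify_mab_change(
            p, f, detection_floor=detection_floor, same_tolerance=same_tolerance
        )
        rows.append({"mutation_id": mut, "primary_mab": p, "followup_mab": f,
                     "category": cat.value, "note": note})
    return pd.DataFrame(rows, columns=["mutation_id", "primary_mab",
                                       "followup_mab", "category", "note"])


_DIRECTION = {
    TrajectoryCategory.INCREASED_GE2FOLD: 1,
    TrajectoryCategory.DECREASED_GE2FOLD: -1,
    TrajectoryCategory.NOT_DETECTED: -1,
    TrajectoryCategory.SAME: 0,
    TrajectoryCategory.CHANGED_LT2FOLD: 0,
}


@dataclass
class RecapitulationResult:
    """Concordance between xenograft and patient follow-up trajectories."""

    concordance: float
    direction_concordance: float
    per_mutation: pd.DataFrame


def recapitulation_score(
    categories_a: Mapping[str, TrajectoryCategory | str],
    categories_b: Mapping[str, TrajectoryCategory | str],
) -> RecapitulationResult:
    """Fraction of mutations whose trajectory class agrees in both comparisons.

    Symmetric in its arguments. Also reports direction-only concordance,
    where increased counts as up, decreased/not-detected as down, and
    same/<2-fold change as flat.
    """
    shared = sorted(set(categories_a) & set(categories_b))
    if not shared:
        raise ValueError("no shared mutation panel")

    def norm(c) -> TrajectoryCategory:
        return c if isinstance(c, TrajectoryCategory) else TrajectoryCategory(c)

    rows = []
    for m in shared:
        ca, cb = norm(categories_a[m]), norm(categories_b[m])
        rows.append({
            "mutation_id": m,
            "category_a": ca.value,
            "category_b": cb.value,
            "concordant": ca == cb,
            "direction_concordant": _DIRECTION[ca] == _DIRECTION[cb],
        })
    frame = pd.DataFrame(rows)
    return RecapitulationResult(
        float(frame["concordant"].mean()),
        float(frame["direction_concordant"].mean()),
        frame,
    )


def infer_acquisition_order(
    table: pd.DataFrame,
    timepoint_order: Sequence[str],
) -> pd.DataFrame:
    """Order lesions by first detection across sequential time points.

    ``table`` needs columns ``lesion, timepoint, detected, prevalence`` and
    optionally ``ci_low, ci_high``. Lesion A precedes B when A is first
    detected at an earlier time point. Lesions first detected at the same
    time point are sub-ordered by prevalence where confidence intervals
    separate, and tied otherwise. The result carries one row per detected
    lesion with its first-detection time point and a rank (shared rank =
    tie); never-detected lesions are returned with rank NaN.
    """
    required = {"lesion", "timepoint", "detected", "prevalence"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"acquisition table missing columns: {sorted(missing)}")
    tp_index = {tp: i for i, tp in enumerate(timepoint_order)}
    firsts: list[dict] = []
    undetected: list[str] = []
    for lesion, grp in table.groupby("lesion", sort=True):
        det = grp[grp["detected"].astype(bool)]
        if det.empty:
            undetected.append(str(lesion))
            continue
        idx = det["timepoint"].map(tp_index)
        row = det.loc[idx.idxmin()]
        firsts.append({
            "lesion": lesion,
            "first_timepoint": row["timepoint"],
            "tp_index": int(tp_index[row["timepoint"]]),
            "prevalence": float(row["prevalence"]),
            "ci_low": float(row.get("ci_low", row["prevalence"])),
            "ci_high": float(row.get("ci_high", row["prevalence"])),
        })
    firsts.sort(key=lambda r: (r["tp_index"], -r["prevalence"], r["lesion"]))
    rank = 0
    prev = None
    out = []
    for r in firsts:
        if prev is None:
            rank = 1
        elif r["tp_index"] > prev["tp_index"]:
            rank += 1
        elif r["ci_high"] < prev["ci_low"]:  # CIs separate -> strictly later
            rank += 1
        # else: tied with previous lesion, same rank
        out.append({"lesion": r["lesion"], "first_timepoint": r["first_timepoint"],
                    "prevalence": r["prevalence"], "rank": rank})
        prev = r
    for lesion in undetected:
        out.append({"lesion": lesion, "first_timepoint": None,
                    "prevalence": float("nan"), "rank": float("nan")})
    return pd.DataFrame(out, columns=["lesion", "first_timepoint", "prevalence", "rank"])
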