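"""Per-colony genotype calling from amplicon read counts.

A colony-forming-cell (CFC) colony grows from a single founder cell, so its
sequenced genotype reflects one clone. A mutation is called in a colony when
more than 30% of the reads carry the mutant allele; entries below the
minimum depth are no-calls rather than wild type, because an uncovered
locus carries no evidence either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .config import FilterConfig

__all__ = [
    "MUTANT", "WILDTYPE", "NOCALL",
    "ColonyGenotypeMatrix",
    "call_colony_genotype",
    "build_genotype_matrix",
    "colony_fraction_mutant",
]

MUTANT = "M"
WILDTYPE = "W"
NOCALL = "N"


def call_colony_genotype(alt: int, total: int, config: FilterConfig | None = None) -> str:
    """Call one colony/mutation entry from its read counts.

    No-call below the depth floor; mutant when the alt fraction strictly
    exceeds the colony threshold (30% by default); wild type otherwise.
    """
    cfg = config or FilterConfig()
    if not (0 <= alt <= total):
        raise ValueError("alt must satisfy 0 <= alt <= total")
    if total < cfg.min_colony_depth:
        return NOCALL
    return MUTANT if alt / total > cfg.colony_mutant_threshold else WILDTYPE


@dataclass
class ColonyGenotypeMatrix:
    """Colonies x mutations genotype calls with per-entry evidence.

    ``calls`` holds entry codes M/W/N; ``alt_frac`` and ``depth`` carry the
    supporting alt fraction and total depth for each entry (NaN / 0 where a
    colony had no record for a mutation).
    """

    calls: pd.DataFrame
    alt_frac: pd.DataFrame
    depth: pd.DataFrame

    @property
    def colonies(self) -> list[str]:
        return list(self.calls.index)

    @property
    def mutations(self) -> list[str]:
        return list(self.calls.columns)

    def binary(self) -> pd.DataFrame:
        """Mutant=1, anything else 0 (no-calls are handled by the caller)."""
        return (self.calls == MUTANT).astype(int)

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="colony_id")

    def long_audit(self) -> pd.DataFrame:
        """Long-format audit table: one row per (colony, mutation) entry."""
        rows = []
        for c in self.colonies:
            for m in self.mutations:
                rows.append({
                    "colony_id": c,
                    "mutation_id": m,
                    "call": self.calls.at[c, m],
                    "alt_fraction": self.alt_frac.at[c, m],
                    "depth": self.depth.at[c, m],
                })
        return pd.DataFrame(rows)


def build_genotype_matrix(
    reads: pd.DataFrame,
    panel: Sequence[str] | None = None,
    config: FilterConfig | None = None,
) -> ColonyGenotypeMatrix:
    """Build the colonies x mutations call matrix from long-format read counts.

    ``reads`` needs columns ``colony_id, mutation_id, alt_reads,
    total_reads``. Colonies are ordered by identifier, mutations by panel
    order (panel defaults to the mutations present, sorted). A colony
    missing a panel mutation gets a no-call; duplicate (colony, mutation)
    entries are an error.
    """
    cfg = config or FilterConfig()
    required = {"colony_id", "mutation_id", "alt_reads", "total_reads"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"colony table missing columns: {sorted(missing)}")
    if reads.duplicated(["colony_id", "mutation_id"]).any():
        dup = reads[reads.duplicated(["colony_id", "mutation_id"])].iloc[0]
        raise ValueError(
            f"duplicate colony entry: {dup['colony_id']}/{dup['mutation_id']}"
        )
    panel = list(panel) if panel is not None else sorted(reads["mutation_id"].unique())
    colonies = sorted(reads["colony_id"].unique())
    calls = pd.DataFrame(NOCALL, index=colonies, columns=panel)
    frac = pd.DataFrame(float("nan"), index=colonies, columns=panel)
    depth = pd.DataFrame(0, index=colonies, columns=panel)
    for row in reads.itertuples(index=False):
        if row.mutation_id not in calls.columns:
            continue  # off-panel mutation
        c, m = row.colony_id, row.mutation_id
        calls.at[c, m] = call_colony_genotype(int(row.alt_reads), int(row.total_reads), cfg)
        frac.at[c, m] = row.alt_reads / row.total_reads if row.total_reads else float("nan")
        depth.at[c, m] = int(row.total_reads)
    return ColonyGenotypeMatrix(calls, frac, depth)


def colony_fraction_mutant(matrix: ColonyGenotypeMatrix, mutation: str) -> tuple[int, float]:
    """Percent of evaluable colonies mutant for one mutation.

    No-call colonies are excluded from the denominator. Returns the percent
    rounded half-up to the nearest integer alongside the raw fraction.
    """
    if mutation not in matrix.calls.columns:
        raise KeyError(f"mutation {mutation!r} not in matrix")
    col = matrix.calls[mutation]
    n_mut = int((col == MUTANT).sum())
    n_wt = int((col == WILDTYPE).sum())
    if n_mut + n_wt == 0:
        raise ValueError(f"no evaluable colonies for {mutation!r}")
    frac = n_mut / (n_mut + n_wt)
    return int(math.floor(100.0 * frac + 0.5)), frac
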