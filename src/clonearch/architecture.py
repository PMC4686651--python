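"""Clonal-architecture inference from colony genotypes and bulk burdens.

Colonies are single-founder samples, so the set of distinct mutant genotype
signatures is a direct census of subclones. Under the infinite-sites
assumption with a known all-wild-type ancestral state, the signatures are
consistent with a clone tree exactly when no mutation pair shows all three
patterns {A only, B only, A and B} across colonies (the directed
two-character / three-gamete test). The tree is then recovered by ordering
observed signatures under strict set containment — unobserved intermediate
clones are never invented, so an edge may gain several mutations at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .colonies import ColonyGenotypeMatrix, MUTANT, NOCALL, WILDTYPE
from .quantify import MabEstimate
from .tree import CloneTree

__all__ = [
    "SubcloneCatalog",
    "TreeCompatibilityError",
    "enumerate_subclones",
    "check_tree_compatibility",
    "infer_clone_tree",
    "identify_founder",
    "FounderReport",
    "mab_hierarchy",
    "assign_origin_compartment",
    "OriginResult",
]

# compartments ordered from most primitive to most differentiated
DIFFERENTIATION_ORDER = ("HSC", "MPP", "MLP", "CMP", "GMP", "MEP")


class TreeCompatibilityError(ValueError):
    """Genotype matrix is not consistent with any clone tree."""

    def __init__(self, pair: tuple[str, str]):
        self.pair = pair
        super().__init__(
            f"mutations {pair[0]!r} and {pair[1]!r} show all of the patterns "
            "{A only, B only, A and B}: no tree is consistent with the matrix"
        )


@dataclass
class SubcloneCatalog:
    """Distinct mutant genotype signatures with colony counts."""

    entries: list[tuple[frozenset[str], int]]
    wildtype_count: int
    n_evaluable: int

    @property
    def n_subclones(self) -> int:
        return len(self.entries)

    def frequencies(self) -> dict[frozenset[str], float]:
        return {sig: n / self.n_evaluable for sig, n in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"signature": "+".join(sorted(sig)), "n_colonies": n,
             "frequency": n / self.n_evaluable}
            for sig, n in self.entries
        ]
        rows.append({"signature": "(wild type)", "n_colonies": self.wildtype_count,
                     "frequency": self.wildtype_count / self.n_evaluable})
        return pd.DataFrame(rows)


def _colony_signatures(
    matrix: ColonyGenotypeMatrix, nocall_policy: str
) -> dict[str, frozenset[str]]:
    """Per-colony mutation sets, honouring the no-call policy.

    ``exclude`` drops colonies containing any no-call (a no-call could flip
    containment relations); ``as_wildtype`` treats no-calls as wild type.
    """
    if nocall_policy not in ("exclude", "as_wildtype"):
        raise ValueError("nocall_policy must be 'exclude' or 'as_wildtype'")
    sigs: dict[str, frozenset[str]] = {}
    for c in matrix.colonies:
        row = matrix.calls.loc[c]
        if nocall_policy == "exclude" and (row == NOCALL).any():
            continue
        sigs[c] = frozenset(m for m in matrix.mutations if row[m] == MUTANT)
    return sigs


def enumerate_subclones(
    matrix: ColonyGenotypeMatrix, nocall_policy: str = "exclude"
) -> SubcloneCatalog:
    """Census of distinct mutant genotype signatures among evaluable colonies."""
    sigs = _colony_signatures(matrix, nocall_policy)
    counts: dict[frozenset[str], int] = {}
    wt = 0
    for sig in sigs.values():
        if not sig:
            wt += 1
        else:
            counts[sig] = counts.get(sig, 0) + 1
    entries = sorted(counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    return SubcloneCatalog(entries, wt, len(sigs))


def check_tree_compatibility(
    matrix: ColonyGenotypeMatrix | pd.DataFrame,
    nocall_policy: str = "exclude",
) -> tuple[bool, tuple[str, str] | None]:
    """Directed two-character (three-gamete) test with known ancestral state.

    The binary colony x mutation matrix is tree-compatible iff no mutation
    pair (A, B), taken in panel order, exhibits all three colony patterns
    {A only, B only, A and B}. Returns the first violating pair otherwise.
    """
    if isinstance(matrix, ColonyGenotypeMatrix):
        sigs = _colony_signatures(matrix, nocall_policy)
        cols = matrix.mutations
        binary = pd.DataFrame(
            [[int(m in sig) for m in cols] for sig in sigs.values()], columns=cols
        )
    else:
        binary = matrix.astype(int)
        cols = list(binary.columns)
    for i, a in enumerate(cols):
        va = binary[a].to_numpy()
        for b in cols[i + 1:]:
            vb = binary[b].to_numpy()
            has_10 = bool(((va == 1) & (vb == 0)).any())
            has_01 = bool(((va == 0) & (vb == 1)).any())
            has_11 = bool(((va == 1) & (vb == 1)).any())
            if has_10 and has_01 and has_11:
                return False, (a, b)
    return True, None


def infer_clone_tree(
    matrix: ColonyGenotypeMatrix, nocall_policy: str = "exclude"
) -> CloneTree:
    """Reconstruct the clone tree over observed genotype signatures.

    Requires a tree-compatible matrix. Each observed signature becomes a
    clone whose parent is the largest observed proper-subset signature (the
    wild-type root if none); the mutations gained on an edge are the set
    difference, so edges may be multi-mutation where colony data cannot
    resolve order. Sibling branches are exactly containment-incomparable
    signatures. Per-clone colony counts are attached as tree metadata.
    """
    ok, pair = check_tree_compatibility(matrix, nocall_policy)
    if not ok:
        raise TreeCompatibilityError(pair)  # type: ignore[arg-type]
    catalog = enumerate_subclones(matrix, nocall_policy)
    sigs = [sig for sig, _ in catalog.entries]
    counts = dict(catalog.entries)

    def clone_id(sig: frozenset[str]) -> str:
        return "+".join(sorted(sig)) if sig else "WT"

    clones: dict[str, frozenset[str]] = {"WT": frozenset()}
    parents: dict[str, str | None] = {"WT": None}
    meta: dict[str, dict] = {"WT": {"n_colonies": catalog.wildtype_count}}
    for sig in sorted(sigs, key=len):
        subsets = [s for s in sigs if s < sig]
        if subsets:
            maxlen = max(len(s) for s in subsets)
            maximal = [s for s in subsets if len(s) == maxlen]
            # two incomparable maximal subsets would mean a three-gamete
            # violation, already excluded above
            assert len(maximal) == 1, f"ambiguous parent candidates: {maximal}"
            parent_sig = maximal[0]
        else:
            parent_sig = frozenset()
        cid = clone_id(sig)
        clones[cid] = sig
        parents[cid] = clone_id(parent_sig)
        meta[cid] = {"n_colonies": counts[sig]}
    return CloneTree(clones, parents, root="WT", meta=meta)


@dataclass
class FounderReport:
    """Founder mutations and mutually exclusive mutation pairs."""

    founder: frozenset[str]
    exclusive_pairs: list[tuple[str, str]] = field(default_factory=list)


def identify_founder(
    matrix: ColonyGenotypeMatrix,
    *,
    min_pair_count: int = 2,
    nocall_policy: str = "exclude",
) -> FounderReport:
    """Founder set and mutual-exclusivity pairs from the colony matrix.

    A founder mutation is present in every mutant colony (over evaluable
    entries). Two mutations are reported mutually exclusive when each
    appears in at least ``min_pair_count`` colonies and they never co-occur
    — singleton subclones alone never declare exclusivity.
    """
    sigs = _colony_signatures(matrix, nocall_policy)
    mutant = {c: s for c, s in sigs.items() if s}
    if not mutant:
        raise ValueError("at least one mutant colony required")
    founder = set(matrix.mutations)
    for m in matrix.mutations:
        seen_in_any = False
        for c, sig in mutant.items():
            call = matrix.calls.at[c, m]
            if call == NOCALL:
                continue
            if call == MUTANT:
                seen_in_any = True
            else:
                founder.discard(m)
                break
        if not seen_in_any:
            founder.discard(m)
    counts = {m: sum(1 for s in sigs.values() if m in s) for m in matrix.mutations}
    pairs = []
    muts = list(matrix.mutations)
    for i, a in enumerate(muts):
        for b in muts[i + 1:]:
            if counts[a] >= min_pair_count and counts[b] >= min_pair_count:
                if not any(a in s and b in s for s in sigs.values()):
                    pairs.append((a, b))
    return FounderReport(frozenset(founder), pairs)


def mab_hierarchy(estimates: Sequence[MabEstimate]) -> list[tuple[str, str]]:
    """Partial order over mutations from bulk burdens in one sample.

    Under heterozygosity, cellular prevalence is ordered exactly as MAB, so
    mutation A is placed above B when A's confidence interval lies entirely
    above B's. Overlapping intervals leave the pair unordered — similar
    burdens cannot decide which mutation is ancestral. Returns the list of
    (above, below) pairs.
    """
    samples = {e.sample_id for e in estimates}
    if len(samples) > 1:
        raise ValueError("all estimates must come from one sample")
    order: list[tuple[str, str]] = []
    for a in estimates:
        for b in estimates:
            if a is b:
                continue
            if a.ci_low > b.ci_high:
                order.append((a.mutation_id, b.mutation_id))
    return sorted(set(order))


@dataclass
class OriginResult:
    """Earliest compartment of detection along the differentiation hierarchy."""

    origin: str | None
    progenitor_origin: bool


def assign_origin_compartment(
    detection: Mapping[str, bool],
    hierarchy: Sequence[str] = DIFFERENTIATION_ORDER,
) -> OriginResult:
    """Most primitive compartment in which a mutation is detected.

    ``detection`` maps compartment label to a detected flag; compartments
    are scanned in differentiation order (HSC first). The
    ``progenitor_origin`` flag marks mutations absent in assayed HSCs but
    present downstream — the signature of a lesion acquired at the
    progenitor level.
    """
    ordered = [c for c in hierarchy if c in detection]
    ordered += [c for c in detection if c not in hierarchy]
    origin = next((c for c in ordered if detection[c]), None)
    progenitor = (
        origin is not None
        and "HSC" in detection
        and not detection["HSC"]
        and origin != "HSC"
    )
    return OriginResult(origin, progenitor)
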