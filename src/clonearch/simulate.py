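"""Synthetic clone-architecture data generator.

Emulates the statistical structure the downstream analysis assumes:
heterozygous somatic mutations acquired along a clone tree, clone fractions
that drift mildly between sorted haematopoietic compartments, colonies
founded by single cells drawn from those fractions, amplicon read counts at
~800x coverage with symmetric per-read sequencing error, and
whole-genome-amplification artifacts (spurious variants, homopolymer-context
errors, allele dropout).

Ground-truth quantities (true MAB, colony founders, artifact labels) are
emitted alongside the observable tables; analysis operations never read
them — they exist so that filter performance and parameter recovery can be
measured against a known truth.

All randomness flows from ``SimulationConfig.seed`` through a named
generator per stage, so partial pipelines are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .tree import CloneTree

__all__ = [
    "CompartmentProfile",
    "stage_rng",
    "simulate_clone_tree",
    "assign_clone_fractions",
    "simulate_bulk_counts",
    "simulate_colonies",
    "inject_wga_artifacts",
    "simulate_loh_snps",
]

COMPARTMENTS = ("HSC", "MPP", "MLP", "CMP", "GMP", "MEP", "CD34+", "HEC", "LTC", "TNC")

_STAGE_IDS = {
    "tree": 1,
    "fractions": 2,
    "bulk": 3,
    "colonies": 4,
    "wga": 5,
    "loh": 6,
}

_BASES = np.array(list("ACGT"))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one simulator stage, derived from one seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_IDS[stage]]))


@dataclass
class CompartmentProfile:
    """Per-clone cell fractions in one sorted compartment at one time point.

    Fractions refer to cells whose genotype is *exactly* that clone's
    mutation set; the remainder up to 1 is wild type.
    """

    compartment: str
    fractions: dict[str, float]
    timepoint: str = "TP1"

    def validate(self) -> None:
        vals = np.asarray(list(self.fractions.values()), dtype=float)
        if (vals < -1e-12).any():
            raise ConfigurationError("clone fractions must be >= 0")
        if vals.sum() > 1.0 + 1e-9:
            raise ConfigurationError("clone fractions must sum to <= 1")

    @property
    def wildtype_fraction(self) -> float:
        return max(0.0, 1.0 - float(sum(self.fractions.values())))

    def mutation_prevalence(self, tree: CloneTree) -> dict[str, float]:
        """Fraction of cells carrying each mutation (sum over clones containing it)."""
        prev: dict[str, float] = {m: 0.0 for m in tree.mutations}
        sig = {c: tree.clones[c] for c in tree.clones}
        for clone, frac in self.fractions.items():
            for m in sig[clone]:
                prev[m] += frac
        return prev


def simulate_clone_tree(config: SimulationConfig) -> CloneTree:
    """Grow a clone tree by sequential mutation acquisition.

    Each of ``n_mutations`` mutations founds one new clone. With probability
    ``branching_prob`` the new clone branches off a uniformly chosen existing
    clone; otherwise it extends the most recently created clone, so a
    branching probability of 0 yields a single linear chain.
    """
    config.validate()
    rng = stage_rng(config.seed, "tree")
    clones: dict[str, frozenset[str]] = {"WT": frozenset()}
    parents: dict[str, str | None] = {"WT": None}
    order = ["WT"]
    last = "WT"
    for i in range(1, config.n_mutations + 1):
        mut = f"m{i:02d}"
        if last != "WT" and rng.random() < config.branching_prob:
            parent = order[int(rng.integers(len(order)))]
        else:
            parent = last
        cid = f"C{i:02d}"
        clones[cid] = clones[parent] | {mut}
        parents[cid] = parent
        order.append(cid)
        last = cid
    return CloneTree(clones, parents)


def assign_clone_fractions(
    tree: CloneTree,
    compartments: Sequence[str],
    config: SimulationConfig,
) -> list[CompartmentProfile]:
    """Draw per-compartment clone fractions around one shared base mixture.

    A base mixture over (clones + wild type) is drawn from a flat Dirichlet;
    each compartment perturbs the log-weights by N(0, drift) and
    renormalises. Drift 0 therefore reproduces identical fraction vectors in
    every compartment — the "MAB largely maintained across compartments"
    regime.
    """
    if not compartments:
        raise ConfigurationError("compartment list must be non-empty")
    config.validate()
    rng = stage_rng(config.seed, "fractions")
    clone_ids = sorted(c for c in tree.clones if c != tree.root)
    base = rng.dirichlet(np.ones(len(clone_ids) + 1))  # last slot = wild type
    profiles = []
    for comp in compartments:
        logw = np.log(np.clip(base, 1e-12, None))
        if config.drift > 0:
            logw = logw + rng.normal(0.0, config.drift, size=logw.shape)
        w = np.exp(logw - logw.max())
        w = w / w.sum()
        prof = CompartmentProfile(comp, dict(zip(clone_ids, w[:-1].tolist())))
        prof.validate()
        profiles.append(prof)
    return profiles


def _mutation_catalog(tree: CloneTree, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic per-mutation locus metadata (chrom, pos, alleles, flanks)."""
    muts = sorted(tree.mutations)
    rows = []
    for i, m in enumerate(muts):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        rows.append(
            {
                "mutation_id": m,
                "gene": f"GENE{i + 1:02d}",
                "chrom": "2" if i == 0 else str(1 + (i % 22)),
                "pos": 1000 * (i + 1) + 1,
                "ref": str(ref),
                "alt": str(alt),
                "flank_left": _clean_flank(rng),
                "flank_right": _clean_flank(rng),
            }
        )
    return pd.DataFrame(rows)


def _clean_flank(rng: np.random.Generator, length: int = 6) -> str:
    """Random flank free of homopolymer runs >= 5 (so it never trips the filter)."""
    while True:
        s = "".join(rng.choice(_BASES, size=length))
        if _max_run(s) < 5:
            return s


def _max_run(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def simulate_bulk_counts(
    profile: CompartmentProfile,
    tree: CloneTree,
    config: SimulationConfig,
    *,
    sample_id: str | None = None,
    source_class: str = "compartment",
    replicate_id: str = "r1",
    experiment_id: str = "exp1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate bulk amplicon allele counts for one compartment sample.

    For a heterozygous mutation carried by a cell fraction *f*, the expected
    mutant-read fraction is f/2; observed alt counts are binomial at the
    configured coverage after a symmetric per-read error flip. The returned
    table is the canonical variant-table dialect plus a ``true_mab`` ground
    truth column (never consumed by analysis operations).
    """
    config.validate()
    profile.validate()
    if config.coverage < 1:
        raise ConfigurationError("coverage must be >= 1")
    if not set(profile.fractions) <= set(tree.clones):
        raise ConfigurationError("profile and tree must share clone identifiers")
    if rng is None:
        rng = stage_rng(config.seed, "bulk")
    catalog = _mutation_catalog(tree, stage_rng(config.seed, "tree"))
    prev = profile.mutation_prevalence(tree)
    e = config.seq_error_rate
    rows = []
    sample = sample_id or f"{profile.compartment}_{profile.timepoint}"
    for _, loc in catalog.iterrows():
        m = loc["mutation_id"]
        true_mab = prev[m] / 2.0
        p_obs = true_mab * (1.0 - e) + (1.0 - true_mab) * e
        total = int(config.coverage)
        alt = int(rng.binomial(total, p_obs))
        fwd = int(rng.binomial(alt, 0.5))
        rows.append(
            {
                "sample_id": sample,
                "source_class": source_class,
                "replicate_id": replicate_id,
                "experiment_id": experiment_id,
                "mutation_id": m,
                "gene": loc["gene"],
                "chrom": loc["chrom"],
                "pos": int(loc["pos"]),
                "ref": loc["ref"],
                "alt": loc["alt"],
                "alt_reads": alt,
                "total_reads": total,
                "fwd_alt_reads": fwd,
                "rev_alt_reads": alt - fwd,
                "mean_align_score": 60.0,
                "mean_base_quality": 35.0,
                "flank_left": loc["flank_left"],
                "flank_right": loc["flank_right"],
                "wga": False,
                "pop_known": False,
                "pop_af": 0.0,
                "dup_region": False,
                "known_mutation": False,
                "bias_flag": False,
                "true_mab": true_mab,
            }
        )
    return pd.DataFrame(rows)


def simulate_colonies(
    profile: CompartmentProfile,
    tree: CloneTree,
    n_colonies: int,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate single-founder colony read counts.

    Each colony's founder clone is drawn i.i.d. from the profile's clone
    fractions (wild type with the residual probability); all cells of the
    colony share the founder genotype, so carried heterozygous mutations
    sequence at expectation 0.5 and non-carried ones at the error rate.

    Returns ``(reads, truth)``: a long table ``colony_id, mutation_id,
    alt_reads, total_reads`` and a ground-truth table mapping each colony to
    its founder clone and mutation set.
    """
    if n_colonies < 1:
        raise ConfigurationError("n_colonies must be >= 1")
    config.validate()
    profile.validate()
    if rng is None:
        rng = stage_rng(config.seed, "colonies")
    clone_ids = sorted(profile.fractions)
    probs = np.array([profile.fractions[c] for c in clone_ids] + [profile.wildtype_fraction])
    probs = probs / probs.sum()
    labels = clone_ids + [tree.root]
    muts = sorted(tree.mutations)
    e = config.seq_error_rate
    reads, truth = [], []
    for i in range(n_colonies):
        cid = f"colony{i + 1:03d}"
        founder = labels[int(rng.choice(len(labels), p=probs))]
        carried = tree.clones[founder]
        truth.append(
            {"colony_id": cid, "founder_clone": founder, "mutations": ";".join(sorted(carried))}
        )
        for m in muts:
            p = 0.5 if m in carried else e
            total = int(config.coverage)
            alt = int(rng.binomial(total, p))
            reads.append(
                {"colony_id": cid, "mutation_id": m, "alt_reads": alt, "total_reads": total}
            )
    return pd.DataFrame(reads), pd.DataFrame(truth)


def inject_wga_artifacts(
    table: pd.DataFrame,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlay WGA artifacts on a bulk variant table.

    Spurious variant records are injected per input locus with probability
    ``wga_artifact_rate``; a configurable fraction carry a homopolymer
    flanking context (run >= 5) and/or a positional/read-length bias mark.
    Allele dropout zeroes the alt or ref reads of existing records with
    probability ``wga_dropout_prob``.

    Returns ``(table, truth)`` where *truth* labels every output row with
    ``is_artifact`` and ``dropout_applied`` for filter-evaluation tests; the
    observable table itself only gains the WGA flag.
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "wga")
    out = table.copy().reset_index(drop=True)
    out["wga"] = True
    is_artifact = np.zeros(len(out), dtype=bool)
    dropout = np.zeros(len(out), dtype=bool)

    # allele dropout on existing heterozygous records
    for i in range(len(out)):
        if config.wga_dropout_prob > 0 and rng.random() < config.wga_dropout_prob:
            dropout[i] = True
            if rng.random() < 0.5:  # alt allele drops out
                out.loc[i, ["alt_reads", "fwd_alt_reads", "rev_alt_reads"]] = 0
            else:  # ref allele drops out -> apparent homozygous mutant
                total = int(out.loc[i, "total_reads"])
                alt = total
                fwd = int(rng.binomial(alt, 0.5))
                out.loc[i, ["alt_reads", "fwd_alt_reads", "rev_alt_reads"]] = [alt, fwd, alt - fwd]

    # spurious variants
    new_rows = []
    base_pos = int(out["pos"].max()) + 10_000 if len(out) else 10_000
    k = 0
    for i in range(len(out)):
        if rng.random() < config.wga_artifact_rate:
            k += 1
            proto = out.iloc[i].to_dict()
            frac = float(rng.uniform(0.05, 0.5))
            total = int(proto["total_reads"])
            alt = int(rng.binomial(total, frac))
            fwd = int(rng.binomial(alt, 0.5))
            homopoly = rng.random() < config.wga_homopolymer_frac
            ref, altb = rng.choice(_BASES, size=2, replace=False)
            row = dict(
                proto,
                mutation_id=f"art{k:03d}",
                gene=f"ARTGENE{k:02d}",
                pos=base_pos + 137 * k,
                ref=str(ref),
                alt=str(altb),
                alt_reads=alt,
                fwd_alt_reads=fwd,
                rev_alt_reads=alt - fwd,
                flank_left=("T" + str(ref) * 5) if homopoly else _clean_flank(rng),
                flank_right=_clean_flank(rng),
                bias_flag=bool(rng.random() < config.wga_bias_frac),
                true_mab=0.0,
            )
            new_rows.append(row)
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
        is_artifact = np.concatenate([is_artifact, np.ones(len(new_rows), dtype=bool)])
        dropout = np.concatenate([dropout, np.zeros(len(new_rows), dtype=bool)])
    truth = pd.DataFrame(
        {
            "mutation_id": out["mutation_id"],
            "sample_id": out["sample_id"],
            "is_artifact": is_artifact,
            "dropout_applied": dropout,
        }
    )
    return out, truth


def simulate_loh_snps(
    config: SimulationConfig,
    *,
    n_snps: int = 300,
    chrom: str = "7",
    region: tuple[int, int] | None = None,
    affected_fraction: float = 1.0,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate germline heterozygous SNP allele fractions along a chromosome.

    SNPs are evenly spaced; inside ``region`` (index range, half of the
    chromosome by default) a heterozygous deletion present in
    ``affected_fraction`` of cells shifts the retained-allele fraction to
    (1-f)/(2-f) or its mirror. Outside the region fractions are binomial
    around 0.5.
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "loh")
    d = int(depth if depth is not None else config.coverage)
    if region is None:
        region = (n_snps // 3, 2 * n_snps // 3)
    f = float(affected_fraction)
    shifted_low = (1.0 - f) / (2.0 - f)  # fraction of the deleted allele
    rows = []
    for i in range(n_snps):
        pos = 100_000 + 1_000 * i
        in_region = region[0] <= i < region[1]
        if in_region:
            p = shifted_low if rng.random() < 0.5 else 1.0 - shifted_low
        else:
            p = 0.5
        alt = int(rng.binomial(d, p))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "alt_fraction": alt / d,
                "depth": d,
                "pop_known": True,
                "pop_af": 0.25,
                "somatic": False,
                "dup_region": False,
                "normal_fraction": 0.5,
                "true_loh": bool(in_region),
            }
        )
    return pd.DataFrame(rows)
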