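"""End-to-end pipeline driver with run manifests.

Chains simulate -> filter -> mab -> colonies -> tree -> dynamics -> loh on
synthetic or file inputs. Every run writes a manifest (config snapshot,
seed, per-stage record counts, output digests) so that identical config and
seed reproduce byte-identical outputs, and record conservation
(passed <= called <= simulated) is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .architecture import enumerate_subclones, infer_clone_tree
from .colonies import build_genotype_matrix
from .config import FilterConfig, SimulationConfig
from .dynamics import clone_trajectory_table
from .filtering import AlleleCountRecord, filter_cascade, verdicts_to_frame
from .loh import allele_fraction_profile, detect_loh_segments, segments_to_bed, \
    select_informative_snps
from .quantify import mab_from_counts, pool_mab
from .simulate import (
    assign_clone_fractions,
    simulate_bulk_counts,
    simulate_clone_tree,
    simulate_colonies,
    simulate_loh_snps,
    stage_rng,
)

__all__ = ["RunManifest", "run_pipeline"]

DEFAULT_STAGES = ("simulate", "filter", "mab", "colonies", "tree", "dynamics", "loh")


@dataclass
class RunManifest:
    """Provenance record accompanying every pipeline run."""

    version: str
    seed: int
    config: dict[str, Any]
    stages: list[str] = field(default_factory=list)
    record_counts: dict[str, int] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    status: str = "ok"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    out_dir: str | Path,
    *,
    sim_config: SimulationConfig | None = None,
    filter_config: FilterConfig | None = None,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    n_colonies: int = 48,
    compartments: tuple[str, ...] = ("HSC", "MPP", "GMP", "MEP"),
    timestamps: bool = True,
) -> RunManifest:
    """Run the synthetic end-to-end pipeline, writing outputs and a manifest.

    Stage failure aborts downstream stages; the manifest records the partial
    state. With ``timestamps=False`` the manifest omits wall-clock times so
    that repeated runs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = sim_config or SimulationConfig()
    fcfg = filter_config or FilterConfig()
    scfg.validate()
    fcfg.validate()
    manifest = RunManifest(
        version=__version__,
        seed=scfg.seed,
        config={"simulation": scfg.to_dict(), "filter": fcfg.to_dict()},
        started=time.strftime("%Y-%m-%dT%H:%M:%S") if timestamps else "",
    )
    outputs: dict[str, Path] = {}

    try:
        bulk = colony_reads = None
        tree = None
        profiles = []
        if "simulate" in stages:
            tree = simulate_clone_tree(scfg)
            profiles = assign_clone_fractions(tree, list(compartments), scfg)
            rng = stage_rng(scfg.seed, "bulk")
            tables = [
                simulate_bulk_counts(p, tree, scfg, source_class="compartment", rng=rng)
                for p in profiles
            ]
            bulk = pd.concat(tables, ignore_index=True)
            outputs["bulk_counts.tsv"] = out / "bulk_counts.tsv"
            bulk.to_csv(outputs["bulk_counts.tsv"], sep="\t", index=False)
            tree.to_json(out / "true_tree.json")
            outputs["true_tree.json"] = out / "true_tree.json"
            manifest.record_counts["simulated"] = len(bulk)
            colony_reads, colony_truth = simulate_colonies(
                profiles[0], tree, n_colonies, scfg
            )
            outputs["colony_reads.tsv"] = out / "colony_reads.tsv"
            colony_reads.to_csv(outputs["colony_reads.tsv"], sep="\t", index=False)
            colony_truth.to_csv(out / "colony_truth.tsv", sep="\t", index=False)
            outputs["colony_truth.tsv"] = out / "colony_truth.tsv"
            manifest.stages.append("simulate")

        passed_df = None
        if "filter" in stages and bulk is not None:
            records = [AlleleCountRecord.from_mapping(r) for r in
                       bulk.drop(columns=["true_mab"]).to_dict("records")]
            normals = {
                m: AlleleCountRecord(
                    sample_id="normal_skin", mutation_id=m, alt_reads=0,
                    total_reads=scfg.coverage, source_class="normal_skin",
                    chrom=rec.chrom, pos=rec.pos,
                )
                for m, rec in {r.mutation_id: r for r in records}.items()
            }
            passed, verdicts = filter_cascade(records, fcfg, normals=normals)
            passed_keys = {(r.sample_id, r.mutation_id) for r in passed}
            mask = [
                (s, m) in passed_keys
                for s, m in zip(bulk["sample_id"], bulk["mutation_id"])
            ]
            passed_df = bulk[mask]
            log = verdicts_to_frame(verdicts)
            outputs["passed_variants.tsv"] = out / "passed_variants.tsv"
            passed_df.to_csv(outputs["passed_variants.tsv"], sep="\t", index=False)
            outputs["filter_log.tsv"] = out / "filter_log.tsv"
            log.to_csv(outputs["filter_log.tsv"], sep="\t", index=False)
            manifest.record_counts["filter_input"] = len(records)
            manifest.record_counts["filter_passed"] = len(passed)
            manifest.stages.append("filter")

        if "mab" in stages and passed_df is not None:
            ests = []
            for (mut, sample), grp in passed_df.groupby(["mutation_id", "sample_id"]):
                reps = [
                    mab_from_counts(int(r.alt_reads), int(r.total_reads),
                                    mutation_id=mut, sample_id=sample,
                                    ci_level=fcfg.ci_level,
                                    detection_floor=fcfg.detection_floor)
                    for r in grp.itertuples()
                ]
                e = pool_mab(reps, ci_level=fcfg.ci_level,
                             detection_floor=fcfg.detection_floor)
                ests.append({"mutation_id": mut, "sample_id": sample, "mab": e.mab,
                             "ci_low": e.ci_low, "ci_high": e.ci_high,
                             "n_replicates": e.n_replicates, "detected": e.detected})
            mab_table = pd.DataFrame(ests)
            outputs["mab_table.tsv"] = out / "mab_table.tsv"
            mab_table.to_csv(outputs["mab_table.tsv"], sep="\t", index=False)
            manifest.record_counts["mab_estimates"] = len(mab_table)
            manifest.stages.append("mab")

        matrix = None
        if "colonies" in stages and colony_reads is not None:
            matrix = build_genotype_matrix(colony_reads, config=fcfg)
            outputs["genotype_matrix.tsv"] = out / "genotype_matrix.tsv"
            matrix.to_tsv(outputs["genotype_matrix.tsv"])
            manifest.record_counts["colonies_called"] = len(matrix.colonies)
            manifest.stages.append("colonies")

        if "tree" in stages and matrix is not None:
            catalog = enumerate_subclones(matrix)
            inferred = infer_clone_tree(matrix)
            outputs["subclones.tsv"] = out / "subclones.tsv"
            catalog.to_frame().to_csv(outputs["subclones.tsv"], sep="\t", index=False)
            inferred.to_json(out / "inferred_tree.json")
            outputs["inferred_tree.json"] = out / "inferred_tree.json"
            manifest.record_counts["subclones"] = catalog.n_subclones
            manifest.stages.append("tree")

        if "dynamics" in stages and bulk is not None and tree is not None:
            prim = profiles[0].mutation_prevalence(tree)
            primary = {m: v / 2.0 for m, v in prim.items()}
            foll = profiles[-1].mutation_prevalence(tree)
            followup = {m: v / 2.0 for m, v in foll.items()}
            traj = clone_trajectory_table(
                primary, followup,
                detection_floor=fcfg.detection_floor,
                same_tolerance=fcfg.same_tolerance,
            )
            outputs["trajectories.tsv"] = out / "trajectories.tsv"
            traj.to_csv(outputs["trajectories.tsv"], sep="\t", index=False)
            manifest.record_counts["trajectories"] = len(traj)
            manifest.stages.append("dynamics")

        if "loh" in stages:
            snps = simulate_loh_snps(scfg, affected_fraction=0.9)
            informative = select_informative_snps(
                snps.drop(columns=["true_loh"]), fcfg
            )
            profile = allele_fraction_profile(informative, "7")
            segments = detect_loh_segments(profile, chrom="7", config=fcfg)
            outputs["loh_segments.bed"] = out / "loh_segments.bed"
            outputs["loh_segments.bed"].write_text(segments_to_bed(segments))
            manifest.record_counts["loh_segments"] = len(segments)
            manifest.stages.append("loh")

    except Exception as exc:  # record partial state, then re-raise
        manifest.status = f"failed: {exc}"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S") if timestamps else ""
        manifest.output_digests = {k: _digest(p) for k, p in outputs.items()}
        manifest.write(out / "manifest.json")
        raise

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S") if timestamps else ""
    manifest.output_digests = {k: _digest(p) for k, p in outputs.items()}
    manifest.write(out / "manifest.json")
    return manifest
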