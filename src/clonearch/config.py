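"""Configuration containers for the analysis pipeline.

Two dataclasses hold every numeric threshold used anywhere in the package:

* :class:`FilterConfig` — thresholds of the somatic-variant filter cascade,
  colony genotype calling, detection floors and LOH segmentation.
* :class:`SimulationConfig` — parameters of the synthetic clone simulator.

Both round-trip losslessly through YAML and JSON so that a pipeline run can
snapshot its exact configuration into the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ConfigurationError", "FilterConfig", "SimulationConfig"]


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its admissible range."""


@dataclass
class FilterConfig:
    """Thresholds of the variant-filter cascade and downstream calling rules.

    Defaults implement the published operating point of the study design this
    package reproduces: a somatic Fisher p below 0.01, at least 3 mutant
    reads, normal contamination below 20% (skin) or 50% (T cells), tumour
    allele burden above 5%, read-level exclusion at alignment score <10,
    base quality <15 and fold strand bias >10, homopolymer runs of >=5
    flanking the variant, population allele frequency 0.001, a >30% mutant
    read fraction for colony calls, and a 1% MAB detection floor at the
    reference amplicon coverage of 800x.
    """

    somatic_p_max: float = 0.01
    min_supporting_reads: int = 3
    normal_max_fraction_skin: float = 0.20
    normal_max_fraction_tcell: float = 0.50
    tumour_min_burden: float = 0.05
    min_alignment_score: float = 10.0
    min_base_quality: float = 15.0
    max_fold_strand_bias: float = 10.0
    pop_af_max: float = 0.001
    homopolymer_min_run: int = 5
    mds3_min_animals: int = 2  # "at least two of the three animal experiments"
    colony_mutant_threshold: float = 0.30
    min_colony_depth: int = 20
    detection_floor: float = 0.01
    reference_coverage: int = 800
    # read-count floor entering detection_limit(); 8/800 = 1% at reference depth
    min_detection_alt_reads: int = 8
    same_tolerance: float = 0.05  # absolute MAB tolerance for the "same" trajectory class
    ci_level: float = 0.95
    # LOH segmentation
    loh_min_depth: int = 20
    loh_window: int = 25
    loh_delta: float = 0.15
    loh_min_consecutive: int = 2
    loh_normal_het_low: float = 0.25
    loh_normal_het_high: float = 0.75
    # direction of the population-AF comparison when selecting informative
    # SNPs for LOH ("ge" keeps common polymorphisms; see docs/methods.md)
    loh_pop_af_direction: str = "ge"
    loh_pop_af_cut: float = 0.001

    def validate(self) -> None:
        for name in (
            "somatic_p_max", "normal_max_fraction_skin", "normal_max_fraction_tcell",
            "tumour_min_burden", "pop_af_max", "detection_floor", "same_tolerance",
            "ci_level", "colony_mutant_threshold", "loh_delta",
        ):
            v = getattr(self, name)
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in (
            "min_supporting_reads", "min_alignment_score", "min_base_quality",
            "max_fold_strand_bias", "homopolymer_min_run", "mds3_min_animals",
            "min_colony_depth", "reference_coverage", "min_detection_alt_reads",
            "loh_min_depth", "loh_window", "loh_min_consecutive",
        ):
            v = getattr(self, name)
            if float(v) < 0 or v != v:  # NaN check
                raise ConfigurationError(f"{name}={v} must be finite and non-negative")
        if self.reference_coverage < 1:
            raise ConfigurationError("reference_coverage must be >= 1")
        if self.loh_pop_af_direction not in ("ge", "lt"):
            raise ConfigurationError("loh_pop_af_direction must be 'ge' or 'lt'")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "FilterConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown filter-config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_file(self, path: str | Path) -> None:
        _dump_config(self.to_dict(), Path(path))

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        return cls.from_dict(_load_config(Path(path)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic clone simulator.

    The defaults are the study conditions the downstream analysis assumes:
    amplicon coverage 800x (the reference depth at which a 1% MAB is
    reliably detectable), heterozygous point mutations on a clone tree, and
    mild compartment-to-compartment drift of clone fractions. Error and WGA
    magnitudes are the package's own documented choices (see
    docs/methods.md); the study design quantifies neither.
    """

    n_mutations: int = 6
    branching_prob: float = 0.4
    drift: float = 0.02
    coverage: int = 800
    seq_error_rate: float = 0.002
    wga_artifact_rate: float = 0.05
    wga_dropout_prob: float = 0.05
    wga_homopolymer_frac: float = 0.5
    wga_bias_frac: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_mutations < 1:
            raise ConfigurationError("n_mutations must be >= 1")
        if self.coverage < 1:
            raise ConfigurationError("coverage must be >= 1")
        for name in (
            "branching_prob", "seq_error_rate", "wga_artifact_rate",
            "wga_dropout_prob", "wga_homopolymer_frac", "wga_bias_frac",
        ):
            v = getattr(self, name)
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.drift < 0:
            raise ConfigurationError("drift must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation-config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_file(self, path: str | Path) -> None:
        _dump_config(self.to_dict(), Path(path))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(_load_config(Path(path)))


def _dump_config(data: dict[str, Any], path: Path) -> None:
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def _load_config(path: Path) -> dict[str, Any]:
    text = Path(path).read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
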