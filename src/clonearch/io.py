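"""Tabular dialects and validated readers/writers.

TSV is the canonical interchange format for every table in the pipeline;
the column schemas live here and are documented in docs/tables.md. VCF
ingestion (via cyvcf2) is a mapped convenience that produces the same
variant records as the equivalent TSV. Malformed rows are collected into an
error report rather than silently dropped: input rows always equal accepted
plus rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "VARIANT_COLUMNS",
    "VARIANT_REQUIRED",
    "COLONY_COLUMNS",
    "SNP_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "read_colony_table",
    "read_snp_table",
    "read_vcf_variants",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


# canonical variant-table dialect (see docs/tables.md)
VARIANT_REQUIRED = [
    "sample_id", "mutation_id", "chrom", "pos", "ref", "alt",
    "alt_reads", "total_reads",
]
VARIANT_OPTIONAL = {
    "source_class": "compartment",
    "replicate_id": "r1",
    "experiment_id": "exp1",
    "gene": "",
    "fwd_alt_reads": 0,
    "rev_alt_reads": 0,
    "mean_align_score": 60.0,
    "mean_base_quality": 35.0,
    "flank_left": "",
    "flank_right": "",
    "wga": False,
    "pop_known": False,
    "pop_af": 0.0,
    "dup_region": False,
    "known_mutation": False,
    "bias_flag": False,
}
VARIANT_COLUMNS = VARIANT_REQUIRED + list(VARIANT_OPTIONAL)

COLONY_COLUMNS = ["colony_id", "mutation_id", "alt_reads", "total_reads"]
SNP_COLUMNS = ["chrom", "pos", "alt_fraction", "depth", "pop_known",
               "pop_af", "somatic", "dup_region"]

_BOOL_COLUMNS = ("wga", "pop_known", "dup_region", "known_mutation",
                 "bias_flag", "somatic")


def _coerce_bools(df: pd.DataFrame) -> pd.DataFrame:
    for col in _BOOL_COLUMNS:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map(
                {"True": True, "False": False, "true": True, "false": False,
                 "1": True, "0": False, True: True, False: False}
            ).astype(bool)
    return df


def _validate_variant_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into accepted rows and rejected rows with reasons."""
    reasons = pd.Series("", index=df.index)
    bad = df["alt_reads"] > df["total_reads"]
    reasons[bad] = "alt_reads > total_reads"
    bad2 = (df["alt_reads"] < 0) | (df["total_reads"] < 0)
    reasons[bad2 & (reasons == "")] = "negative read count"
    bad3 = df["pos"] < 1
    reasons[bad3 & (reasons == "")] = "position < 1"
    if {"fwd_alt_reads", "rev_alt_reads"} <= set(df.columns):
        strand = df["fwd_alt_reads"] + df["rev_alt_reads"]
        bad4 = (strand != 0) & (strand != df["alt_reads"])
        reasons[bad4 & (reasons == "")] = "strand counts do not sum to alt_reads"
    rejected = df[reasons != ""].copy()
    rejected["error"] = reasons[reasons != ""]
    return df[reasons == ""].copy(), rejected


def read_variant_table(path: str | Path, dialect: str = "tsv") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a variant table; returns (accepted, rejected-with-reason).

    ``dialect`` is ``tsv`` or ``vcf``. Missing required columns raise
    :class:`SchemaError` naming the column; rows violating record
    invariants land in the rejection report.
    """
    if dialect == "vcf":
        df = read_vcf_variants(path)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in VARIANT_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    for col, default in VARIANT_OPTIONAL.items():
        if col not in df.columns:
            df[col] = default
    df = _coerce_bools(df)
    df["chrom"] = df["chrom"].astype(str)
    return _validate_variant_rows(df)


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def read_colony_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in COLONY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    return df


def read_snp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in SNP_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    df = _coerce_bools(df)
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_vcf_variants(path: str | Path, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Map a VCF with AD-style depth fields onto the variant-table dialect.

    Per-sample alt/ref depths come from FORMAT/AD; population allele
    frequency from INFO/AF (``pop_known`` true when present). One output
    row per sample per variant.
    """
    from cyvcf2 import VCF  # imported lazily; only VCF ingestion needs it

    vcf = VCF(str(path))
    samples = list(sample_ids) if sample_ids else list(vcf.samples)
    rows = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            continue
        af = var.INFO.get("AF")
        gene = var.INFO.get("GENE") or ""
        for si, sample in enumerate(vcf.samples):
            if sample not in samples:
                continue
            ref_d, alt_d = int(ad[si][0]), int(ad[si][1])
            if ref_d < 0 or alt_d < 0:  # missing AD encodes as negative
                continue
            rows.append({
                "sample_id": sample,
                "mutation_id": var.ID or f"{var.CHROM}:{var.POS}{var.REF}>{var.ALT[0]}",
                "gene": gene,
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "alt_reads": alt_d,
                "total_reads": ref_d + alt_d,
                "pop_known": af is not None,
                "pop_af": float(af) if af is not None else 0.0,
            })
    return pd.DataFrame(rows)
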