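"""Readers and writers for the pipeline's tabular formats.

Variant tables travel either as a TSV dialect with columns
``chrom, pos, ref, alt, gene, effect, af, alt_reads, depth`` (1-based
positions) or as VCF v4.2 with ``AF``/``AD``/``DP`` in FORMAT and
``GENE``/``EFFECT`` INFO tags.  Copy ratios are a ``sample_id, gene, fold``
TSV; the clinical table is a CSV keyed by patient and sample.  The WBC
artifact database and the healthy-plasma background error model round-trip
through TSVs with ``#`` metadata headers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "effect", "af", "alt_reads", "depth"]
CLINICAL_COLUMNS = [
    "patient_id", "sample_id", "date", "timepoint", "response",
    "cea_ng_ml", "anc", "amc", "alc", "tissue_her2",
]


class InputValidationError(ValueError):
    """A malformed input table; message carries file and row context."""


def variant_key(row) -> tuple:
    """Allele-specific site key (chrom, pos, ref, alt) — VCF semantics."""
    return (row["chrom"], int(row["pos"]), row["ref"], row["alt"])


def add_variant_keys(df: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``key`` column of (chrom, pos, ref, alt) tuples."""
    df = df.copy()
    if len(df):
        df["key"] = list(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))
    else:
        df["key"] = pd.Series(dtype=object)
    return df


def _validate_variants(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise InputValidationError(f"{source}: missing columns {missing}")
    df = df[VARIANT_COLUMNS].copy()
    df["pos"] = df["pos"].astype(int)
    df["af"] = df["af"].astype(float)
    df["alt_reads"] = df["alt_reads"].astype(int)
    df["depth"] = df["depth"].astype(int)
    bad_af = df.index[(df["af"] < 0) | (df["af"] > 1)]
    if len(bad_af):
        raise InputValidationError(f"{source}: AF outside [0, 1] at row {bad_af[0] + 2}")
    bad_reads = df.index[df["alt_reads"] > df["depth"]]
    if len(bad_reads):
        raise InputValidationError(
            f"{source}: alt_reads > depth at row {bad_reads[0] + 2}"
        )
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant table (TSV dialect, or VCF when the suffix is .vcf)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_variant_vcf(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return _validate_variants(df, str(path))


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df = df[VARIANT_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_variant_vcf(path: str | Path) -> pd.DataFrame:
    """Read the first sample of a VCF into the variant-table frame.

    AF comes from FORMAT/AF when present, else AD/DP; GENE and EFFECT from
    INFO tags (blank when absent).
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        if not list(vf.header.samples):
            raise InputValidationError(f"{path}: VCF has no sample columns")
        sample = list(vf.header.samples)[0]
        for rec in vf:
            call = rec.samples[sample]
            depth = call.get("DP") or 0
            ad = call.get("AD")
            for i, alt in enumerate(rec.alts or ()):
                alt_reads = int(ad[i + 1]) if ad is not None and len(ad) > i + 1 else 0
                af = call.get("AF")
                if af is not None:
                    af_val = float(af[i] if isinstance(af, tuple) else af)
                elif depth:
                    af_val = alt_reads / depth
                else:
                    af_val = 0.0
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "gene": rec.info.get("GENE", ""),
                        "effect": rec.info.get("EFFECT", "other"),
                        "af": af_val,
                        "alt_reads": alt_reads,
                        "depth": int(depth),
                    }
                )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return _validate_variants(df, str(path))


def read_copy_ratios(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "gene", "fold") if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")
    df["fold"] = df["fold"].astype(float)
    if (df["fold"] < 0).any():
        row = df.index[df["fold"] < 0][0]
        raise InputValidationError(f"{path}: negative fold at row {row + 2}")
    return df


def write_copy_ratios(df: pd.DataFrame, path: str | Path) -> None:
    df[["sample_id", "gene", "fold"]].to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    for col in ("cea_ng_ml", "anc", "amc", "alc"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["response"] = df["response"].fillna("")
    df["tissue_her2"] = df["tissue_her2"].fillna("")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[CLINICAL_COLUMNS].to_csv(path, index=False)


def read_wbc_database(path: str | Path):
    """Read the WBC artifact occurrence table; returns (DataFrame, total)."""
    total = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#total_samples="):
                total = int(line.strip().split("=", 1)[1])
            if not line.startswith("#"):
                break
    if total is None:
        raise InputValidationError(f"{path}: missing '#total_samples=' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    if (df["count"] > total).any():
        raise InputValidationError(f"{path}: occurrence count exceeds total_samples")
    return df, total


def write_wbc_database(df: pd.DataFrame, total_samples: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#total_samples={total_samples}\n")
        df[["chrom", "pos", "ref", "alt", "count"]].to_csv(fh, sep="\t", index=False)


def write_removal_log(log: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "pos", "ref", "alt", "gene", "af", "reason", "detail"]
    log[cols].to_csv(path, sep="\t", index=False)
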