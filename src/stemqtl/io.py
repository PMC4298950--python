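"""Readers for the TSV/GTF/FASTA/TRANSFAC fixture formats.

All on-disk coordinates follow the usual conventions (GTF and the SNP
position table are 1-based; CNV segments and ChIP regions are BED-like,
0-based half-open); loaders convert to the internal 0-based half-open
representation.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression_qc import PROBE_META_COLS
from .genotype_qc import GenotypeMatrix

__all__ = [
    "read_samples",
    "read_genotypes",
    "read_cnv_segments",
    "read_probe_table",
    "read_chip_regions",
    "read_expression",
]


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError("samples file needs 'sample' and 'group' columns")
    return df


def read_genotypes(snps_path, calls_path, confidences_path) -> GenotypeMatrix:
    snps = pd.read_csv(snps_path, sep="\t")
    snps["pos"] = snps.pos - 1  # 1-based on disk
    calls = pd.read_csv(calls_path, sep="\t", index_col="snp_id")
    conf = pd.read_csv(confidences_path, sep="\t", index_col="snp_id")
    return GenotypeMatrix(snps=snps, calls=calls.astype(int), confidences=conf)


def read_cnv_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "chrom", "start", "end", "state", "n_markers"}
    if not need <= set(df.columns):
        raise ValueError(f"CNV segment file needs columns {sorted(need)}")
    return df


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns {sorted(missing)}")
    df["probeset_id"] = df.probeset_id.fillna("")
    for col in ("is_antigenomic", "is_crosshyb", "overlaps_snp"):
        df[col] = df[col].astype(bool)
    return df


def read_chip_regions(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "tf_name"]
    )
    return df[["tf_name", "chrom", "start", "end"]]


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def dataset_paths(directory) -> dict[str, Path]:
    d = Path(directory)
    return {
        "samples": d / "samples.tsv",
        "annotation": d / "annotation.gtf",
        "snps": d / "snps.tsv",
        "genotypes": d / "genotypes.tsv",
        "confidences": d / "confidences.tsv",
        "cnv_segments": d / "cnv_segments.tsv",
        "probes": d / "probes.tsv",
        "motifs": d / "motifs.transfac",
        "alleles": d / "allele_flanks.fasta",
        "chip_regions": d / "chip_regions.bed",
        "truth": d / "truth.json",
    }
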