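"""SNP-side quality filters: genetic variation, call confidence, CNV regions.

Genotype calls are coded 1 (homozygous reference), 2 (heterozygous),
3 (homozygous alternate).  Three per-SNP predicates are applied before
association testing:

* variation  — SNPs with less than 25% genetic variation among the analyzed
  samples are removed (default metric: minor-allele frequency; a
  genotype-fraction alternative is available),
* confidence — a SNP is removed if any sample's call confidence is below 0.9,
* regions    — SNPs inside reported CNV regions of any analyzed sample, or on
  a mosaic-gained chromosome of any sample, are removed.

Each predicate is independent of the others, so the filters commute; the
pipeline applies them in a fixed order only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExclusionRegions",
    "genotype_variation",
    "genotype_fraction_variation",
    "filter_low_variation",
    "filter_low_confidence",
    "exclude_region_snps",
]


@dataclass
class GenotypeMatrix:
    """SNP x sample calls with per-call confidences and SNP coordinates.

    ``snps`` columns: snp_id, chrom, pos (0-based point), ref, alt.
    ``calls`` and ``confidences`` are DataFrames indexed by snp_id with one
    column per sample; calls take values in {1, 2, 3}, confidences in (0, 1].
    """

    snps: pd.DataFrame
    calls: pd.DataFrame
    confidences: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.shape != self.confidences.shape:
            raise ValueError("calls and confidences must share shape")
        if not self.calls.index.equals(self.confidences.index):
            raise ValueError("calls and confidences must share the SNP index")
        if not set(np.unique(self.calls.to_numpy())) <= {1, 2, 3}:
            raise ValueError("genotype calls must be coded 1/2/3")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def snp_ids(self) -> pd.Index:
        return self.calls.index

    def subset(self, snp_ids) -> "GenotypeMatrix":
        keep = self.calls.index.isin(set(snp_ids))
        return GenotypeMatrix(
            snps=self.snps[self.snps.snp_id.isin(set(snp_ids))].reset_index(drop=True),
            calls=self.calls.loc[keep],
            confidences=self.confidences.loc[keep],
        )


@dataclass
class ExclusionRegions:
    """CNV intervals (per sample) and mosaic-gained chromosomes (sample, chrom).

    ``regions`` columns: sample, chrom, start, end (0-based half-open).
    """

    regions: pd.DataFrame
    mosaic: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.regions) and (self.regions.start >= self.regions.end).any():
            raise ValueError("exclusion intervals must satisfy start < end")


def genotype_variation(calls) -> float:
    """Minor-allele frequency of one SNP from its 1/2/3 calls, in [0, 0.5]."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("need at least one call")
    alt = float((calls - 1).sum())
    f = alt / (2 * calls.size)
    return min(f, 1.0 - f)


def genotype_fraction_variation(calls) -> float:
    """Fraction of samples carrying a non-modal genotype (alternative metric)."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("need at least one call")
    _, counts = np.unique(calls, return_counts=True)
    return 1.0 - counts.max() / calls.size


def _variation_per_snp(calls: pd.DataFrame, metric: str) -> pd.Series:
    arr = calls.to_numpy()
    n = arr.shape[1]
    if metric == "maf":
        f = (arr - 1).sum(axis=1) / (2 * n)
        v = np.minimum(f, 1 - f)
    elif metric == "genotype_fraction":
        v = np.array([genotype_fraction_variation(row) for row in arr])
    else:
        raise ValueError(f"unknown variation metric: {metric!r}")
    return pd.Series(v, index=calls.index)


def filter_low_variation(
    genotypes: GenotypeMatrix,
    threshold: float = 0.25,
    group: list[str] | None = None,
    metric: str = "maf",
) -> GenotypeMatrix:
    """Keep SNPs whose variation within ``group`` is >= threshold.

    The quoted rule removes SNPs with *less than* 25% variation, so a SNP at
    exactly the threshold is kept.  ``group`` defaults to all samples.
    """
    samples = group if group is not None else genotypes.samples
    if len(samples) == 0:
        raise ValueError("empty sample group")
    missing = set(samples) - set(genotypes.samples)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")
    v = _variation_per_snp(genotypes.calls[list(samples)], metric)
    return genotypes.subset(v.index[v >= threshold])


def filter_low_confidence(genotypes: GenotypeMatrix, min_conf: float = 0.9) -> GenotypeMatrix:
    """Remove a SNP if any sample's confidence is strictly below ``min_conf``."""
    ok = (genotypes.confidences >= min_conf).all(axis=1)
    return genotypes.subset(genotypes.confidences.index[ok])


def exclude_region_snps(genotypes: GenotypeMatrix, regions: ExclusionRegions) -> GenotypeMatrix:
    """Remove SNPs inside any sample's CNV region or on any mosaic-gained chromosome."""
    snps = genotypes.snps
    drop = np.zeros(len(snps), dtype=bool)
    for chrom, sub in regions.regions.groupby("chrom") if len(regions.regions) else []:
        on_chrom = snps.chrom.to_numpy() == chrom
        pos = snps.pos.to_numpy()
        hit = np.zeros(len(snps), dtype=bool)
        for s, e in zip(sub.start.to_numpy(), sub.end.to_numpy()):
            hit |= (pos >= s) & (pos < e)
        drop |= on_chrom & hit
    mosaic_chroms = {chrom for _, chrom in regions.mosaic}
    if mosaic_chroms:
        drop |= snps.chrom.isin(mosaic_chroms).to_numpy()
    return genotypes.subset(snps.snp_id[~drop])
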