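"""Probe-level QC cascade and probeset summarization for exon-array data.

The cascade removes unreliable probes before any association testing:

1. background   — a probe is kept only if its maximum intensity across samples
   exceeds a GC-content-specific limit, defined per GC bin as mean + 2 SD of
   the antigenomic control probes in that bin (antigenomic probes have no
   genomic target, so they measure pure GC-dependent background),
2. flags        — probes that may cross-hybridize, and probes whose sequence
   contains a SNP, are removed (flags consumed as precomputed annotation),
3. small sets   — probesets left with fewer than ``min_probes`` (default 3)
   surviving probes are masked out entirely.

Surviving probesets are summarized to one value per feature and sample as the
mean of log2 intensities, a declared stand-in for RMA summarization; the QC
decisions themselves follow the published cascade exactly.

Probe tables are plain DataFrames with columns
``probe_id, probeset_id, level, gc, is_antigenomic, is_crosshyb, overlaps_snp``
followed by one linear-scale intensity column per sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PROBE_META_COLS",
    "sample_columns",
    "compute_background_thresholds",
    "filter_background_probes",
    "filter_flagged_probes",
    "mask_small_probesets",
    "summarize_probesets",
    "run_expression_qc",
]

PROBE_META_COLS = [
    "probe_id",
    "probeset_id",
    "level",
    "gc",
    "is_antigenomic",
    "is_crosshyb",
    "overlaps_snp",
]


def sample_columns(probes: pd.DataFrame) -> list[str]:
    return [c for c in probes.columns if c not in PROBE_META_COLS]


def compute_background_thresholds(probes: pd.DataFrame) -> pd.Series:
    """Per-GC-bin background limit: mean + 2 SD of antigenomic intensities.

    All intensity values of the bin's antigenomic probes (across samples) are
    pooled; the SD uses the n-1 denominator, and a single-value bin gets SD 0.
    Raises if a GC bin seen among genomic probes has no antigenomic probes.
    """
    anti = probes[probes.is_antigenomic]
    genomic_bins = set(probes.loc[~probes.is_antigenomic, "gc"].unique())
    missing = sorted(genomic_bins - set(anti.gc.unique()))
    if missing:
        raise ValueError(f"no antigenomic probes for GC bin(s): {missing}")
    cols = sample_columns(probes)
    limits = {}
    for gc, sub in anti.groupby("gc"):
        vals = sub[cols].to_numpy(dtype=float).ravel()
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        limits[gc] = float(vals.mean()) + 2.0 * sd
    return pd.Series(limits, name="limit").sort_index()


def filter_background_probes(probes: pd.DataFrame, thresholds: pd.Series) -> pd.DataFrame:
    """Keep genomic probes whose max intensity across samples strictly exceeds
    the limit of their GC bin; antigenomic probes are dropped from the output."""
    genomic = probes[~probes.is_antigenomic]
    cols = sample_columns(probes)
    max_int = genomic[cols].to_numpy(dtype=float).max(axis=1)
    limit = thresholds.reindex(genomic.gc).to_numpy()
    return genomic[max_int > limit].reset_index(drop=True)


def filter_flagged_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Remove probes flagged as cross-hybridizing or SNP-overlapping."""
    keep = ~(probes.is_crosshyb | probes.overlaps_snp)
    return probes[keep].reset_index(drop=True)


def mask_small_probesets(probes: pd.DataFrame, min_probes: int = 3) -> pd.DataFrame:
    """Drop every probeset with fewer than ``min_probes`` surviving probes."""
    counts = probes.groupby("probeset_id")["probe_id"].transform("size")
    return probes[counts >= min_probes].reset_index(drop=True)


def summarize_probesets(probes: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Feature x sample log2 expression per level: mean of log2 intensities."""
    cols = sample_columns(probes)
    out = {}
    for level, sub in probes.groupby("level"):
        logged = sub[["probeset_id"] + cols].copy()
        logged[cols] = np.log2(logged[cols].to_numpy(dtype=float))
        mat = logged.groupby("probeset_id")[cols].mean()
        mat.index.name = "feature_id"
        out[level] = mat.sort_index()
    return out


def run_expression_qc(
    probes: pd.DataFrame, min_probes: int = 3
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict]:
    """Full cascade in its fixed order; returns (expression per level,
    surviving probe table, count report per step and level)."""
    thresholds = compute_background_thresholds(probes)
    genomic = probes[~probes.is_antigenomic]
    after_bg = filter_background_probes(probes, thresholds)
    after_flags = filter_flagged_probes(after_bg)
    after_mask = mask_small_probesets(after_flags, min_probes=min_probes)
    expr = summarize_probesets(after_mask)

    def _counts(df: pd.DataFrame) -> dict:
        return {
            "probes": int(len(df)),
            "probesets": {
                str(level): int(df[df.level == level].probeset_id.nunique())
                for level in sorted(genomic.level.unique())
            },
        }

    report = {
        "thresholds": {int(k): float(v) for k, v in thresholds.items()},
        "input": _counts(genomic),
        "after_background_filter": _counts(after_bg),
        "after_flag_filter": _counts(after_flags),
        "after_small_probeset_mask": _counts(after_mask),
        "min_probes": min_probes,
    }
    return expr, after_mask, report
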