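"""Copy-number vs expression integration: state labelling, weight statistic,
permutation p-values and fold changes.

Per-sample CNV segments (gain/loss, with marker counts) are first filtered by
minimum marker count and length, then projected onto genes: a gene is labelled
``gain`` or ``loss`` in a sample when its span overlaps a surviving segment of
that state by at least one base; overlap with both states in one sample gives
``ambiguous`` (excluded from testing); otherwise ``normal``.

For every gene altered in at least one sample the weight statistic

    w = (m_altered - m_normal) / (sd_altered + sd_normal)

is computed per direction (the loss direction flips the numerator so positive
weight always means the expected shift), a one-sided permutation p-value is
attached, and p-values are BH-adjusted within each direction family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import FeatureAnnotation
from .stats import bh_adjust, perm_index_masks, permutation_pvalue, weight_from_values

__all__ = [
    "CNVGroupSummary",
    "filter_segments",
    "label_gene_states",
    "weight_statistic",
    "loss_weight",
    "fold_change",
    "run_cnv_scan",
]

STATES = ("gain", "loss")


@dataclass
class CNVGroupSummary:
    """Group moments feeding the weight statistic (n-1 SD, singleton SD 0)."""

    m_altered: float
    sd_altered: float
    m_normal: float
    sd_normal: float
    n_altered: int
    n_normal: int

    @classmethod
    def from_values(cls, altered, normal) -> "CNVGroupSummary":
        altered = np.asarray(altered, dtype=float)
        normal = np.asarray(normal, dtype=float)
        if altered.size == 0 or normal.size == 0:
            raise ValueError("both groups must be nonempty")
        return cls(
            m_altered=float(altered.mean()),
            sd_altered=float(altered.std(ddof=1)) if altered.size > 1 else 0.0,
            m_normal=float(normal.mean()),
            sd_normal=float(normal.std(ddof=1)) if normal.size > 1 else 0.0,
            n_altered=int(altered.size),
            n_normal=int(normal.size),
        )


def _weight(num: float, den: float) -> float:
    if den == 0.0:
        return 0.0 if num == 0.0 else float(np.sign(num) * np.inf)
    return num / den


def weight_statistic(summary: CNVGroupSummary) -> float:
    """Gain-direction weight (m_altered - m_normal) / (sd_altered + sd_normal)."""
    return _weight(summary.m_altered - summary.m_normal, summary.sd_altered + summary.sd_normal)


def loss_weight(summary: CNVGroupSummary) -> float:
    """Loss-direction weight (m_normal - m_loss) / (sd_loss + sd_normal):
    positive when the lost samples express the gene lower."""
    return _weight(summary.m_normal - summary.m_altered, summary.sd_altered + summary.sd_normal)


def fold_change(summary: CNVGroupSummary) -> tuple[float, float]:
    """(log2 fold change altered vs normal, linear fold change 2**log2fc)."""
    log2_fc = summary.m_altered - summary.m_normal
    return log2_fc, float(2.0**log2_fc)


def filter_segments(
    segments: pd.DataFrame, min_markers: int = 5, min_length_bp: int = 10_000
) -> pd.DataFrame:
    """Keep segments with at least ``min_markers`` markers and length >= ``min_length_bp``."""
    bad = set(segments.state.unique()) - set(STATES)
    if bad:
        raise ValueError(f"unknown CNV state(s): {sorted(bad)}")
    length = segments.end - segments.start
    keep = (segments.n_markers >= min_markers) & (length >= min_length_bp)
    return segments[keep].reset_index(drop=True)


def label_gene_states(
    annotation: FeatureAnnotation,
    segments: pd.DataFrame,
    samples: list[str],
    min_markers: int = 5,
    min_length_bp: int = 10_000,
) -> pd.DataFrame:
    """Gene x sample state matrix over {gain, normal, loss, ambiguous}.

    ``segments`` columns: sample, chrom, start, end, state, n_markers
    (0-based half-open intervals).
    """
    surviving = filter_segments(segments, min_markers, min_length_bp)
    genes = annotation.genes
    labels = pd.DataFrame("normal", index=list(genes.gene_id), columns=list(samples))
    labels.index.name = "gene_id"
    for _, seg in surviving.iterrows():
        if seg["sample"] not in labels.columns:
            continue
        hit = genes[
            (genes.chrom == seg.chrom) & (genes.start < seg.end) & (genes.end > seg.start)
        ]
        for gid in hit.gene_id:
            current = labels.at[gid, seg["sample"]]
            if current == "normal" or current == seg.state:
                labels.at[gid, seg["sample"]] = seg.state
            else:
                labels.at[gid, seg["sample"]] = "ambiguous"
    return labels


def run_cnv_scan(
    expression: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
    exhaustive_if_possible: bool = True,
) -> pd.DataFrame:
    """Test every gene altered in >= 1 sample, separately per direction.

    ``expression`` is gene x sample log2 values; ``labels`` the state matrix.
    For each direction only that direction's samples and the normal samples
    enter the test (the other state and ambiguous samples are excluded).
    BH adjustment is applied within each direction family.  Genes whose
    expression shifts against the direction are kept in the output with
    ``opposite_direction=True``; significance is only claimed at
    adjusted p < alpha.
    """
    if not set(labels.columns) == set(expression.columns):
        raise ValueError("expression and labels must cover the same samples")
    samples = list(expression.columns)
    labels = labels[samples]
    mask_cache: dict[tuple[int, int], tuple[np.ndarray, bool]] = {}
    records = []
    common_genes = [g for g in labels.index if g in expression.index]
    for direction in STATES:
        for gene in common_genes:
            state = labels.loc[gene]
            altered_samples = [s for s in samples if state[s] == direction]
            normal_samples = [s for s in samples if state[s] == "normal"]
            if not altered_samples or not normal_samples:
                continue
            x = expression.loc[gene, altered_samples + normal_samples].to_numpy(dtype=float)
            altered_mask = np.zeros(x.size, dtype=bool)
            altered_mask[: len(altered_samples)] = True
            n, k = x.size, len(altered_samples)
            if (n, k) not in mask_cache:
                mask_cache[(n, k)] = perm_index_masks(
                    n, k, n_perm, seed=[seed, n, k], exhaustive_if_possible=exhaustive_if_possible
                )
            masks, exact = mask_cache[(n, k)]
            summary = CNVGroupSummary.from_values(x[altered_mask], x[~altered_mask])
            w = weight_statistic(summary) if direction == "gain" else loss_weight(summary)
            p, was_exact = permutation_pvalue(
                x,
                altered_mask,
                direction=direction,
                alternative=alternative,
                masks=masks,
                exact=exact,
            )
            p = max(p, np.nextafter(0.0, 1.0)) if p == 0.0 else p
            log2_fc, linear_fc = fold_change(summary)
            records.append(
                {
                    "gene_id": gene,
                    "direction": direction,
                    "n_altered": summary.n_altered,
                    "n_normal": summary.n_normal,
                    "weight": w,
                    "log2_fc": log2_fc,
                    "linear_fc": linear_fc,
                    "raw_p": p,
                    "exact_null": was_exact,
                    "opposite_direction": bool(w < 0),
                }
            )
    result = pd.DataFrame(
        records,
        columns=[
            "gene_id",
            "direction",
            "n_altered",
            "n_normal",
            "weight",
            "log2_fc",
            "linear_fc",
            "raw_p",
            "exact_null",
            "opposite_direction",
        ],
    )
    if len(result) == 0:
        result["adjusted_p"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["adjusted_p"] = np.nan
    for direction in STATES:
        idx = result.direction == direction
        if idx.any():
            result.loc[idx, "adjusted_p"] = bh_adjust(result.loc[idx, "raw_p"])
    result["significant"] = result.adjusted_p < alpha
    return result.sort_values(["direction", "adjusted_p", "gene_id"]).reset_index(drop=True)
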