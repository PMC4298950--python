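"""SNP-to-feature linking, genotype regression scans and overlap summaries.

SNPs are linked to expression features at four interval definitions:

* gene        — SNP within the gene span or up to 5000 bp up/downstream,
* transcript  — SNP within the transcript span (introns included, no flank),
* exon_short  — SNP within the exon or in an intron immediately adjacent to
  it in any parent transcript,
* exon_long   — SNP anywhere in the exon's parent gene span.

For every linked pair an ordinary least-squares regression of log2 expression
on the numeric genotype code (1/2/3; slope units are per allele) yields a
two-sided t-test p-value; p-values are BH-adjusted within each
(level, sample-group) family.  Linking is unstranded; all boundaries are
inclusive on the 1-based closed input convention (internally 0-based
half-open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import FeatureAnnotation
from .genotype_qc import GenotypeMatrix, _variation_per_snp
from .stats import bh_adjust

__all__ = [
    "LEVELS",
    "RegressionResult",
    "link_gene",
    "link_transcript",
    "link_exon_short",
    "link_exon_long",
    "link_all_levels",
    "fit_genotype_regression",
    "run_snp_scan",
    "summarize_overlaps",
    "cross_reference_cnv",
]

LEVELS = ("gene", "transcript", "exon_short", "exon_long")
PAIR_COLS = ["snp_id", "feature_id", "level", "snp_inside_feature"]


def _pairs_from_windows(
    snps: pd.DataFrame, windows: pd.DataFrame, level: str
) -> pd.DataFrame:
    """All (snp, feature) pairs with snp.pos in [win_start, win_end) on the
    same chromosome; ``windows`` needs feature_id, chrom, win_start, win_end,
    feat_start, feat_end columns."""
    out = []
    for chrom, w in windows.groupby("chrom"):
        s = snps[snps.chrom == chrom]
        if len(s) == 0 or len(w) == 0:
            continue
        pos = s.pos.to_numpy()[:, None]
        inside_win = (pos >= w.win_start.to_numpy()) & (pos < w.win_end.to_numpy())
        si, fi = np.nonzero(inside_win)
        inside_feat = (pos >= w.feat_start.to_numpy()) & (pos < w.feat_end.to_numpy())
        out.append(
            pd.DataFrame(
                {
                    "snp_id": s.snp_id.to_numpy()[si],
                    "feature_id": w.feature_id.to_numpy()[fi],
                    "level": level,
                    "snp_inside_feature": inside_feat[si, fi],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=PAIR_COLS)
    return (
        pd.concat(out, ignore_index=True)
        .drop_duplicates(["snp_id", "feature_id"])
        .sort_values(["snp_id", "feature_id"])
        .reset_index(drop=True)
    )


def link_gene(snps: pd.DataFrame, annotation: FeatureAnnotation, flank: int = 5000) -> pd.DataFrame:
    """SNP within the gene or within ``flank`` bp up/downstream (inclusive)."""
    g = annotation.genes
    windows = pd.DataFrame(
        {
            "feature_id": g.gene_id,
            "chrom": g.chrom,
            "win_start": g.start - flank,
            "win_end": g.end + flank,
            "feat_start": g.start,
            "feat_end": g.end,
        }
    )
    return _pairs_from_windows(snps, windows, "gene")


def link_transcript(snps: pd.DataFrame, annotation: FeatureAnnotation) -> pd.DataFrame:
    """SNP within the transcript span (intron or exon), no flank."""
    t = annotation.transcripts
    windows = pd.DataFrame(
        {
            "feature_id": t.transcript_id,
            "chrom": t.chrom,
            "win_start": t.start,
            "win_end": t.end,
            "feat_start": t.start,
            "feat_end": t.end,
        }
    )
    return _pairs_from_windows(snps, windows, "transcript")


def _exon_short_windows(annotation: FeatureAnnotation) -> pd.DataFrame:
    """Per (exon, transcript) window spanning the exon plus its immediately
    adjacent introns: from the previous exon's end to the next exon's start
    (transcript boundary for terminal exons).  An exon in several transcripts
    contributes one window per transcript (the union is taken pair-wise)."""
    rows = []
    tx_bounds = annotation.transcripts.set_index("transcript_id")
    for tx_id, ex in annotation.exons.groupby("transcript_id"):
        ex = ex.sort_values("start").reset_index(drop=True)
        starts = ex.start.to_numpy()
        ends = ex.end.to_numpy()
        for i in range(len(ex)):
            left = ends[i - 1] if i > 0 else starts[i]
            right = starts[i + 1] if i + 1 < len(ex) else ends[i]
            rows.append(
                {
                    "feature_id": ex.exon_id[i],
                    "chrom": ex.chrom[i],
                    "win_start": left,
                    "win_end": right,
                    "feat_start": starts[i],
                    "feat_end": ends[i],
                    "transcript_id": tx_id,
                }
            )
    return pd.DataFrame(rows)


def link_exon_short(snps: pd.DataFrame, annotation: FeatureAnnotation) -> pd.DataFrame:
    """SNP within the exon or an immediately adjacent intron (short interval)."""
    windows = _exon_short_windows(annotation)
    if len(windows) == 0:
        return pd.DataFrame(columns=PAIR_COLS)
    return _pairs_from_windows(snps, windows, "exon_short")


def link_exon_long(snps: pd.DataFrame, annotation: FeatureAnnotation) -> pd.DataFrame:
    """SNP anywhere in the exon's parent gene span (long interval, no flank)."""
    ex = annotation.feature_table("exon")
    genes = annotation.genes.set_index("gene_id")
    windows = pd.DataFrame(
        {
            "feature_id": ex.feature_id,
            "chrom": ex.chrom,
            "win_start": genes.start.reindex(ex.gene_id).to_numpy(),
            "win_end": genes.end.reindex(ex.gene_id).to_numpy(),
            "feat_start": ex.start,
            "feat_end": ex.end,
        }
    )
    return _pairs_from_windows(snps, windows, "exon_long")


def link_all_levels(
    snps: pd.DataFrame, annotation: FeatureAnnotation, flank: int = 5000
) -> dict[str, pd.DataFrame]:
    return {
        "gene": link_gene(snps, annotation, flank=flank),
        "transcript": link_transcript(snps, annotation),
        "exon_short": link_exon_short(snps, annotation),
        "exon_long": link_exon_long(snps, annotation),
    }


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    t_statistic: float
    raw_p: float
    n: int
    genotype_counts: dict[int, int]
    perfect_fit: bool = False


def fit_genotype_regression(expr, calls) -> RegressionResult:
    """OLS of expression on the 1/2/3 genotype code, two-sided t-test on the
    slope with n-2 df.  Perfect fits (zero residuals, nonzero slope) return
    p = 0 and are flagged; constant expression returns slope 0, p = 1."""
    y = np.asarray(expr, dtype=float)
    g = np.asarray(calls, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    counts = {int(c): int((g == c).sum()) for c in (1, 2, 3)}
    if len(np.unique(g)) < 2:
        raise ValueError("monomorphic in tested group")
    gc = g - g.mean()
    sxx = float(gc @ gc)
    slope = float(gc @ y) / sxx
    intercept = float(y.mean() - slope * g.mean())
    resid = y - (intercept + slope * g)
    sse = float(resid @ resid)
    syy = float(((y - y.mean()) ** 2).sum())
    # treat round-off-level residuals as a perfect fit
    if sse <= 1e-12 * max(syy, 1e-300):
        if syy == 0.0:
            return RegressionResult(0.0, intercept, 0.0, 1.0, n, counts)
        return RegressionResult(slope, intercept, float(np.sign(slope) * np.inf), 0.0, n, counts, True)
    se = np.sqrt(sse / (n - 2) / sxx)
    t = slope / se
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return RegressionResult(slope, intercept, float(t), p, n, counts)


def _vectorized_ols(y_mat: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, t and two-sided p for each row of ``y_mat`` against genotype ``g``."""
    n = g.size
    gc = g - g.mean()
    sxx = float(gc @ gc)
    yc = y_mat - y_mat.mean(axis=1, keepdims=True)
    slope = (yc @ gc) / sxx
    syy = (yc * yc).sum(axis=1)
    sse = np.maximum(syy - slope * slope * sxx, 0.0)
    perfect = sse <= 1e-12 * np.maximum(syy, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        t = slope / se
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    t[perfect] = np.sign(slope[perfect]) * np.inf
    p[perfect] = 0.0
    const = perfect & (syy == 0.0)
    slope[const] = 0.0
    t[const] = 0.0
    p[const] = 1.0
    return slope, t, p


def run_snp_scan(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    genotypes: GenotypeMatrix,
    groups: dict[str, list[str]],
    alpha: float = 0.10,
    variation_threshold: float = 0.25,
    variation_metric: str = "maf",
    all_group: str = "all",
) -> pd.DataFrame:
    """Regression of every linked pair within every sample group.

    The variation filter is re-applied within each group, and a SNP removed
    for the full data set (the ``all_group`` entry of ``groups``) is removed
    from every subgroup as well.  Pairs monomorphic in a group (fewer than two
    genotype codes) are skipped.  BH is applied per group family (callers scan
    one level at a time, so a family is one (level, group)).
    """
    level = pairs.level.iloc[0] if len(pairs) else None
    if len(pairs) and pairs.level.nunique() > 1:
        raise ValueError("run_snp_scan expects pairs of a single level")
    for name, samples in groups.items():
        missing = set(samples) - set(genotypes.samples)
        if missing:
            raise ValueError(f"group {name!r} has unknown samples: {sorted(missing)}")
    all_pass: set | None = None
    if all_group in groups:
        v_all = _variation_per_snp(genotypes.calls[list(groups[all_group])], variation_metric)
        all_pass = set(v_all.index[v_all >= variation_threshold])
    chunks = []
    for group_name, samples in groups.items():
        samples = list(samples)
        expr_g = expression[samples]
        v = _variation_per_snp(genotypes.calls[samples], variation_metric)
        passing = set(v.index[v >= variation_threshold])
        if all_pass is not None:
            passing &= all_pass
        sub = pairs[pairs.snp_id.isin(passing) & pairs.feature_id.isin(expression.index)]
        rows = []
        for snp_id, snp_pairs in sub.groupby("snp_id"):
            g = genotypes.calls.loc[snp_id, samples].to_numpy(dtype=float)
            if len(np.unique(g)) < 2 or g.size < 3:
                continue
            feats = snp_pairs.feature_id.to_numpy()
            y = expr_g.loc[feats].to_numpy(dtype=float)
            slope, t, p = _vectorized_ols(y, g)
            rows.append(
                pd.DataFrame(
                    {
                        "snp_id": snp_id,
                        "feature_id": feats,
                        "level": level,
                        "group": group_name,
                        "n": g.size,
                        "slope": slope,
                        "t_statistic": t,
                        "raw_p": p,
                        "snp_inside_feature": snp_pairs.snp_inside_feature.to_numpy(),
                    }
                )
            )
        if rows:
            chunk = pd.concat(rows, ignore_index=True)
            safe = chunk.raw_p.clip(lower=np.nextafter(0.0, 1.0))
            chunk["adjusted_p"] = bh_adjust(safe)
            chunk["significant"] = chunk.adjusted_p < alpha
            chunks.append(chunk)
    cols = [
        "snp_id",
        "feature_id",
        "level",
        "group",
        "n",
        "slope",
        "t_statistic",
        "raw_p",
        "adjusted_p",
        "significant",
        "snp_inside_feature",
    ]
    if not chunks:
        return pd.DataFrame(columns=cols)
    return (
        pd.concat(chunks, ignore_index=True)[cols]
        .sort_values(["group", "adjusted_p", "snp_id", "feature_id"])
        .reset_index(drop=True)
    )


def summarize_overlaps(results: pd.DataFrame, annotation: FeatureAnnotation) -> dict:
    """Per-(level, group) counts and a gene-resolution Venn across levels.

    Counts per family: pairs tested, pairs significant, unique significant
    features and genes, and significant SNPs inside vs outside the feature
    span.  The Venn maps significant features to genes (exon/transcript ->
    gene) and, per group, counts every region of the four level-sets, plus the
    SNPs significant at all four levels.
    """
    gene_of = annotation.gene_of_feature()
    families = {}
    for (level, group), sub in results.groupby(["level", "group"]):
        sig = sub[sub.significant]
        families[f"{level}|{group}"] = {
            "tested": int(len(sub)),
            "significant": int(len(sig)),
            "unique_features": int(sig.feature_id.nunique()),
            "unique_genes": int(sig.feature_id.map(gene_of).nunique()),
            "unique_snps": int(sig.snp_id.nunique()),
            "snps_inside": int(sig.snp_inside_feature.sum()),
            "snps_outside": int((~sig.snp_inside_feature).sum()),
        }
    venn = {}
    snps_all_levels = {}
    for group, sub in results.groupby("group"):
        gene_sets = {
            level: set(sub[(sub.level == level) & sub.significant].feature_id.map(gene_of))
            for level in LEVELS
        }
        union = set().union(*gene_sets.values())
        regions = {}
        for gene in union:
            key = ",".join(lv for lv in LEVELS if gene in gene_sets[lv])
            regions[key] = regions.get(key, 0) + 1
        venn[group] = {"union": len(union), "regions": regions}
        snp_sets = [
            set(sub[(sub.level == level) & sub.significant].snp_id) for level in LEVELS
        ]
        snps_all_levels[group] = len(set.intersection(*snp_sets)) if snp_sets else 0
    return {
        "families": families,
        "gene_venn": venn,
        "snps_significant_at_all_levels": snps_all_levels,
    }


def cross_reference_cnv(
    snp_results: pd.DataFrame, cnv_results: pd.DataFrame, annotation: FeatureAnnotation
) -> pd.DataFrame:
    """Genes significant in both the SNP and the CNV analyses.

    For these genes the expression difference may reflect copy-number dosage
    rather than the genotype itself; they are flagged for interpretation, not
    removed.
    """
    gene_of = annotation.gene_of_feature()
    snp_sig = snp_results[snp_results.significant].copy()
    snp_genes = set(snp_sig.feature_id.map(gene_of))
    cnv_sig = cnv_results[cnv_results.significant]
    shared = sorted(snp_genes & set(cnv_sig.gene_id))
    rows = []
    for gene in shared:
        rows.append(
            {
                "gene_id": gene,
                "cnv_directions": ",".join(sorted(cnv_sig[cnv_sig.gene_id == gene].direction)),
                "n_snp_records": int((snp_sig.feature_id.map(gene_of) == gene).sum()),
                "note": "expression difference may reflect CNV, not genotype",
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "cnv_directions", "n_snp_records", "note"])
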