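"""Synthetic pluripotent-stem-cell array study with planted effects.

Emulates the structure of a 20-sample design (nine hESC, eight hiPSC and
three fibroblast lines, the hiPSC lines reprogrammed from the fibroblasts):
a two-chromosome synthetic genome with a gene -> transcript -> exon
annotation, SNP genotypes coded 1/2/3 sampled at Hardy-Weinberg proportions
with per-call confidences, per-sample CNV segments (gain/loss, with marker
counts), probe-level expression with GC-dependent background and antigenomic
control probes, TRANSFAC-style motifs and SNP allele flank sequences.

Effects are planted additively on log2 expression:

    probe = feature baseline + probe affinity
            + eqtl_effect * (genotype - 2)      for planted SNP -> feature pairs
            + cnv_effect * state_shift          (+1 gain, -1 loss)
            + Gaussian noise (noise_sd)

and every planted effect is recorded in a truth table so downstream scans can
be scored for recovery.  All generation is deterministic under a fixed seed;
each generator op derives its RNG stream from (seed, op-tag) so ops are
reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import FeatureAnnotation
from .cnv import label_gene_states
from .genotype_qc import GenotypeMatrix
from . import snp as snp_mod
from .tfbs import BASES, build_pwm, write_transfac

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedDataset",
    "make_samples",
    "generate_annotation",
    "generate_genotypes",
    "sample_genotypes",
    "generate_cnv_segments",
    "generate_expression",
    "generate_motif_fixtures",
    "generate_chip_regions",
    "simulate_dataset",
]

GROUPS = ("hESC", "hiPSC", "fibroblast")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data set.

    Defaults mirror the emulated design: 20 samples in three groups, additive
    eQTL effects of 1.0 log2 units per allele on 20 causal SNP-feature pairs,
    +/-0.6 log2 dosage shifts on 10 CNV genes, and residual noise SD 0.5 log2.
    """

    n_samples: int = 20
    group_sizes: tuple[int, int, int] = (9, 8, 3)  # hESC, hiPSC, fibroblast
    n_genes: int = 40
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (2, 5)
    n_snps: int = 250
    maf_range: tuple[float, float] = (0.05, 0.5)
    eqtl_effect: float = 1.0
    cnv_effect: float = 0.6
    noise_sd: float = 0.5
    n_causal_snps: int = 20
    n_cnv_events: int = 10
    seed: int = 0
    # layout and nuisance knobs
    chrom_lengths: tuple[int, ...] = (10_000_000, 10_000_000)
    probes_per_probeset: int = 4
    small_probeset_fraction: float = 0.05
    background_probe_fraction: float = 0.05
    crosshyb_fraction: float = 0.03
    snp_probe_fraction: float = 0.03
    low_conf_snp_fraction: float = 0.05
    n_antigenomic_per_gc: int = 25
    gc_range: tuple[int, int] = (6, 18)
    n_motifs: int = 8
    n_motif_hits: int = 5
    motif_flank: int = 20
    # thresholds the planted truth must survive (match the analysis defaults)
    variation_threshold: float = 0.25
    min_conf: float = 0.9
    cnv_min_markers: int = 5
    cnv_min_length_bp: int = 10_000

    def validate(self) -> None:
        if sum(self.group_sizes) != self.n_samples:
            raise ValueError("group_sizes must sum to n_samples")
        for name in ("n_samples", "n_genes", "n_snps", "probes_per_probeset"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in [0, 0.5]")


@dataclass
class TruthTable:
    """Planted effects: what a perfect analysis should recover."""

    causal_snps: list[dict] = field(default_factory=list)
    dosage_genes: list[dict] = field(default_factory=list)
    motif_hits: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def make_samples(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: name, group, and (for hiPSC) the parent fibroblast line."""
    n_es, n_ips, n_fib = config.group_sizes
    rows = [{"sample": f"hESC_{i + 1}", "group": "hESC", "parent": ""} for i in range(n_es)]
    fibs = [f"FIB_{i + 1}" for i in range(n_fib)]
    for i in range(n_ips):
        parent = fibs[i % n_fib] if n_fib else ""
        rows.append({"sample": f"hiPSC_{i + 1}", "group": "hiPSC", "parent": parent})
    rows += [{"sample": f, "group": "fibroblast", "parent": ""} for f in fibs]
    return pd.DataFrame(rows, columns=["sample", "group", "parent"])


# ------------------------------------------------------------------ annotation


def generate_annotation(config: SimulationConfig) -> FeatureAnnotation:
    """Non-overlapping genes on >= 2 chromosomes with nested transcripts/exons.

    The first transcript of every gene spans the whole gene; exons partition a
    transcript into alternating exon/intron blocks, so introns are exactly the
    inter-exon gaps.  Raises if the requested gene density does not fit the
    chromosome lengths.
    """
    config.validate()
    rng = _rng(config, 1)
    genes, txs, exons = [], [], []
    n_chroms = len(config.chrom_lengths)
    per_chrom = [config.n_genes // n_chroms] * n_chroms
    for i in range(config.n_genes % n_chroms):
        per_chrom[i] += 1
    gi = 0
    for ci, (chrom_len, n_here) in enumerate(zip(config.chrom_lengths, per_chrom)):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(20_000, 60_000))
        for _ in range(n_here):
            gap = int(rng.integers(30_000, 120_000))
            length = int(rng.integers(20_000, 80_000))
            start = pos + gap
            end = start + length
            if end > chrom_len:
                raise ValueError(
                    f"gene density does not fit {chrom} (need > {end} bp, have {chrom_len})"
                )
            gi += 1
            gene_id = f"G{gi:04d}"
            genes.append((gene_id, chrom, start, end))
            n_tx = int(rng.integers(config.transcripts_per_gene[0], config.transcripts_per_gene[1] + 1))
            for ti in range(n_tx):
                tx_id = f"{gene_id}.T{ti + 1}"
                if ti == 0:
                    t_start, t_end = start, end
                else:
                    pad = length // 4
                    t_start = start + int(rng.integers(0, pad + 1))
                    t_end = end - int(rng.integers(0, pad + 1))
                txs.append((tx_id, gene_id, chrom, t_start, t_end))
                n_ex = int(
                    rng.integers(config.exons_per_transcript[0], config.exons_per_transcript[1] + 1)
                )
                for ei, (e_start, e_end) in enumerate(_split_exons(t_start, t_end, n_ex, rng)):
                    exons.append((f"{tx_id}.E{ei + 1}", tx_id, gene_id, chrom, e_start, e_end))
            pos = end
    ann = FeatureAnnotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"]),
        transcripts=pd.DataFrame(txs, columns=["transcript_id", "gene_id", "chrom", "start", "end"]),
        exons=pd.DataFrame(
            exons, columns=["exon_id", "transcript_id", "gene_id", "chrom", "start", "end"]
        ),
    )
    ann.validate()
    return ann


def _split_exons(t_start: int, t_end: int, n_ex: int, rng) -> list[tuple[int, int]]:
    """Partition [t_start, t_end) into n_ex exons separated by introns."""
    length = t_end - t_start
    n_blocks = 2 * n_ex - 1
    if n_blocks == 1:
        return [(t_start, t_end)]
    w = rng.random(n_blocks) + 0.3
    widths = np.maximum((w / w.sum() * length).astype(int), 1)
    widths[-1] = length - int(widths[:-1].sum())
    if widths[-1] < 1:  # rebalance degenerate rounding
        widths = np.full(n_blocks, length // n_blocks, dtype=int)
        widths[-1] = length - int(widths[:-1].sum())
    bounds = t_start + np.concatenate([[0], np.cumsum(widths)])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_blocks, 2)]


# ------------------------------------------------------------------- genotypes


def sample_genotypes(maf: float, n_samples: int, rng) -> np.ndarray:
    """Hardy-Weinberg genotype codes: 1 + Binomial(2, maf) per sample."""
    return rng.binomial(2, maf, size=n_samples) + 1


def generate_genotypes(config: SimulationConfig, annotation: FeatureAnnotation) -> GenotypeMatrix:
    """SNP x sample 1/2/3 calls with confidences.

    Positions are placed inside genes (~50%), in 5 kb gene flanks (~20%) and
    uniformly elsewhere (~30%).  A configurable fraction of SNPs receives one
    sub-0.9 confidence call to exercise the confidence filter.
    """
    config.validate()
    rng = _rng(config, 2)
    samples = list(make_samples(config)["sample"])
    genes = annotation.genes
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    positions = []
    for i in range(config.n_snps):
        u = rng.random()
        if u < 0.5 and len(genes):
            g = genes.iloc[int(rng.integers(len(genes)))]
            pos = int(rng.integers(g.start, g.end))
            positions.append((g.chrom, pos))
        elif u < 0.7 and len(genes):
            g = genes.iloc[int(rng.integers(len(genes)))]
            side = -1 if rng.random() < 0.5 else 1
            off = int(rng.integers(1, 5001))
            pos = int(g.start - off if side < 0 else g.end + off - 1)
            positions.append((g.chrom, max(pos, 0)))
        else:
            ci = int(rng.integers(len(chrom_names)))
            positions.append((chrom_names[ci], int(rng.integers(0, config.chrom_lengths[ci]))))
    order = sorted(range(config.n_snps), key=lambda i: (positions[i][0], positions[i][1]))
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    calls = np.vstack([sample_genotypes(m, config.n_samples, rng) for m in mafs])
    conf = rng.uniform(config.min_conf, 1.0, size=calls.shape)
    low = rng.random(config.n_snps) < config.low_conf_snp_fraction
    for i in np.nonzero(low)[0]:
        conf[i, int(rng.integers(config.n_samples))] = rng.uniform(0.5, config.min_conf)
    base_pairs = np.array(list(BASES))
    snp_rows, call_rows, conf_rows = [], [], []
    for rank, i in enumerate(order):
        chrom, pos = positions[i]
        ref, alt = rng.choice(base_pairs, size=2, replace=False)
        snp_rows.append((f"rs{rank + 1:05d}", chrom, pos, ref, alt))
        call_rows.append(calls[i])
        conf_rows.append(conf[i])
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    idx = pd.Index(snps.snp_id, name="snp_id")
    return GenotypeMatrix(
        snps=snps,
        calls=pd.DataFrame(np.vstack(call_rows), index=idx, columns=samples),
        confidences=pd.DataFrame(np.vstack(conf_rows), index=idx, columns=samples),
    )


# ---------------------------------------------------------------- CNV segments


def generate_cnv_segments(config: SimulationConfig, annotation: FeatureAnnotation) -> pd.DataFrame:
    """Per-sample gain/loss segments with marker counts.

    ``n_cnv_events`` genes receive a threshold-passing segment in 3-6 samples
    (with some events shared between a fibroblast line and its derived hiPSC
    samples, mirroring reprogramming-inherited CNVs); a few decoy segments
    deliberately violate the marker-count or length thresholds and carry no
    expression effect.  Columns: sample, chrom, start, end, state, n_markers
    (0-based half-open).
    """
    config.validate()
    rng = _rng(config, 3)
    cols = ["sample", "chrom", "start", "end", "state", "n_markers"]
    if config.n_cnv_events == 0:
        return pd.DataFrame(columns=cols)
    samples_df = make_samples(config)
    all_samples = list(samples_df["sample"])
    genes = annotation.genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    n_events = min(config.n_cnv_events, len(genes))
    event_idx = rng.choice(len(genes), size=n_events, replace=False)
    rows = []
    for j, gidx in enumerate(sorted(event_idx)):
        g = genes.iloc[gidx]
        state = "gain" if j % 2 == 0 else "loss"
        # margins clipped so the segment never reaches a neighbouring gene
        prev_end = genes.iloc[gidx - 1].end if gidx > 0 and genes.iloc[gidx - 1].chrom == g.chrom else 0
        nxt = genes.iloc[gidx + 1] if gidx + 1 < len(genes) else None
        next_start = nxt.start if nxt is not None and nxt.chrom == g.chrom else g.end + 50_000
        left = int(min(rng.integers(500, 4000), max(g.start - prev_end - 1, 0)))
        right = int(min(rng.integers(500, 4000), max(next_start - g.end - 1, 0)))
        start, end = int(g.start - left), int(g.end + right)
        if rng.random() < 0.4:
            fib = samples_df[samples_df.group == "fibroblast"]["sample"]
            if len(fib):
                parent = fib.iloc[int(rng.integers(len(fib)))]
                derived = list(samples_df[samples_df.parent == parent]["sample"])
                carriers = [parent] + derived
            else:
                carriers = []
        else:
            carriers = []
        if not carriers:
            k = int(rng.integers(3, 7))
            carriers = list(rng.choice(all_samples, size=min(k, len(all_samples)), replace=False))
        n_markers = int(rng.integers(8, 40))
        for s in carriers:
            rows.append((s, g.chrom, start, end, state, n_markers))
    # sub-threshold decoys: too few markers or too short
    n_decoys = max(2, n_events // 3)
    other = [i for i in range(len(genes)) if i not in set(event_idx)]
    for j in range(min(n_decoys, len(other))):
        g = genes.iloc[other[int(rng.integers(len(other)))]]
        s = all_samples[int(rng.integers(len(all_samples)))]
        state = "gain" if rng.random() < 0.5 else "loss"
        if j % 2 == 0:
            start = int(g.start)
            end = int(g.start + max(config.cnv_min_length_bp, 1_000))
            n_markers = int(rng.integers(1, config.cnv_min_markers))  # too few markers
        else:
            start = int(g.start)
            end = int(g.start + max(config.cnv_min_length_bp // 2, 500))  # too short
            n_markers = int(rng.integers(8, 20))
        rows.append((s, g.chrom, start, min(end, g.end), state, n_markers))
    return (
        pd.DataFrame(rows, columns=cols)
        .sort_values(["chrom", "start", "sample"])
        .reset_index(drop=True)
    )


# ------------------------------------------------------------------ expression


def generate_expression(
    config: SimulationConfig,
    annotation: FeatureAnnotation,
    genotypes: GenotypeMatrix,
    cnv_segments: pd.DataFrame,
) -> tuple[pd.DataFrame, TruthTable]:
    """Probe-level intensity table plus the truth table of planted effects.

    Causal SNP-feature pairs are chosen among SNPs that survive the genotype
    QC thresholds (realized variation, confidence, CNV regions) and that are
    linked to their target by construction (the SNP lies inside the target
    feature); the choice is verified against the actual linking rules and the
    generator fails if any planted pair would not be linkable.  Probesets of
    planted features are kept free of QC flags so the truth is recoverable.
    """
    config.validate()
    rng = _rng(config, 4)
    samples = genotypes.samples
    labels = label_gene_states(
        annotation,
        cnv_segments,
        samples,
        min_markers=config.cnv_min_markers,
        min_length_bp=config.cnv_min_length_bp,
    )
    state_value = {"gain": 1.0, "loss": -1.0, "normal": 0.0, "ambiguous": 0.0}
    shift = labels.apply(lambda col: col.map(state_value)).astype(float)
    dosage_gene_ids = list(shift.index[(shift != 0).any(axis=1)])

    causal = _choose_causal_pairs(config, annotation, genotypes, cnv_segments, dosage_gene_ids, rng)
    _verify_linkable(causal, genotypes, annotation)

    truth = TruthTable()
    for snp_id, feature_id, level, gene_id in causal:
        truth.causal_snps.append(
            {"snp_id": snp_id, "feature_id": feature_id, "level": level, "effect": config.eqtl_effect}
        )
    for gene_id in dosage_gene_ids:
        states = labels.loc[gene_id]
        direction = "gain" if (states == "gain").any() else "loss"
        truth.dosage_genes.append(
            {
                "gene_id": gene_id,
                "direction": direction,
                "effect": config.cnv_effect if direction == "gain" else -config.cnv_effect,
                "n_altered": int((states == direction).sum()),
            }
        )

    # feature baselines (log2)
    gene_base = {g: rng.uniform(6.5, 11.0) for g in annotation.genes.gene_id}
    tx_base = {
        t.transcript_id: gene_base[t.gene_id] + rng.uniform(-0.4, 0.4)
        for t in annotation.transcripts.itertuples()
    }
    exon_rows = annotation.exons.drop_duplicates("exon_id")
    ex_base = {
        e.exon_id: tx_base[e.transcript_id] + rng.uniform(-0.4, 0.4) for e in exon_rows.itertuples()
    }

    protected = {feature_id for _, feature_id, _, _ in causal}
    protected |= set(dosage_gene_ids)  # gene-level probesets of dosage genes
    causal_by_feature = {feature_id: snp_id for snp_id, feature_id, _, _ in causal}

    features = (
        [("gene", g, g, gene_base[g]) for g in annotation.genes.gene_id]
        + [
            ("transcript", t.transcript_id, t.gene_id, tx_base[t.transcript_id])
            for t in annotation.transcripts.itertuples()
        ]
        + [
            ("exon", e.exon_id, e.gene_id, ex_base[e.exon_id])
            for e in exon_rows.itertuples()
        ]
    )
    gc_lo, gc_hi = config.gc_range
    n_s = len(samples)
    calls_arr = genotypes.calls
    meta_rows = []
    intensity_rows = []
    pid = 0
    for level, feature_id, gene_id, base in features:
        is_protected = feature_id in protected
        n_probes = config.probes_per_probeset
        if not is_protected and rng.random() < config.small_probeset_fraction:
            n_probes = 2  # filter fodder for the small-probeset mask
        eff = np.zeros(n_s)
        if feature_id in causal_by_feature:
            g = calls_arr.loc[causal_by_feature[feature_id], samples].to_numpy(dtype=float)
            eff = eff + config.eqtl_effect * (g - 2.0)
        if gene_id in shift.index:
            eff = eff + config.cnv_effect * shift.loc[gene_id, samples].to_numpy(dtype=float)
        for _ in range(n_probes):
            pid += 1
            # protected probesets get low-GC probes (lowest background limits)
            gc = int(rng.integers(gc_lo, min(gc_lo + 7, gc_hi) + 1)) if is_protected else int(
                rng.integers(gc_lo, gc_hi + 1)
            )
            crosshyb = (not is_protected) and rng.random() < config.crosshyb_fraction
            snp_probe = (not is_protected) and rng.random() < config.snp_probe_fraction
            dead = (not is_protected) and rng.random() < config.background_probe_fraction
            if dead:
                log2_int = _background_log2(gc, n_s, rng)
            else:
                affinity = rng.normal(0.0, 0.25)
                log2_int = base + affinity + eff + rng.normal(0.0, config.noise_sd, size=n_s)
            meta_rows.append(
                (f"P{pid:06d}", feature_id, level, gc, False, crosshyb, snp_probe)
            )
            intensity_rows.append(np.power(2.0, log2_int))
    for gc in range(gc_lo, gc_hi + 1):
        for _ in range(config.n_antigenomic_per_gc):
            pid += 1
            meta_rows.append((f"P{pid:06d}", "", "antigenomic", gc, True, False, False))
            intensity_rows.append(np.power(2.0, _background_log2(gc, n_s, rng)))
    meta = pd.DataFrame(
        meta_rows,
        columns=["probe_id", "probeset_id", "level", "gc", "is_antigenomic", "is_crosshyb", "overlaps_snp"],
    )
    intensities = pd.DataFrame(np.vstack(intensity_rows), columns=samples)
    probes = pd.concat([meta, intensities], axis=1)
    return probes, truth


def _background_log2(gc: int, n: int, rng) -> np.ndarray:
    """GC-dependent background on the log2 scale."""
    return 2.0 + 0.12 * gc + rng.normal(0.0, 0.3, size=n)


def _choose_causal_pairs(config, annotation, genotypes, cnv_segments, dosage_gene_ids, rng):
    """Pick (snp, feature, level, gene) targets that survive QC and are linked.

    SNPs must have realized variation >= threshold across all samples, every
    confidence >= min_conf, lie outside threshold-passing CNV segments, and
    sit inside the target feature; targets avoid dosage-affected genes, cycle
    the three levels, and prefer distinct genes.
    """
    from .cnv import filter_segments
    from .genotype_qc import genotype_variation

    if config.n_causal_snps == 0:
        return []
    surviving = filter_segments(cnv_segments, config.cnv_min_markers, config.cnv_min_length_bp)
    snps = genotypes.snps
    ok = np.ones(len(snps), dtype=bool)
    for _, seg in surviving.iterrows():
        ok &= ~(
            (snps.chrom == seg.chrom).to_numpy()
            & (snps.pos.to_numpy() >= seg.start)
            & (snps.pos.to_numpy() < seg.end)
        )
    conf_ok = (genotypes.confidences >= config.min_conf).all(axis=1)
    var_ok = genotypes.calls.apply(lambda row: genotype_variation(row) >= config.variation_threshold, axis=1)
    eligible = snps[ok & conf_ok.loc[snps.snp_id].to_numpy() & var_ok.loc[snps.snp_id].to_numpy()]
    banned_genes = set(dosage_gene_ids)
    candidates = {"gene": [], "transcript": [], "exon": []}
    for level in candidates:
        feats = annotation.feature_table(level)
        feats = feats[~feats.gene_id.isin(banned_genes)]
        for chrom, fsub in feats.groupby("chrom"):
            esub = eligible[eligible.chrom == chrom]
            if len(esub) == 0:
                continue
            pos = esub.pos.to_numpy()[:, None]
            inside = (pos >= fsub.start.to_numpy()) & (pos < fsub.end.to_numpy())
            si, fi = np.nonzero(inside)
            for a, b in zip(si, fi):
                candidates[level].append(
                    (esub.snp_id.iloc[a], fsub.feature_id.iloc[b], level, fsub.gene_id.iloc[b])
                )
    for level in candidates:
        rng.shuffle(candidates[level])
    chosen, used_snps, used_genes, used_features = [], set(), set(), set()
    order = ["gene", "transcript", "exon"]
    for strict_genes in (True, False):
        li = 0
        stall = 0
        while len(chosen) < config.n_causal_snps and stall < 3 * len(order):
            level = order[li % len(order)]
            li += 1
            picked = None
            for cand in candidates[level]:
                snp_id, feature_id, _, gene_id = cand
                if snp_id in used_snps or feature_id in used_features:
                    continue
                if strict_genes and gene_id in used_genes:
                    continue
                picked = cand
                break
            if picked is None:
                stall += 1
                continue
            stall = 0
            chosen.append(picked)
            used_snps.add(picked[0])
            used_features.add(picked[1])
            used_genes.add(picked[3])
        if len(chosen) >= config.n_causal_snps:
            break
    if len(chosen) < config.n_causal_snps:
        raise ValueError(
            f"could only place {len(chosen)} of {config.n_causal_snps} causal SNPs; "
            "increase n_snps or n_genes"
        )
    return chosen


def _verify_linkable(causal, genotypes, annotation) -> None:
    """Check every planted pair against the real linking rules."""
    if not causal:
        return
    snp_ids = [c[0] for c in causal]
    sub = genotypes.snps[genotypes.snps.snp_id.isin(snp_ids)]
    links = snp_mod.link_all_levels(sub, annotation)
    need = {"gene": ["gene"], "transcript": ["transcript"], "exon": ["exon_short", "exon_long"]}
    for snp_id, feature_id, level, _ in causal:
        for link_level in need[level]:
            pairs = links[link_level]
            hit = ((pairs.snp_id == snp_id) & (pairs.feature_id == feature_id)).any()
            if not hit:
                raise ValueError(
                    f"planted causal SNP {snp_id} is not linkable to {feature_id} at {link_level}"
                )


# ---------------------------------------------------------------------- motifs


def generate_motif_fixtures(
    config: SimulationConfig, snp_ids: list[str] | None = None
) -> tuple[list[tuple[str, str, np.ndarray]], pd.DataFrame, list[dict]]:
    """TRANSFAC-style count matrices and ref/alt allele flank pairs.

    For each planted hit the reference allele carries the motif consensus
    (relative score exactly 1.0) and the alternate allele replaces the most
    informative consensus base with the column-minimum base, breaking the
    site.  One uniform (degenerate) motif is emitted as scoring fodder.
    Returns (motifs, allele table, planted-hit truth records).
    """
    config.validate()
    rng = _rng(config, 5)
    motifs = []
    for mi in range(config.n_motifs):
        L = int(rng.integers(8, 11))
        counts = np.ones((L, 4))
        for j in range(L):
            dom = int(rng.integers(4))
            counts[j] = (1.0, 1.0, 1.0, 1.0)
            counts[j, dom] = 6.0
            counts[j, (dom + 1) % 4] = 2.0
        # one high-information anchor column: a critical contact base whose
        # substitution alone moves the relative score substantially
        anchor = int(rng.integers(L))
        counts[anchor] = (0.0, 0.0, 0.0, 0.0)
        counts[anchor, int(rng.integers(4))] = 50.0
        motifs.append((f"M{mi + 1:03d}", f"TF{mi + 1:02d}", counts))
    motifs.append(("M_uniform", "TF_UNIFORM", np.full((8, 4), 5.0)))
    n_pairs = config.n_motif_hits + 10
    if snp_ids is None:
        snp_ids = [f"rs_tf{i + 1:03d}" for i in range(n_pairs)]
    snp_ids = list(snp_ids)[:n_pairs]
    rows, hits = [], []
    flank = config.motif_flank
    for i, snp_id in enumerate(snp_ids):
        seq = rng.choice(list(BASES), size=2 * flank + 1)
        if i < config.n_motif_hits and len(motifs) > 1:
            motif_id, tf_name, counts = motifs[i % config.n_motifs]
            pwm = build_pwm(counts, motif_id=motif_id, tf_name=tf_name)
            consensus = pwm.consensus
            info = pwm.log_odds.max(axis=1) - pwm.log_odds.min(axis=1)
            j = int(np.argmax(info))  # SNP hits the most informative column
            offset = flank - j
            seq[offset : offset + len(consensus)] = list(consensus)
            ref = "".join(seq)
            worst = BASES[int(pwm.log_odds[j].argmin())]
            alt_seq = seq.copy()
            alt_seq[flank] = worst
            alt = "".join(alt_seq)
            drop = float(info[j] / (pwm.max_score - pwm.min_score))
            hits.append(
                {
                    "snp_id": snp_id,
                    "motif_id": motif_id,
                    "tf_name": tf_name,
                    "expected_rel_ref": 1.0,
                    "planted_score_drop": drop,
                }
            )
        else:
            ref = "".join(seq)
            alt_seq = seq.copy()
            others = [b for b in BASES if b != alt_seq[flank]]
            alt_seq[flank] = others[int(rng.integers(3))]
            alt = "".join(alt_seq)
        rows.append({"snp_id": snp_id, "ref_seq": ref, "alt_seq": alt})
    alleles = pd.DataFrame(rows, columns=["snp_id", "ref_seq", "alt_seq"])
    return motifs, alleles, hits


def generate_chip_regions(config: SimulationConfig, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """ChIP-defined binding regions for the key stem-cell TFs, placed away
    from every SNP position (the emulated study found no overlaps)."""
    rng = _rng(config, 6)
    tfs = ["NANOG", "OCT4", "SOX2", "E2F4"]
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    snp_pos = {c: set(genotypes.snps[genotypes.snps.chrom == c].pos) for c in chrom_names}
    rows = []
    for tf in tfs:
        for _ in range(3):
            for _attempt in range(200):
                ci = int(rng.integers(len(chrom_names)))
                chrom = chrom_names[ci]
                start = int(rng.integers(0, config.chrom_lengths[ci] - 500))
                end = start + 500
                if not any(start <= p < end for p in snp_pos[chrom]):
                    rows.append({"tf_name": tf, "chrom": chrom, "start": start, "end": end})
                    break
    return pd.DataFrame(rows, columns=["tf_name", "chrom", "start", "end"])


# --------------------------------------------------------------------- bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    samples: pd.DataFrame
    annotation: FeatureAnnotation
    genotypes: GenotypeMatrix
    cnv_segments: pd.DataFrame
    probes: pd.DataFrame
    motifs: list
    alleles: pd.DataFrame
    chip_regions: pd.DataFrame
    truth: TruthTable

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        self.annotation.to_gtf(out / "annotation.gtf")
        snps_out = self.genotypes.snps.copy()
        snps_out["pos"] = snps_out.pos + 1  # 1-based on disk
        snps_out.to_csv(out / "snps.tsv", sep="\t", index=False)
        self.genotypes.calls.to_csv(out / "genotypes.tsv", sep="\t")
        self.genotypes.confidences.to_csv(out / "confidences.tsv", sep="\t", float_format="%.6f")
        self.cnv_segments.to_csv(out / "cnv_segments.tsv", sep="\t", index=False)
        self.probes.to_csv(out / "probes.tsv", sep="\t", index=False, float_format="%.6f")
        write_transfac(self.motifs, out / "motifs.transfac")
        with open(out / "allele_flanks.fasta", "w") as fh:
            for rec in self.alleles.itertuples():
                fh.write(f">{rec.snp_id}|ref\n{rec.ref_seq}\n>{rec.snp_id}|alt\n{rec.alt_seq}\n")
        self.chip_regions[["chrom", "start", "end", "tf_name"]].to_csv(
            out / "chip_regions.bed", sep="\t", index=False, header=False
        )
        self.truth.to_json(out / "truth.json")


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate the full fixture set with one call."""
    config = config or SimulationConfig()
    config.validate()
    samples = make_samples(config)
    annotation = generate_annotation(config)
    genotypes = generate_genotypes(config, annotation)
    cnv_segments = generate_cnv_segments(config, annotation)
    probes, truth = generate_expression(config, annotation, genotypes, cnv_segments)
    causal_ids = [c["snp_id"] for c in truth.causal_snps]
    extra = [s for s in genotypes.snps.snp_id if s not in set(causal_ids)][:10]
    motifs, alleles, hits = generate_motif_fixtures(config, snp_ids=causal_ids + extra)
    truth.motif_hits = hits
    chip = generate_chip_regions(config, genotypes)
    return SimulatedDataset(
        config=config,
        samples=samples,
        annotation=annotation,
        genotypes=genotypes,
        cnv_segments=cnv_segments,
        probes=probes,
        motifs=motifs,
        alleles=alleles,
        chip_regions=chip,
        truth=truth,
    )
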