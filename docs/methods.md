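# Methods

This note documents the models, procedures and design choices behind
`stemqtl`: what each stage assumes, which parameters matter, what the
synthetic data do and do not emulate, and the numerical conventions used
throughout.

## Study design being emulated

The package targets a paired array design: every cell line is measured on a
SNP genotyping array (genotype calls with per-call confidences, plus CNV
segments derived from the same array) and on an exon expression array
(probe-level intensities summarized at gene, transcript and exon
resolution). The default synthetic cohort is 20 lines in three groups —
nine hESC, eight hiPSC and three fibroblast lines, with each hiPSC line
assigned a parent fibroblast so that reprogramming-inherited CNVs can be
simulated. Association scans run in three sample groups (hESC, hiPSC, all)
because the genetic variation available to test differs between them.

## Expression QC

Intensities are compared on the linear scale. Antigenomic control probes —
probes with no genomic target — estimate pure background as a function of
probe GC content: for each GC bin the limit is the mean plus twice the
sample SD (n−1 denominator; a single-value bin has SD 0) of all antigenomic
intensity values in the bin, pooled across samples. A genomic probe
survives only if its **maximum** intensity across samples strictly exceeds
the limit of its GC bin; a probe at exactly the limit is treated as
background (the conservative reading of "compared with the limit"). Probes
flagged as cross-hybridizing or as containing a SNP are removed next (flags
are consumed from annotation, not recomputed from sequence), and probesets
left with fewer than `min_probes = 3` probes are masked entirely.

Summarization is the mean of log2 intensities over a probeset's surviving
probes. This is a deliberate stand-in for RMA: multi-array background
correction and quantile normalization are out of scope, and the QC
decisions — which are the substance here — are unaffected. Because the
limits are statistics of the data, multiplying every intensity by a
constant leaves the kept/removed partition unchanged, and each filter is
idempotent; the pipeline nevertheless applies them in a fixed order so the
per-stage counts in the run report are well defined.

## Genotype QC

Calls are coded 1/2/3 (hom. reference / het / hom. alternate) with a
confidence per call. Three per-SNP predicates:

* **Variation**: minor-allele frequency, computed as
  `min(f, 1−f)` with `f = Σ(call−1) / 2n`, must be ≥ 0.25 in the analyzed
  group ("less than 25%" is removed, so exactly 25% survives). The
  alternative reading — fraction of samples carrying a non-modal genotype —
  is available as `variation_metric="genotype_fraction"`; MAF is the
  default. A SNP removed for the full sample set is removed from every
  subgroup as well, even if the subgroup alone would retain it.
* **Confidence**: a SNP is dropped if any sample's confidence is strictly
  below 0.9.
* **Regions**: SNPs inside any sample's reported CNV segment, or on a
  mosaic-gained chromosome of any sample, are dropped. Intervals are
  1-based closed on input and 0-based half-open internally; the SNP is
  tested as a point, and both interval boundaries are inclusive on the
  input convention.

The predicates are independent per SNP, so the filters commute; order only
matters for reporting.

## CNV–expression integration

CNV segments carry a sample, an interval, a state (gain/loss) and a marker
count. Segments with fewer than `min_markers = 5` markers or shorter than
`min_length_bp` are discarded; the length default is 10 kb (the hiPSC
calling profile) with 50 kb available as the stricter hESC profile. A gene
is labelled gain or loss in a sample when its span overlaps a surviving
segment of that state by ≥ 1 bp; overlap with both states in one sample
yields `ambiguous`, which is excluded from testing.

For each gene altered in at least one sample, and separately per direction,
the weight statistic

    w = (m_altered − m_normal) / (sd_altered + sd_normal)

is computed from the log2 expression of the altered-state and normal-state
samples (n−1 SD; a singleton group — which does occur, many real dosage
events are private to one line — has SD 0). The loss-direction weight flips
the numerator so that a positive weight always denotes the expected shift
(gain → high, loss → low); records whose weight is negative are retained
and flagged `opposite_direction` but never claimed significant in the
one-sided test. If the denominator is 0 with a nonzero numerator the weight
is a signed infinity ranked most extreme; 0/0 is defined as 0.

The null distribution reassigns the altered/normal labels uniformly at
random, preserving group sizes, among the samples entering the test
(samples in the other state or ambiguous are excluded first). The one-sided
Monte-Carlo p-value uses the add-one plug, p = (1 + #{w_perm ≥ w_obs}) /
(1 + n_perm), so p is never zero; when the number of distinct assignments
C(n, k) is at most `n_perm` the assignments are enumerated exhaustively and
the plug is dropped (the enumeration includes the observed assignment, so
p ≥ 1/C(n, k)). Ties are counted as exceedances with a 1e-12 relative
guard. Permutation index matrices are cached per (n, k) and seeded from
(seed, n, k), so two genes with the same group sizes share one null — a
pure speed optimization that also makes results independent of gene order.
`n_perm` defaults to 10000. BH adjustment runs within each direction
family; fold change is reported both as m_altered − m_normal (log2) and as
its linear counterpart 2^Δ. A two-sided mode (`alternative="two-sided"`,
comparing |w|) is available but not default, since the stated hypotheses
are directional.

## cis-eQTL scans

Linking rules (all unstranded; internal coordinates 0-based half-open,
boundaries inclusive on the 1-based input convention):

* **gene** — SNP within the gene span or ≤ 5000 bp up/downstream;
* **transcript** — SNP within the transcript span (introns count; no
  flank);
* **exon, short interval** — SNP within the exon or in an intron
  immediately adjacent to it in any parent transcript (terminal exons have
  one adjacent intron; an exon shared by several transcripts uses the union
  of its adjacent introns);
* **exon, long interval** — SNP anywhere within the exon's parent gene
  span. The short pair set is a subset of the long pair set on every input.

Each linked pair is tested by ordinary least squares of log2 expression on
the genotype code regressed as-is (1/2/3 is allele dosage up to an affine
transform, so the slope is in log2 units per allele). The two-sided p-value
uses the t distribution with n−2 df. Pairs with fewer than two genotype
classes in the tested group are skipped as monomorphic; the two-class
requirement is enforced within each group, not only in the full set.
Perfect fits return p = 0 and carry a flag; constant expression returns
slope 0 and p = 1. Scans run per (level, group) with the variation filter
re-applied inside the group (intersected with the full-set filter) and BH
within each (level, group) family at α = 0.10. Overlap summaries count
significant pairs, unique features and genes (exons and transcripts mapped
to their gene), SNPs inside vs outside the feature's own span, a
gene-resolution Venn across the four levels, and the SNPs significant at
all levels. Genes significant in both the SNP and the CNV analyses are
cross-referenced and flagged, since their expression difference may reflect
dosage rather than genotype.

## TF-binding scoring

A count matrix column with counts c becomes frequencies
f = (c/Σc + 0.005) / (1 + 4·0.005) — the pseudocount is added to the
normalized frequencies, not the raw counts, and the division by 1.02
renormalizes — and log-odds log2(f / 0.25) against a uniform background. A
uniform column therefore scores exactly 0. The binding score of a sequence
is the maximum summed log-odds over all windows on both strands (strand
scanning can be disabled); windows containing non-ACGT bases are skipped
with a warning. Scores are rescaled to the relative score
(s − min) / (max − min) where min/max are the motif's attainable bounds, so
the consensus scores exactly 1 and the anti-consensus 0; motifs with
max = min are degenerate and excluded. For a SNP, both allele flanks are
scored and the pair is kept only if either allele reaches the gate
(default 0.8); TFs are then ranked by the largest absolute difference of
relative scores, with a reporting threshold `diff_threshold = 0.2` chosen
as a sensible default on the relative-score scale (the underlying ranking
is threshold-free and the threshold is echoed in every output). The
min–max normalization is the standard reading of "maximum possible binding
score"; a raw score/max ratio is available as a configuration option.

## Synthetic data and what it shows

The generator produces a two-chromosome genome (10 Mb each; coordinates
carry no reference meaning) with non-overlapping genes (20–80 kb),
transcripts nested in genes (the first transcript spans its gene, so the
degenerate one-transcript/one-exon configuration collapses to identical
spans) and exons partitioning transcripts with introns as the gaps.
Genotypes are Hardy–Weinberg draws at a per-SNP allele frequency uniform on
[0.05, 0.5]; ~50% of SNPs fall inside genes, ~20% in 5 kb flanks and the
rest anywhere, and a configurable fraction of SNPs receives one sub-0.9
confidence call. Probe intensities are built additively on the log2 scale:

    probe = feature baseline (gene U(6.5, 11), transcript/exon ± U(−0.4, 0.4))
          + probe affinity N(0, 0.25)
          + eqtl_effect · (genotype − 2)      for planted SNP→feature pairs
          + cnv_effect · state shift          (+1 gain, −1 loss)
          + N(0, noise_sd)

then exponentiated. Antigenomic probes cover the GC range 6–18 per 25-mer
with a GC-dependent background (log2 mean 2 + 0.12·GC, SD 0.3); a fraction
of genomic probes is drawn from this background (dead probes), others are
flagged cross-hybridizing or SNP-overlapping, and a few probesets get only
two probes to exercise the mask.

Default conditions: 20 causal SNP→feature pairs at 1.0 log2/allele spread
over the three levels, 10 dosage genes at ±0.6 log2 carried by 3–6 samples
each (some shared between a fibroblast and its derived hiPSC lines),
residual noise SD 0.5. Causal SNPs are chosen so they survive the genotype
QC thresholds and sit inside their target feature; the choice is verified
against the actual linking rules at generation time and generation fails on
any unlinkable planted pair. Probesets of planted features are kept free of
QC flags and given low-GC probes, so the truth table measures the
statistics' power rather than fixture attrition. Sub-threshold CNV decoy
segments (too few markers or too short) are emitted without any expression
effect: they model spurious calls that the marker/length filter exists to
remove. Motif fixtures concentrate information in one anchor column per
motif so that a single-nucleotide change can move the relative score
substantially, which is what makes planted allele-differential hits
detectable; the reference allele carries the consensus (relative score
exactly 1.0).

What passing tests show — and do not. With independent SNPs there is no
linkage disequilibrium, so false positives arise only from noise; real
studies would show correlated discoveries. Effects are purely additive
(no dominance), noise is Gaussian and homoscedastic, probe effects are
additive rather than RMA-modelled, and CNV states are error-free labels
rather than noisy copy-number estimates. Recovery and FDR numbers under
these conditions demonstrate correctness and calibration of the
statistics, not expected power on real arrays.

## Numerical and reproducibility notes

All randomness flows through `numpy.random.default_rng`; each generator
stage derives its stream from (seed, stage-tag), so stages are reproducible
in isolation and the full pipeline is byte-identical across runs with the
same seed. BH adjustment is delegated to statsmodels (`fdr_bh`) behind
`stemqtl.stats.bh_adjust`, which validates p ∈ (0, 1]. OLS is computed in
closed form (needed for the vectorized scan) and agrees with
`scipy.stats.linregress` to 1e-10 relative. GTF is written in the
conventional interleaved gene/transcript/exon order and read via gffutils;
TRANSFAC matrices go through Bio.motifs; FASTA through Bio.SeqIO.

Problem sizes in the test suite and acceptance script are the package's
own choices for a desk-scale study: 40 genes / 250 SNPs per replicate,
permutation nulls of ~2000 draws where the scan is repeated many times
(the pipeline default stays at 10000), 50 replicates for recovery, 2000
null genes for calibration. The real study's headline counts (hundreds of
associated genes and SNPs) depend on genome-scale inputs and are not
reproducible at this scale; the package instead verifies the arithmetic
identities the analysis implies, the calibration of its nulls, and the
recovery of planted truth.

## Known limitations

No RMA/SNPRMA normalization, genotype/CNV calling, imputation or
missing-call policy (upstream callers emit complete calls); no covariate or
population-structure adjustment (none is part of the method); no trans-eQTL
scan (the linking rules are cis by construction); no p-value calibration
for PWM scores; strand is ignored in linking (distances are genomic).
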