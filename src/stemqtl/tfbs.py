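"""Allele-specific transcription-factor binding scores from PWMs.

Count matrices (TRANSFAC-style) are converted to log-odds position weight
matrices: per-column base frequencies get a pseudocount of 0.005 added after
normalization (then renormalized by 1.02), and log-odds are taken against a
uniform 0.25 background.  A sequence is scored as the maximum summed log-odds
over all windows on both strands; scores are rescaled to a relative score in
[0, 1] between the per-motif minimum and maximum attainable scores.  For a
SNP, both allele flanking sequences are scored; pairs where neither allele
reaches the relative-score gate (default 0.8) are discarded, and the absolute
difference of the allele relative scores ranks candidate regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "PWM",
    "AlleleScorePair",
    "build_pwm",
    "read_transfac",
    "write_transfac",
    "read_allele_fasta",
    "max_binding_score",
    "relative_score",
    "score_allele_pair",
    "score_allele_table",
    "rank_differential_tfs",
    "overlap_chip_regions",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PWM:
    motif_id: str
    tf_name: str
    counts: np.ndarray  # L x 4 raw counts (A, C, G, T)
    log_odds: np.ndarray  # L x 4 log2 odds vs uniform background
    pseudocount: float = 0.005
    min_score: float = field(init=False)
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.min_score = float(self.log_odds.min(axis=1).sum())
        self.max_score = float(self.log_odds.max(axis=1).sum())

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @property
    def degenerate(self) -> bool:
        """True when every sequence scores identically (max == min)."""
        return self.max_score == self.min_score

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))


def build_pwm(counts, pseudocount: float = 0.005, motif_id: str = "motif", tf_name: str = "TF") -> PWM:
    """Log-odds PWM: f = (c/colsum + pseudocount) / (1 + 4*pseudocount),
    log-odds = log2(f / 0.25).  Raises on an all-zero column."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be an L x 4 matrix (A, C, G, T)")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    colsum = counts.sum(axis=1, keepdims=True)
    if np.any(colsum == 0):
        raise ValueError("all-zero count column")
    freqs = (counts / colsum + pseudocount) / (1.0 + 4.0 * pseudocount)
    log_odds = np.log2(freqs / 0.25)
    return PWM(motif_id=motif_id, tf_name=tf_name, counts=counts, log_odds=log_odds, pseudocount=pseudocount)


def read_transfac(path, pseudocount: float = 0.005) -> list[PWM]:
    """Parse a TRANSFAC-style matrix file into PWMs (via Bio.motifs)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "TRANSFAC")
    pwms = []
    for m in records:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)], dtype=float)
        motif_id = m.get("ID", m.get("AC", "motif"))
        tf_name = m.get("NA", motif_id)
        pwms.append(build_pwm(counts, pseudocount=pseudocount, motif_id=motif_id, tf_name=tf_name))
    return pwms


def write_transfac(motifs: list[tuple[str, str, np.ndarray]], path) -> None:
    """Write (motif_id, tf_name, L x 4 counts) triples in TRANSFAC layout."""
    with open(path, "w") as fh:
        for motif_id, tf_name, counts in motifs:
            counts = np.asarray(counts)
            fh.write(f"ID  {motif_id}\n")
            fh.write(f"NA  {tf_name}\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(counts, start=1):
                vals = "".join(f"{v:7g}" for v in row)
                cons = BASES[int(np.argmax(row))]
                fh.write(f"{i:02d}{vals}      {cons}\n")
            fh.write("XX\n//\n")


def read_allele_fasta(path) -> pd.DataFrame:
    """Read allele flank FASTA with headers ``snpid|ref`` / ``snpid|alt`` into
    a table (snp_id, ref_seq, alt_seq)."""
    seqs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        snp_id, allele = rec.id.rsplit("|", 1)
        seqs.setdefault(snp_id, {})[allele] = str(rec.seq).upper()
    rows = []
    for snp_id, d in seqs.items():
        if "ref" not in d or "alt" not in d:
            raise ValueError(f"missing ref/alt sequence for {snp_id}")
        rows.append({"snp_id": snp_id, "ref_seq": d["ref"], "alt_seq": d["alt"]})
    return pd.DataFrame(rows, columns=["snp_id", "ref_seq", "alt_seq"])


def _reverse_complement(seq: str) -> str:
    # non-ACGT bases stay ambiguous; their windows are skipped downstream
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


def _scan_one_strand(seq: str, log_odds: np.ndarray) -> float:
    L = log_odds.shape[0]
    best = -np.inf
    skipped = False
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        try:
            idx = [_BASE_IDX[b] for b in window]
        except KeyError:
            skipped = True
            continue
        score = float(log_odds[np.arange(L), idx].sum())
        if score > best:
            best = score
    if skipped:
        warnings.warn("windows containing ambiguous bases were skipped", stacklevel=3)
    return best


def max_binding_score(sequence: str, pwm: PWM, scan_both_strands: bool = True) -> float:
    """Maximum summed log-odds over all windows (both strands by default)."""
    sequence = sequence.upper()
    if len(sequence) < len(pwm):
        raise ValueError("sequence shorter than motif")
    best = _scan_one_strand(sequence, pwm.log_odds)
    if scan_both_strands:
        best = max(best, _scan_one_strand(_reverse_complement(sequence), pwm.log_odds))
    return best


def relative_score(score: float, pwm: PWM) -> float:
    """Min-max rescaling of a raw score into [0, 1]."""
    if pwm.degenerate:
        raise ValueError(f"degenerate motif {pwm.motif_id}: max score equals min score")
    return (score - pwm.min_score) / (pwm.max_score - pwm.min_score)


@dataclass
class AlleleScorePair:
    snp_id: str
    motif_id: str
    tf_name: str
    score_ref: float
    score_alt: float
    rel_ref: float
    rel_alt: float

    @property
    def abs_difference(self) -> float:
        return abs(self.rel_ref - self.rel_alt)


def score_allele_pair(
    pwm: PWM,
    ref_seq: str,
    alt_seq: str,
    snp_id: str = "",
    gate: float = 0.8,
    scan_both_strands: bool = True,
) -> AlleleScorePair | None:
    """Score both alleles; return the pair only if either allele's relative
    score reaches ``gate``.  Returns None below the gate or when the flank is
    too short for the motif (logged via warning)."""
    if min(len(ref_seq), len(alt_seq)) < len(pwm):
        warnings.warn(f"flank shorter than motif {pwm.motif_id}; skipped", stacklevel=2)
        return None
    if pwm.degenerate:
        warnings.warn(f"degenerate motif {pwm.motif_id} excluded", stacklevel=2)
        return None
    s_ref = max_binding_score(ref_seq, pwm, scan_both_strands)
    s_alt = max_binding_score(alt_seq, pwm, scan_both_strands)
    r_ref = relative_score(s_ref, pwm)
    r_alt = relative_score(s_alt, pwm)
    if max(r_ref, r_alt) < gate:
        return None
    return AlleleScorePair(snp_id, pwm.motif_id, pwm.tf_name, s_ref, s_alt, r_ref, r_alt)


def score_allele_table(
    pwms: list[PWM], alleles: pd.DataFrame, gate: float = 0.8, scan_both_strands: bool = True
) -> pd.DataFrame:
    """All gated (snp, motif) pairs for a table of allele flank sequences."""
    rows = []
    for _, rec in alleles.iterrows():
        for pwm in pwms:
            if pwm.degenerate:
                continue
            pair = score_allele_pair(
                pwm, rec.ref_seq, rec.alt_seq, snp_id=rec.snp_id, gate=gate,
                scan_both_strands=scan_both_strands,
            )
            if pair is not None:
                rows.append(
                    {
                        "snp_id": pair.snp_id,
                        "motif_id": pair.motif_id,
                        "tf_name": pair.tf_name,
                        "rel_ref": pair.rel_ref,
                        "rel_alt": pair.rel_alt,
                        "abs_difference": pair.abs_difference,
                    }
                )
    return pd.DataFrame(
        rows, columns=["snp_id", "motif_id", "tf_name", "rel_ref", "rel_alt", "abs_difference"]
    )


def rank_differential_tfs(pairs: pd.DataFrame, diff_threshold: float = 0.2) -> pd.DataFrame:
    """Unique TFs whose best gated pair exceeds ``diff_threshold``, ranked by
    maximum allele score difference (descending)."""
    if len(pairs) == 0:
        return pd.DataFrame(columns=["tf_name", "max_abs_difference", "n_pairs"])
    best = (
        pairs.groupby("tf_name")
        .agg(max_abs_difference=("abs_difference", "max"), n_pairs=("abs_difference", "size"))
        .reset_index()
    )
    best = best[best.max_abs_difference > diff_threshold]
    return best.sort_values(
        ["max_abs_difference", "tf_name"], ascending=[False, True]
    ).reset_index(drop=True)


def overlap_chip_regions(snps: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """SNPs falling in ChIP-defined binding regions, annotated with the TF.

    ``snps`` needs snp_id, chrom, pos (0-based); ``regions`` needs
    tf_name, chrom, start, end (0-based half-open).
    """
    rows = []
    for _, reg in regions.iterrows():
        hit = snps[(snps.chrom == reg.chrom) & (snps.pos >= reg.start) & (snps.pos < reg.end)]
        for _, s in hit.iterrows():
            rows.append({"snp_id": s.snp_id, "tf_name": reg.tf_name, "chrom": reg.chrom, "pos": s.pos})
    return pd.DataFrame(rows, columns=["snp_id", "tf_name", "chrom", "pos"])
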