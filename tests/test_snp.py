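"""Linking rules, genotype regression, scans and overlap summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stemqtl.annotation import FeatureAnnotation
from stemqtl.genotype_qc import GenotypeMatrix
from stemqtl.simulate import SimulationConfig, generate_annotation
from stemqtl.snp import (
    LEVELS,
    cross_reference_cnv,
    fit_genotype_regression,
    link_all_levels,
    link_exon_long,
    link_exon_short,
    link_gene,
    link_transcript,
    run_snp_scan,
    summarize_overlaps,
)

def snp_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def pair_set(df):
    return set(zip(df.snp_id, df.feature_id))


class TestLinkGene:
    def test_flank_boundary(self, tiny_annotation):
        # geneA starts at 1000 (0-based); 1-based start is 1001, so the SNP
        # exactly 5000 bp upstream sits at 1-based 1001-5000 -> 0-based -4000... use geneB
        snps = snp_frame(
            [
                ("at_5000", "chr2", 500 - 5000),
                ("at_5001", "chr2", 500 - 5001),
                ("down_5000", "chr2", 1500 + 5000 - 1),
                ("down_5001", "chr2", 1500 + 5000),
            ]
        )
        pairs = pair_set(link_gene(snps, tiny_annotation))
        assert ("at_5000", "geneB") in pairs
        assert ("at_5001", "geneB") not in pairs
        assert ("down_5000", "geneB") in pairs
        assert ("down_5001", "geneB") not in pairs

    def test_inside_flag(self, tiny_annotation):
        snps = snp_frame([("inside", "chr1", 5000), ("flank", "chr1", 1000 - 100)])
        out = link_gene(snps, tiny_annotation)
        flags = dict(zip(out.snp_id, out.snp_inside_feature))
        assert flags["inside"] and not flags["flank"]


class TestLinkTranscript:
    def test_intron_is_linked(self, tiny_annotation):
        # 2500 lies between exons exA1 [1000,2000) and exA2 [3000,4000)
        snps = snp_frame([("intronic", "chr1", 2500), ("past_end", "chr1", 9000)])
        pairs = pair_set(link_transcript(snps, tiny_annotation))
        assert ("intronic", "txA1") in pairs
        assert ("past_end", "txA1") not in pairs


class TestLinkExon:
    def test_short_interval_hand_enumeration(self, tiny_annotation):
        # txA1 exons [1000,2000) [3000,4000) [6000,9000); introns
        # [2000,3000) and [4000,6000)
        cases = {
            ("in_exA1", 1500): {"exA1"},
            ("intron1", 2500): {"exA1", "exA2"},  # adjacent to both
            ("in_exA2", 3500): {"exA2"},
            ("intron2", 5000): {"exA2", "exA3"},
            ("in_exA3", 7000): {"exA3"},
            ("upstream", 900): set(),
        }
        snps = snp_frame([(name, "chr1", pos) for (name, pos) in cases])
        out = link_exon_short(snps, tiny_annotation)
        for (name, _), expect in cases.items():
            got = set(out[out.snp_id == name].feature_id)
            assert got == expect, name

    def test_two_introns_away_not_linked(self, tiny_annotation):
        snps = snp_frame([("far_intron", "chr1", 5000)])  # intron2: not adjacent to exA1
        out = link_exon_short(snps, tiny_annotation)
        assert "exA1" not in set(out.feature_id)

    def test_long_interval_contains_short(self, tiny_annotation):
        snps = snp_frame([(f"s{i}", "chr1", p) for i, p in enumerate(range(0, 12_000, 250))])
        short = pair_set(link_exon_short(snps, tiny_annotation))
        long = pair_set(link_exon_long(snps, tiny_annotation))
        assert short <= long

    def test_long_has_no_flank(self, tiny_annotation):
        snps = snp_frame([("up", "chr1", 999)])
        assert len(link_exon_long(snps, tiny_annotation)) == 0


class TestLinkOracles:
    def _bruteforce(self, snps, ann, flank=5000):
        gene, tx, ex_s, ex_l = set(), set(), set(), set()
        for s in snps.itertuples():
            for g in ann.genes.itertuples():
                if g.chrom == s.chrom and g.start - flank <= s.pos < g.end + flank:
                    gene.add((s.snp_id, g.gene_id))
            for t in ann.transcripts.itertuples():
                if t.chrom == s.chrom and t.start <= s.pos < t.end:
                    tx.add((s.snp_id, t.transcript_id))
            for t_id, exons in ann.exons.groupby("transcript_id"):
                exons = exons.sort_values("start").reset_index(drop=True)
                for i in range(len(exons)):
                    e = exons.iloc[i]
                    if e.chrom != s.chrom:
                        continue
                    lo = exons.iloc[i - 1].end if i > 0 else e.start
                    hi = exons.iloc[i + 1].start if i + 1 < len(exons) else e.end
                    if lo <= s.pos < hi:
                        ex_s.add((s.snp_id, e.exon_id))
            for e in ann.exons.drop_duplicates("exon_id").itertuples():
                g = ann.genes[ann.genes.gene_id == e.gene_id].iloc[0]
                if e.chrom == s.chrom and g.start <= s.pos < g.end:
                    ex_l.add((s.snp_id, e.exon_id))
        return {"gene": gene, "transcript": tx, "exon_short": ex_s, "exon_long": ex_l}

    @pytest.mark.parametrize("seed", range(8))
    def test_random_annotations_match_bruteforce(self, seed):
        cfg = SimulationConfig(seed=seed, n_genes=6, n_snps=1, chrom_lengths=(1_500_000, 1_500_000))
        ann = generate_annotation(cfg)
        rng = np.random.default_rng(seed + 100)
        snps = snp_frame(
            [
                (f"rs{i}", f"chr{int(rng.integers(1, 3))}", int(rng.integers(0, 1_500_000)))
                for i in range(120)
            ]
        )
        expect = self._bruteforce(snps, ann)
        got = link_all_levels(snps, ann)
        for level in LEVELS:
            assert pair_set(got[level]) == expect[level], level
        assert pair_set(got["exon_short"]) <= pair_set(got["exon_long"])


class TestRegression:
    def test_closed_form_example(self):
        # Sxy = sum (g - mean g) * y = 4.0, Sxx = 4.0 -> slope exactly 1.0
        res = fit_genotype_regression([1.0, 1.2, 1.9, 2.1, 3.0, 3.2], [1, 1, 2, 2, 3, 3])
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        lr = sps.linregress([1, 1, 2, 2, 3, 3], [1.0, 1.2, 1.9, 2.1, 3.0, 3.2])
        assert res.slope == pytest.approx(lr.slope, rel=1e-12)
        assert res.raw_p == pytest.approx(lr.pvalue, rel=1e-10)

    def test_constant_expression(self):
        res = fit_genotype_regression([2.0, 2.0, 2.0, 2.0], [1, 2, 2, 3])
        assert res.slope == 0.0 and res.raw_p == 1.0

    def test_perfect_fit_flagged(self):
        res = fit_genotype_regression([2.0, 4.0, 4.0, 6.0], [1, 2, 2, 3])
        assert res.perfect_fit and res.raw_p == 0.0 and res.slope == pytest.approx(2.0)

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fit_genotype_regression([1.0, 2.0, 3.0], [2, 2, 2])

    def test_matches_linregress_on_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 25))
            g = rng.integers(1, 4, n)
            if len(np.unique(g)) < 2:
                continue
            y = rng.normal(0, 1, n)
            res = fit_genotype_regression(y, g)
            lr = sps.linregress(g.astype(float), y)
            assert res.slope == pytest.approx(lr.slope, rel=1e-10)
            assert res.t_statistic == pytest.approx(lr.slope / lr.stderr, rel=1e-8)
            assert res.raw_p == pytest.approx(lr.pvalue, rel=1e-8)


def _scan_fixture(rng, n=12, maf=0.4):
    samples = [f"s{i}" for i in range(n)]
    calls = rng.binomial(2, maf, size=(4, n)) + 1
    ids = [f"rs{i}" for i in range(4)]
    snps = pd.DataFrame(
        {"snp_id": ids, "chrom": "chr1", "pos": [1500, 2500, 3500, 20_000], "ref": "A", "alt": "G"}
    )
    idx = pd.Index(ids, name="snp_id")
    gm = GenotypeMatrix(
        snps=snps,
        calls=pd.DataFrame(calls, index=idx, columns=samples),
        confidences=pd.DataFrame(np.full((4, n), 0.99), index=idx, columns=samples),
    )
    return samples, gm


class TestScan:
    def test_zero_pairs_empty(self, tiny_annotation, rng):
        samples, gm = _scan_fixture(rng)
        expr = pd.DataFrame(rng.normal(8, 1, (1, len(samples))), index=["geneA"], columns=samples)
        empty_pairs = pd.DataFrame(columns=["snp_id", "feature_id", "level", "snp_inside_feature"])
        out = run_snp_scan(empty_pairs, expr, gm, {"all": samples})
        assert len(out) == 0

    def test_unknown_sample_raises(self, tiny_annotation, rng):
        samples, gm = _scan_fixture(rng)
        expr = pd.DataFrame(rng.normal(8, 1, (1, len(samples))), index=["geneA"], columns=samples)
        pairs = link_gene(gm.snps, tiny_annotation)
        with pytest.raises(ValueError, match="unknown samples"):
            run_snp_scan(pairs, expr, gm, {"all": samples + ["ghost"]})

    def test_planted_eqtl_detected(self, tiny_annotation, rng):
        samples, gm = _scan_fixture(rng, n=20)
        g = gm.calls.loc["rs0"].to_numpy(dtype=float)
        expr = pd.DataFrame(
            rng.normal(8, 0.5, (2, 20)), index=["geneA", "geneB"], columns=samples
        )
        expr.loc["geneA"] += 1.0 * (g - 2)
        pairs = link_gene(gm.snps, tiny_annotation)
        out = run_snp_scan(pairs, expr, gm, {"all": samples}, alpha=0.10)
        rec = out[(out.snp_id == "rs0") & (out.feature_id == "geneA")].iloc[0]
        assert rec.significant and rec.slope == pytest.approx(1.0, abs=0.5)

    def test_whole_set_removal_propagates_to_subgroups(self, tiny_annotation):
        # variable within the subgroup but monomorphic outside it: the
        # all-sample variation filter removes the SNP from the subgroup too
        samples = [f"s{i}" for i in range(12)]
        calls = np.ones((1, 12), dtype=int)
        calls[0, :4] = [1, 2, 2, 3]  # subgroup MAF 0.5; all-sample MAF 4/24 < 0.25
        ids = pd.Index(["rs0"], name="snp_id")
        gm = GenotypeMatrix(
            snps=pd.DataFrame({"snp_id": ["rs0"], "chrom": "chr1", "pos": [1500], "ref": "A", "alt": "G"}),
            calls=pd.DataFrame(calls, index=ids, columns=samples),
            confidences=pd.DataFrame(np.full((1, 12), 0.95), index=ids, columns=samples),
        )
        expr = pd.DataFrame(np.random.default_rng(0).normal(8, 1, (1, 12)), index=["geneA"], columns=samples)
        pairs = link_gene(gm.snps, tiny_annotation)
        out = run_snp_scan(pairs, expr, gm, {"sub": samples[:4], "all": samples})
        assert len(out) == 0  # removed everywhere despite subgroup variability


class TestSummaries:
    def _results(self, rows):
        cols = ["snp_id", "feature_id", "level", "group", "significant", "snp_inside_feature"]
        df = pd.DataFrame(rows, columns=cols)
        df["adjusted_p"] = 0.01
        return df

    def test_single_gene_level_signal(self, tiny_annotation):
        res = self._results([("rs1", "geneA", "gene", "all", True, True)])
        s = summarize_overlaps(res, tiny_annotation)
        assert s["gene_venn"]["all"]["regions"] == {"gene": 1}
        assert s["families"]["gene|all"]["significant"] == 1

    def test_multi_level_signal_counted_once(self, tiny_annotation):
        res = self._results(
            [
                ("rs1", "geneA", "gene", "all", True, True),
                ("rs1", "txA1", "transcript", "all", True, True),
                ("rs1", "exA1", "exon_short", "all", True, True),
                ("rs1", "exA1", "exon_long", "all", True, True),
            ]
        )
        s = summarize_overlaps(res, tiny_annotation)
        venn = s["gene_venn"]["all"]
        assert venn["union"] == 1
        assert venn["regions"] == {"gene,transcript,exon_short,exon_long": 1}
        assert s["snps_significant_at_all_levels"]["all"] == 1

    def test_counts_match_set_algebra(self, tiny_annotation, rng):
        rows = []
        feats = ["geneA", "geneB", "txA1", "txB1", "exA1", "exB1"]
        lvl = {"geneA": "gene", "geneB": "gene", "txA1": "transcript", "txB1": "transcript",
               "exA1": "exon_short", "exB1": "exon_short"}
        for i in range(40):
            f = feats[int(rng.integers(len(feats)))]
            rows.append((f"rs{int(rng.integers(6))}", f, lvl[f], "all", bool(rng.random() < 0.5), True))
        res = self._results(rows)
        s = summarize_overlaps(res, tiny_annotation)
        union = set()
        gene_of = tiny_annotation.gene_of_feature()
        for level in LEVELS:
            sig = res[(res.level == level) & res.significant]
            union |= set(sig.feature_id.map(gene_of))
        assert s["gene_venn"]["all"]["union"] == len(union)
        assert sum(s["gene_venn"]["all"]["regions"].values()) == len(union)

    def test_cross_reference(self, tiny_annotation):
        snp_res = self._results([("rs1", "txA1", "transcript", "all", True, True)])
        cnv_res = pd.DataFrame(
            {"gene_id": ["geneA", "geneB"], "direction": ["gain", "loss"], "significant": [True, True]}
        )
        out = cross_reference_cnv(snp_res, cnv_res, tiny_annotation)
        assert list(out.gene_id) == ["geneA"]
        disjoint = cross_reference_cnv(
            self._results([("rs1", "geneB", "gene", "all", False, True)]), cnv_res, tiny_annotation
        )
        assert len(disjoint) == 0
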