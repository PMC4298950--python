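"""Synthetic-data generator: structure, determinism and planted truth."""

import numpy as np
import pandas as pd
import pytest

from stemqtl.cnv import filter_segments
from stemqtl.expression_qc import run_expression_qc
from stemqtl.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_cnv_segments,
    generate_expression,
    generate_genotypes,
    generate_motif_fixtures,
    make_samples,
    sample_genotypes,
    simulate_dataset,
)
from stemqtl.snp import link_all_levels
from stemqtl.tfbs import build_pwm


class TestConfig:
    def test_group_sizes_must_sum(self):
        with pytest.raises(ValueError, match="group_sizes"):
            SimulationConfig(group_sizes=(5, 5, 5)).validate()

    def test_noise_sd_positive(self):
        with pytest.raises(ValueError, match="noise_sd"):
            SimulationConfig(noise_sd=0.0).validate()

    def test_sample_sheet_design(self):
        samples = make_samples(SimulationConfig())
        assert list(samples.group.value_counts()[["hESC", "hiPSC", "fibroblast"]]) == [9, 8, 3]
        # every hiPSC line has a parent fibroblast
        assert (samples[samples.group == "hiPSC"].parent != "").all()


class TestAnnotation:
    def test_degenerate_nesting(self):
        cfg = SimulationConfig(n_genes=1, transcripts_per_gene=(1, 1), exons_per_transcript=(1, 1))
        ann = generate_annotation(cfg)
        g, t, e = ann.genes.iloc[0], ann.transcripts.iloc[0], ann.exons.iloc[0]
        assert (g.start, g.end) == (t.start, t.end) == (e.start, e.end)

    def test_deterministic_under_seed(self):
        a1 = generate_annotation(SimulationConfig(n_genes=10, seed=42))
        a2 = generate_annotation(SimulationConfig(n_genes=10, seed=42))
        pd.testing.assert_frame_equal(a1.genes, a2.genes)
        pd.testing.assert_frame_equal(a1.exons, a2.exons)

    def test_exhaustive_containment(self, default_dataset):
        ann = default_dataset.annotation
        tx_by_id = ann.transcripts.set_index("transcript_id")
        for e in ann.exons.itertuples():
            t = tx_by_id.loc[e.transcript_id]
            assert t.start <= e.start < e.end <= t.end
        gene_by_id = ann.genes.set_index("gene_id")
        for t in ann.transcripts.itertuples():
            g = gene_by_id.loc[t.gene_id]
            assert g.start <= t.start < t.end <= g.end

    def test_genes_do_not_overlap(self, default_dataset):
        for _, sub in default_dataset.annotation.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub.start.to_numpy()[1:] >= sub.end.to_numpy()[:-1]).all()

    def test_density_overflow_raises(self):
        with pytest.raises(ValueError, match="density"):
            generate_annotation(SimulationConfig(n_genes=500, chrom_lengths=(1_000_000, 1_000_000)))


class TestGenotypes:
    def test_monomorphic_at_zero_frequency(self, rng):
        assert (sample_genotypes(0.0, 50, rng) == 1).all()

    def test_hardy_weinberg_heterozygote_fraction(self, rng):
        # at p = 0.5 the heterozygote fraction is 2pq = 0.5
        g = sample_genotypes(0.5, 10_000, rng)
        het = (g == 2).mean()
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_byte_identical_under_seed(self):
        cfg = SimulationConfig(seed=9)
        ann = generate_annotation(cfg)
        g1 = generate_genotypes(cfg, ann)
        g2 = generate_genotypes(cfg, ann)
        pd.testing.assert_frame_equal(g1.calls, g2.calls)
        pd.testing.assert_frame_equal(g1.confidences, g2.confidences)

    def test_low_confidence_fraction_exercises_filter(self, default_dataset):
        conf = default_dataset.genotypes.confidences
        assert (conf < 0.9).any(axis=1).sum() > 0


class TestCNVSegments:
    def test_zero_events_empty(self):
        cfg = SimulationConfig(n_cnv_events=0)
        ann = generate_annotation(cfg)
        assert len(generate_cnv_segments(cfg, ann)) == 0

    def test_subthreshold_decoys_present(self, default_dataset):
        seg = default_dataset.cnv_segments
        surviving = filter_segments(seg, 5, 10_000)
        assert len(surviving) < len(seg)  # decoys were emitted and filtered

    def test_overlap_matches_bruteforce(self, default_dataset):
        ds = default_dataset
        genes = ds.annotation.genes
        for r in ds.cnv_segments.itertuples():
            hits = {
                g.gene_id
                for g in genes.itertuples()
                if g.chrom == r.chrom and g.start < r.end and g.end > r.start
            }
            vec = genes[(genes.chrom == r.chrom) & (genes.start < r.end) & (genes.end > r.start)]
            assert set(vec.gene_id) == hits

    def test_lineage_shared_segments(self, default_dataset):
        # at least one event is carried by a fibroblast and a derived hiPSC
        ds = default_dataset
        parents = dict(zip(ds.samples["sample"], ds.samples.parent))
        shared = False
        for (_, start), sub in ds.cnv_segments.groupby(["chrom", "start"]):
            carriers = set(sub["sample"])
            for c in carriers:
                if parents.get(c) and parents[c] in carriers:
                    shared = True
        assert shared


class TestExpression:
    def test_null_config_empty_truth(self):
        cfg = SimulationConfig(seed=2, eqtl_effect=0.0, cnv_effect=0.0, n_causal_snps=0, n_cnv_events=0)
        ann = generate_annotation(cfg)
        geno = generate_genotypes(cfg, ann)
        seg = generate_cnv_segments(cfg, ann)
        probes, truth = generate_expression(cfg, ann, geno, seg)
        assert truth.causal_snps == [] and truth.dosage_genes == []

    def test_noise_free_additive_limit(self):
        # effect 1.0 per allele step: mean(expr | geno 3) - mean(expr | geno 1) = 2
        cfg = SimulationConfig(seed=4, noise_sd=1e-9, eqtl_effect=1.0, n_cnv_events=0, n_causal_snps=5)
        ds = simulate_dataset(cfg)
        expr, _, _ = run_expression_qc(ds.probes)
        level_key = {"gene": "gene", "transcript": "transcript", "exon": "exon"}
        checked = 0
        for c in ds.truth.causal_snps:
            calls = ds.genotypes.calls.loc[c["snp_id"]]
            mat = expr[level_key[c["level"]]]
            vals = mat.loc[c["feature_id"]]
            g1, g3 = calls[calls == 1].index, calls[calls == 3].index
            if len(g1) and len(g3):
                diff = vals[g3].mean() - vals[g1].mean()
                assert diff == pytest.approx(2.0, abs=1e-6)
                checked += 1
        assert checked > 0

    def test_planted_gain_fold_change_at_low_noise(self):
        # +0.589 log2 per gained state: realized linear FC ~ 1.50
        cfg = SimulationConfig(seed=6, noise_sd=1e-9, cnv_effect=0.589, n_causal_snps=0)
        ds = simulate_dataset(cfg)
        expr, _, _ = run_expression_qc(ds.probes)
        gains = [d for d in ds.truth.dosage_genes if d["direction"] == "gain"]
        assert gains
        from stemqtl.cnv import label_gene_states

        labels = label_gene_states(ds.annotation, ds.cnv_segments, list(ds.samples["sample"]))
        for d in gains:
            states = labels.loc[d["gene_id"]]
            vals = expr["gene"].loc[d["gene_id"]]
            fc = 2 ** (vals[states[states == "gain"].index].mean() - vals[states[states == "normal"].index].mean())
            assert round(fc, 2) == pytest.approx(1.50, abs=0.01)

    def test_truth_table_closure(self, default_dataset):
        # every planted pair is linkable under the level it targets
        ds = default_dataset
        causal_ids = [c["snp_id"] for c in ds.truth.causal_snps]
        sub = ds.genotypes.snps[ds.genotypes.snps.snp_id.isin(causal_ids)]
        links = link_all_levels(sub, ds.annotation)
        need = {"gene": ["gene"], "transcript": ["transcript"], "exon": ["exon_short", "exon_long"]}
        for c in ds.truth.causal_snps:
            for level in need[c["level"]]:
                pairs = links[level]
                assert ((pairs.snp_id == c["snp_id"]) & (pairs.feature_id == c["feature_id"])).any()

    def test_antigenomic_probes_span_gc_range(self, default_dataset):
        anti = default_dataset.probes[default_dataset.probes.is_antigenomic]
        assert set(anti.gc) == set(range(6, 19))
        assert (anti.probeset_id == "").all()


class TestMotifFixtures:
    def test_consensus_hit_scores_one(self):
        motifs, alleles, hits = generate_motif_fixtures(SimulationConfig(seed=8))
        pwms = {m[0]: build_pwm(m[2]) for m in motifs}
        from stemqtl.tfbs import max_binding_score, relative_score

        for h in hits:
            rec = alleles[alleles.snp_id == h["snp_id"]].iloc[0]
            pwm = pwms[h["motif_id"]]
            assert relative_score(max_binding_score(rec.ref_seq, pwm), pwm) == pytest.approx(1.0)

    def test_uniform_motif_emitted_degenerate(self):
        motifs, _, _ = generate_motif_fixtures(SimulationConfig(seed=8))
        uniform = [m for m in motifs if m[0] == "M_uniform"]
        assert uniform and build_pwm(uniform[0][2]).degenerate

    def test_fixed_seed_identical_output(self):
        a = generate_motif_fixtures(SimulationConfig(seed=8))
        b = generate_motif_fixtures(SimulationConfig(seed=8))
        pd.testing.assert_frame_equal(a[1], b[1])
        for (ida, _, ca), (idb, _, cb) in zip(a[0], b[0]):
            assert ida == idb
            np.testing.assert_array_equal(ca, cb)


def test_dataset_roundtrip_to_disk(tmp_path, default_dataset):
    from stemqtl import io as io_mod
    from stemqtl.annotation import FeatureAnnotation

    out = tmp_path / "ds"
    default_dataset.write(out)
    paths = io_mod.dataset_paths(out)
    geno = io_mod.read_genotypes(paths["snps"], paths["genotypes"], paths["confidences"])
    pd.testing.assert_frame_equal(geno.calls, default_dataset.genotypes.calls)
    np.testing.assert_array_equal(geno.snps.pos, default_dataset.genotypes.snps.pos)
    ann = FeatureAnnotation.from_gtf(paths["annotation"])
    got = ann.genes.sort_values("gene_id").reset_index(drop=True)
    want = default_dataset.annotation.genes.sort_values("gene_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(got, want)
    probes = io_mod.read_probe_table(paths["probes"])
    assert len(probes) == len(default_dataset.probes)
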