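"""Generate a synthetic stem-cell array study with planted effects.

The generator emulates a 20-sample design (9 hESC, 8 hiPSC reprogrammed from
3 fibroblast lines): annotation, 1/2/3 genotypes, CNV segments, probe-level
expression with antigenomic background controls, motifs and allele flanks.
Every planted effect is recorded in a truth table.
"""

from stemqtl import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1))
print(f"samples: {len(ds.samples)}  ({dict(ds.samples.group.value_counts())})")
print(
    f"annotation: {len(ds.annotation.genes)} genes, "
    f"{len(ds.annotation.transcripts)} transcripts, "
    f"{ds.annotation.exons.exon_id.nunique()} exons"
)
print(f"genotypes: {len(ds.genotypes.snps)} SNPs x {len(ds.genotypes.samples)} samples")
print(f"CNV segments: {len(ds.cnv_segments)} (incl. sub-threshold decoys)")
print(f"probe table: {len(ds.probes)} probes (antigenomic: {int(ds.probes.is_antigenomic.sum())})")
print(f"planted: {len(ds.truth.causal_snps)} causal SNP-feature pairs, "
      f"{len(ds.truth.dosage_genes)} dosage-affected genes, "
      f"{len(ds.truth.motif_hits)} motif hits")
print("first causal pair:", ds.truth.causal_snps[0])
# The truth table is the reference for recovery tests: a perfect analysis
# would flag exactly these SNP-feature pairs and dosage genes.

ds.write("example_inputs")
print("fixture files written to example_inputs/")
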