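"""cis-eQTL scan: link SNPs to features at four interval definitions and
regress expression on the 1/2/3 genotype code.

Linking windows: gene span +/- 5000 bp; transcript span; exon plus adjacent
introns (short); whole gene area (long).  Regressions run separately for the
hESC, hiPSC and all-sample groups, each with its own variation re-filter and
BH family.
"""

import pandas as pd

from stemqtl import SimulationConfig, simulate_dataset
from stemqtl.cnv import filter_segments
from stemqtl.expression_qc import run_expression_qc
from stemqtl.genotype_qc import (ExclusionRegions, exclude_region_snps,
                                 filter_low_confidence, filter_low_variation)
from stemqtl.snp import LEVELS, link_all_levels, run_snp_scan, summarize_overlaps

ds = simulate_dataset(SimulationConfig(seed=1))
expr, _, _ = run_expression_qc(ds.probes)

# genotype QC: variation >= 25%, all confidences >= 0.9, outside CNV regions
seg = filter_segments(ds.cnv_segments, 5, 10_000)
geno = exclude_region_snps(
    filter_low_confidence(filter_low_variation(ds.genotypes)),
    ExclusionRegions(regions=seg[["sample", "chrom", "start", "end"]]),
)
print(f"SNPs surviving QC: {len(geno.snps)} of {len(ds.genotypes.snps)}")

groups = {
    "hESC": list(ds.samples[ds.samples.group == "hESC"]["sample"]),
    "hiPSC": list(ds.samples[ds.samples.group == "hiPSC"]["sample"]),
    "all": list(ds.samples["sample"]),
}
pairs = link_all_levels(geno.snps, ds.annotation, flank=5000)
expr_of = {"gene": expr["gene"], "transcript": expr["transcript"],
           "exon_short": expr["exon"], "exon_long": expr["exon"]}
res = pd.concat(
    [run_snp_scan(pairs[lv], expr_of[lv], geno, groups, alpha=0.10) for lv in LEVELS],
    ignore_index=True,
)
sig = res[res.significant]
print(f"tested {len(res)} (pair x group) regressions; {len(sig)} significant at adjusted p < 0.10")
top = sig.sort_values("adjusted_p").head(5)
print(top[["snp_id", "feature_id", "level", "group", "slope", "adjusted_p"]].round(4).to_string(index=False))
# slope is in log2 expression units per allele-dose step of the 1/2/3 coding.
summary = summarize_overlaps(res, ds.annotation)
print("gene-resolution Venn (all samples):", summary["gene_venn"]["all"]["regions"])
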