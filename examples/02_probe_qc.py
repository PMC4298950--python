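"""Probe-level QC cascade and probeset summarization.

Probes are kept only if their maximum intensity beats a GC-specific
background limit (mean + 2 SD of the antigenomic control probes of the same
GC content), are not flagged for cross-hybridization or SNP overlap, and
belong to a probeset with at least three surviving probes.
"""

from stemqtl import SimulationConfig, simulate_dataset
from stemqtl.expression_qc import run_expression_qc

ds = simulate_dataset(SimulationConfig(seed=1))
expr, kept, report = run_expression_qc(ds.probes, min_probes=3)

print("background limit for GC=6 :", round(report["thresholds"][6], 2), "(linear intensity)")
print("background limit for GC=18:", round(report["thresholds"][18], 2))
for step in ("input", "after_background_filter", "after_flag_filter", "after_small_probeset_mask"):
    print(f"{step:32s} {report[step]['probes']:5d} probes  {report[step]['probesets']}")
# Each step can only remove probes; probesets reduced below 3 probes are
# masked entirely because their summarized value would be unreliable.
for level, mat in expr.items():
    print(f"expression[{level}]: {mat.shape[0]} features x {mat.shape[1]} samples (log2)")
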