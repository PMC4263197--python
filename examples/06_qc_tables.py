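"""Post-merge QC: info filter, call-rate tables and the MAF spectrum.

Reproduces the structure of the standard post-imputation QC report:
markers dropped/remaining at each call-rate threshold, sample call
rates after the 99% marker filter, and the MAF distribution after the
info and call-rate filters.
"""

from imputemerge import SimulationConfig, simulate_reference, simulate_study
from imputemerge.pipeline import PipelineConfig, run_pipeline
from imputemerge.qc import (
    maf_table,
    marker_call_rate_table,
    sample_call_rate_table,
)
from imputemerge.simulate import coordinate_map_for

config = SimulationConfig(seed=1)
panel = simulate_reference(config)
datasets, map_entries, truth = simulate_study(config, panel)
result = run_pipeline(datasets, coordinate_map_for(map_entries), panel,
                      truth.study_haplotypes, PipelineConfig())
probs, info = result.merged.probs, result.merged.info

print(f"merged data: {probs.shape[0]} markers x {probs.shape[1]} samples "
      "(all already info > 0.7)")
print("marker call-rate thresholds (dropped / remaining):")
for s in marker_call_rate_table(probs):
    print(f"  {s.threshold:.2f}: {s.dropped:4d} / {s.remaining:4d} "
          f"({s.prop_dropped:.4f} / {s.prop_remaining:.4f})")
print("sample call rates after the 99% marker filter:")
for s in sample_call_rate_table(probs):
    print(f"  {s.threshold:.2f}: {s.dropped:4d} / {s.remaining:4d}")
print("MAF spectrum after info and 99% call-rate filters:")
for s in maf_table(probs, info):
    print(f"  {s.threshold:.4f}: {s.dropped:4d} dropped, {s.remaining:4d} remain")
# Every row satisfies dropped + remaining = total; proportions sum to 1.
# Samples are reported, never removed — that choice belongs to analysis.
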