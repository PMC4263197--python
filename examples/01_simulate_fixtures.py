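"""Generate a synthetic multi-platform study and inspect what was injected.

Builds a phased reference panel with block LD and three genotyping
"platforms" observing overlapping marker subsets, with strand flips,
stale-build coordinates, duplicate samples and missingness injected.
"""

from imputemerge import SimulationConfig, simulate_reference, simulate_study

config = SimulationConfig(seed=1)
panel = simulate_reference(config)
datasets, map_entries, truth = simulate_study(config, panel)

print(f"reference panel: {panel.n_markers} markers x {panel.n_haplotypes} haplotypes")
for ds in datasets:
    print(f"{ds.dataset_id}: {ds.n_markers} markers x {ds.n_samples} samples, "
          f"{len(truth.flipped[ds.dataset_id])} strand flips injected")
print(f"unmapped markers (lost in build conversion): {len(truth.unmapped)}")
print(f"duplicate samples across platforms: {len(truth.duplicates)}")
print(f"unique study individuals: {truth.n_unique_samples}")
# Each injected artifact is recorded in the truth store, so every
# pipeline stage's recovery can be checked against it.
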