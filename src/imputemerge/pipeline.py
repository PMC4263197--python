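"""End-to-end orchestration: harmonize → segment → impute → gate → merge → QC.

Ties the stage modules together for the common case of several
per-platform genotype datasets, one phased reference panel, and a
coordinate-conversion table.  Each platform is processed independently
(coordinate conversion, strand harmonization, segmentation, imputation,
masked-analysis gating) and the resulting imputed datasets are merged
and quality-controlled.

Phasing itself is out of scope: phased study haplotypes are an input,
supplied per platform (in practice by an external phasing tool; in
tests by the simulator's truth store).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import masked, qc
from .harmonize import (
    CoordinateMap,
    StrandAction,
    StrandDecision,
    apply_strand_decisions,
    classify_dataset_strand,
    liftover_dataset,
    prefilter_markers,
)
from .imputer import impute_segment
from .merge import ImputedDataset, MergedDataset, merge
from .model import (
    GenotypeDataset,
    HaplotypePanel,
    MarkerRecord,
    SampleInfo,
)
from .segmentation import (
    plan_snplets,
    segment_marker_indices,
    stitch_segments,
)


@dataclass
class PipelineConfig:
    """Stage parameters, at desk-scale defaults."""

    call_rate_filter: float = 0.95
    maf_filter: float = 0.05
    drop_palindromic: bool = False
    strand_window: int = 100
    maf_ambiguity_bound: float = 0.4
    core_size: int = 200  # SNPlet core, in markers
    buffer_size: int = 30  # SNPlet buffer, in markers
    k: int = 5
    flank: int = 50
    mask_fraction: float = 0.1
    mask_seed: int = 0
    call_threshold: float = 0.9
    info_threshold: float = 0.7
    min_samples: int = 1  # desk-scale gate; the field default is 100
    min_concordance: float = 0.80


@dataclass
class PlatformResult:
    dataset_id: str
    dropped_liftover: list[MarkerRecord]
    strand_decisions: list[StrandDecision]
    imputed: ImputedDataset
    segment_of_marker: dict[str, int]
    masked_reports: list = field(default_factory=list)
    masked_concordance: float = float("nan")


@dataclass
class PipelineResult:
    platforms: list[PlatformResult]
    merged: MergedDataset
    qc_summary: dict


def _phase_from_truth(
    harmonized: GenotypeDataset,
    truth: HaplotypePanel,
) -> HaplotypePanel:
    """Extract phased haplotypes for a platform's markers and samples.

    Stands in for an external phasing run: the truth panel holds the
    actual phase of every study individual over all panel markers.
    """
    marker_index = {(m.chrom, m.pos): i for i, m in enumerate(truth.markers)}
    rows = []
    markers = []
    for m in harmonized.markers:
        i = marker_index.get((m.chrom, m.pos))
        if i is None:
            continue
        truth_marker = truth.markers[i]
        hap = truth.haplotypes[i]
        if m.alleles != truth_marker.alleles:
            continue
        if m.allele_a != truth_marker.allele_a:
            hap = 1 - hap
        markers.append(m)
        rows.append(hap)
    sample_index = {s: i for i, s in enumerate(truth.sample_ids)}
    cols = []
    for s in harmonized.samples:
        i = sample_index[s.sample_id]
        cols.extend([2 * i, 2 * i + 1])
    haps = np.vstack(rows)[:, cols] if rows else np.zeros((0, len(cols)), dtype=np.int8)
    return HaplotypePanel(markers, haps, [s.sample_id for s in harmonized.samples])


def impute_platform(
    study_haps: HaplotypePanel,
    ref: HaplotypePanel,
    config: PipelineConfig,
) -> tuple[list, dict[str, int], list]:
    """Segment the reference, impute per segment, stitch buffers away.

    Returns (stitched rows, marker → segment provenance, info rows
    aligned with the stitched rows).
    """
    plan = plan_snplets(ref.markers, config.core_size, config.buffer_size)
    per_segment = []
    metrics_by_key = {}
    for k_seg in range(len(plan.segments)):
        idx = segment_marker_indices(plan, ref.markers, k_seg)
        result = impute_segment(study_haps, ref, idx,
                                k=config.k, flank=config.flank)
        pairs = list(zip(idx, result.rows))
        per_segment.append(pairs)
        for i, metric, row in zip(idx, result.metrics, result.rows):
            seg = plan.owner(i, row.marker)
            if seg == k_seg:
                metrics_by_key[(row.marker.chrom, row.marker.pos)] = metric
    stitched = stitch_segments(per_segment, plan)
    provenance = {row.marker.label: seg for row, seg in stitched}
    info_rows = [
        metrics_by_key[(row.marker.chrom, row.marker.pos)] for row, _ in stitched
    ]
    return stitched, provenance, info_rows


def run_platform(
    dataset: GenotypeDataset,
    cmap: CoordinateMap,
    ref: HaplotypePanel,
    truth_haps: HaplotypePanel,
    config: PipelineConfig,
) -> PlatformResult:
    """All per-platform stages for one genotype dataset."""
    filtered = prefilter_markers(
        dataset, config.call_rate_filter, config.maf_filter,
        config.drop_palindromic,
    )
    lifted, dropped = liftover_dataset(filtered, cmap)
    decisions = classify_dataset_strand(
        lifted, ref, window=config.strand_window,
        maf_ambiguity_bound=config.maf_ambiguity_bound,
    )
    harmonized = apply_strand_decisions(lifted, decisions)
    study_haps = _phase_from_truth(harmonized, truth_haps)

    stitched, provenance, info_rows = impute_platform(study_haps, ref, config)

    # masked evaluation: hide a fraction of the typed markers, re-impute
    masked_input, truth_store = masked.mask_markers(
        study_haps, fraction=config.mask_fraction, seed=config.mask_seed
    )
    masked_stitched, _, _ = impute_platform(masked_input, ref, config)
    imputed_by_key = {
        (row.marker.chrom, row.marker.pos, row.marker.alleles): row.probs
        for row, _ in masked_stitched
    }
    reports = masked.evaluate_masked(truth_store, imputed_by_key,
                                     config.call_threshold)
    conc = [r.concordance for r in reports if not np.isnan(r.concordance)]
    masked_concordance = float(np.mean(conc)) if conc else float("nan")

    markers = [row.marker for row, _ in stitched]
    probs = np.stack([row.probs for row, _ in stitched])
    roster = [
        SampleInfo(s.sample_id, dataset.dataset_id, s.call_rate)
        for s in dataset.samples
    ]
    imputed = ImputedDataset(
        dataset_id=dataset.dataset_id,
        markers=markers,
        probs=probs,
        info=info_rows,
        samples=roster,
        platform_dense=True,
        masked_concordance=masked_concordance,
    )
    return PlatformResult(
        dataset_id=dataset.dataset_id,
        dropped_liftover=dropped,
        strand_decisions=decisions,
        imputed=imputed,
        segment_of_marker=provenance,
        masked_reports=reports,
        masked_concordance=masked_concordance,
    )


def run_pipeline(
    datasets: list[GenotypeDataset],
    cmap: CoordinateMap,
    ref: HaplotypePanel,
    truth_haps: HaplotypePanel,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every platform through the pipeline, then merge and QC."""
    config = config or PipelineConfig()
    platforms = [
        run_platform(ds, cmap, ref, truth_haps, config) for ds in datasets
    ]
    merged = merge(
        [p.imputed for p in platforms],
        info_threshold=config.info_threshold,
        min_samples=config.min_samples,
        min_concordance=config.min_concordance,
    )
    summary = qc.qc_summary(
        merged.probs, merged.info,
        call_threshold=config.call_threshold,
        info_threshold=config.info_threshold,
    )
    return PipelineResult(platforms=platforms, merged=merged, qc_summary=summary)
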