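"""A deterministic nearest-haplotype imputer and the info-score metric.

This module stands in for a full hidden-Markov-model imputation engine
so the surrounding pipeline — segmentation, masked evaluation, merging,
QC — can be exercised end to end at desk scale.  The model is a
k-nearest-haplotype vote:

* Markers genotyped in the study (type 2, the *imputation basis*)
  dictate which reference haplotypes are copied: for each study
  haplotype and each untyped marker, the ``k`` reference haplotypes
  with the highest agreement (Hamming similarity) over the nearest
  ``flank`` typed markers are selected.
* The allele probability at the untyped marker is the
  agreement-weighted vote of the selected reference haplotypes, and the
  genotype triplet is the product over the individual's two haplotypes.
* Type-2 markers keep their observed genotypes as probability-1
  triplets.

Everything is deterministic given its inputs; ties in the neighbor
selection are broken by reference haplotype index.  The accompanying
:func:`info_score` is the ratio-of-variances imputation-certainty
metric: one minus the mean posterior dosage variance over samples,
relative to the binomial variance ``2·θ·(1−θ)`` expected at the
marker's estimated allele frequency θ.

Adapters: any external imputation engine whose output is a GEN +
info-metric file pair can be dropped into the pipeline in place of
:func:`impute_segment`; the downstream stages consume only
:class:`ImputationResult`-shaped data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    UNDEFINED,
    GenotypeProbabilityRow,
    HaplotypePanel,
    InfoMetricRow,
    MarkerRecord,
)


class ImputationError(ValueError):
    pass


@dataclass
class ImputationResult:
    """Per-segment imputation output over reference-panel markers."""

    rows: list[GenotypeProbabilityRow]
    metrics: list[InfoMetricRow]
    type_codes: list[int]


def expected_dosage_triplets(probs: np.ndarray) -> np.ndarray:
    """Expected allele-A dosage 2·P(AA) + 1·P(AB) per sample (NaN if missing)."""
    probs = np.asarray(probs, dtype=float)
    dosage = 2.0 * probs[..., 0] + probs[..., 1]
    missing = ~np.any(probs != 0, axis=-1)
    dosage = np.where(missing, np.nan, dosage)
    return dosage


def info_score(probs: np.ndarray) -> float:
    """IMPUTE-style info score for one marker's probability triplets.

    With per-sample expected dosage e_i = 2·pAA + pAB and posterior
    dosage variance v_i = 4·pAA + pAB − e_i², the score is

        1 − mean(v_i) / (2·θ·(1−θ)),   θ = mean(e_i) / 2.

    Returns 1.0 when all triplets are certain, and −1 (undefined) when
    the marker is monomorphic (θ ∈ {0, 1}) or all triplets are missing.
    """
    probs = np.asarray(probs, dtype=float)
    non_missing = np.any(probs != 0, axis=-1)
    if not non_missing.any():
        return UNDEFINED
    p = probs[non_missing]
    e = 2.0 * p[:, 0] + p[:, 1]
    v = 4.0 * p[:, 0] + p[:, 1] - e**2
    theta = float(e.mean()) / 2.0
    if theta <= 0.0 or theta >= 1.0:
        return UNDEFINED
    return float(1.0 - v.mean() / (2.0 * theta * (1.0 - theta)))


def _hap_allele_probs(
    study_haps: np.ndarray,
    ref_haps: np.ndarray,
    typed_idx: np.ndarray,
    untyped_idx: np.ndarray,
    k: int,
    flank: int,
) -> np.ndarray:
    """Allele-1 probability for each (untyped marker, study haplotype).

    For every untyped marker the nearest ``flank`` typed markers (by
    index, a contiguous block) define the agreement window; windows are
    shared between untyped markers where possible so each distinct
    window costs one matrix product.
    """
    n_study = study_haps.shape[1]
    n_ref = ref_haps.shape[1]
    out = np.zeros((len(untyped_idx), n_study))
    if len(typed_idx) == 0:
        raise ImputationError("segment has no study-typed (type-2) markers")
    flank = min(flank, len(typed_idx))
    k = min(k, n_ref)

    # window start in typed_idx for each untyped marker
    ins = np.searchsorted(typed_idx, untyped_idx)
    starts = np.clip(ins - flank // 2, 0, len(typed_idx) - flank)

    for start in np.unique(starts):
        window = typed_idx[start : start + flank]
        # study_haps holds one row per typed marker, in typed_idx order
        s = study_haps[start : start + flank, :].astype(np.float64)
        r = ref_haps[window, :].astype(np.float64)
        # matches = #positions where alleles agree, for every pair
        agreement = s.T @ r + (1.0 - s).T @ (1.0 - r)  # (n_study, n_ref)
        # top-k reference haplotypes per study haplotype, ties broken by
        # lower reference index: argsort on (-agreement, index)
        order = np.argsort(-agreement, axis=1, kind="stable")[:, :k]
        sel_weight = np.take_along_axis(agreement, order, axis=1)
        # guard all-zero weights (no agreement at all): fall back to equal
        wsum = sel_weight.sum(axis=1, keepdims=True)
        zero = wsum[:, 0] == 0
        sel_weight[zero] = 1.0
        wsum = sel_weight.sum(axis=1, keepdims=True)
        members = np.nonzero(starts == start)[0]
        for mi in members:
            alleles = ref_haps[untyped_idx[mi], :].astype(np.float64)
            votes = np.take_along_axis(
                np.broadcast_to(alleles, (n_study, n_ref)), order, axis=1
            )
            out[mi] = (votes * sel_weight).sum(axis=1) / wsum[:, 0]
    return out


def impute_segment(
    study: HaplotypePanel,
    ref: HaplotypePanel,
    marker_indices: list[int] | None = None,
    k: int = 5,
    flank: int = 50,
) -> ImputationResult:
    """Impute one segment of reference markers from phased study data.

    ``study`` must cover a subset of ``ref``'s markers (matched by
    chromosome, position and allele set, after harmonization).
    ``marker_indices`` restricts the work to a segment of reference
    marker indices (buffers included); default is all markers.

    Typed markers (present in the study) are emitted as probability-1
    triplets of the observed genotype and labeled type 2; untyped
    markers are imputed by the k-nearest-haplotype vote and labeled
    type 0.
    """
    if marker_indices is None:
        marker_indices = list(range(ref.n_markers))
    ref_markers = [ref.markers[i] for i in marker_indices]
    ref_haps = ref.haplotypes[marker_indices, :]

    study_index = {
        (m.chrom, m.pos, m.alleles): i for i, m in enumerate(study.markers)
    }
    typed_local: list[int] = []
    study_rows: list[int] = []
    for local, m in enumerate(ref_markers):
        j = study_index.get((m.chrom, m.pos, m.alleles))
        if j is not None:
            typed_local.append(local)
            study_rows.append(j)
    if not typed_local:
        raise ImputationError("segment has no study-typed (type-2) markers")

    typed_idx = np.array(typed_local, dtype=int)
    typed_set = set(typed_local)
    untyped_idx = np.array(
        [i for i in range(len(ref_markers)) if i not in typed_set], dtype=int
    )

    # study haplotypes laid out on the segment's typed markers, with the
    # 0/1 encoding re-oriented to the reference allele order
    n_haps = study.n_haplotypes
    study_on_typed = np.zeros((len(typed_idx), n_haps), dtype=np.int8)
    for row, (local, j) in enumerate(zip(typed_local, study_rows)):
        hap = study.haplotypes[j, :]
        if study.markers[j].allele_a != ref_markers[local].allele_a:
            hap = 1 - hap
        study_on_typed[row] = hap

    allele1 = np.zeros((len(ref_markers), n_haps))
    allele1[typed_idx, :] = study_on_typed
    if len(untyped_idx):
        allele1[untyped_idx, :] = _hap_allele_probs(
            study_on_typed, ref_haps, typed_idx, untyped_idx, k, flank
        )

    # per-individual genotype triplets: product over the two haplotypes
    p1 = allele1[:, 0::2]  # P(allele B) on haplotype 1
    p2 = allele1[:, 1::2]
    p_bb = p1 * p2
    p_aa = (1 - p1) * (1 - p2)
    p_ab = 1.0 - p_aa - p_bb
    triplets = np.stack([p_aa, p_ab, p_bb], axis=-1)
    triplets = np.clip(triplets, 0.0, 1.0)

    rows: list[GenotypeProbabilityRow] = []
    metrics: list[InfoMetricRow] = []
    type_codes: list[int] = []
    for local, m in enumerate(ref_markers):
        t = 2 if local in typed_set else 0
        marker = MarkerRecord(m.chrom, m.pos, m.label, m.allele_a, m.allele_b,
                              type_code=t)
        probs = triplets[local]
        row = GenotypeProbabilityRow(marker, probs)
        e = expected_dosage_triplets(probs)
        freq_a1 = float(np.nanmean(e)) / 2.0 if np.any(~np.isnan(e)) else UNDEFINED
        certainty = float(probs.max(axis=1).mean())
        metrics.append(
            InfoMetricRow(
                snp_id="---",
                rs_id=m.label,
                position=m.pos,
                exp_freq_a1=freq_a1,
                info=info_score(probs),
                certainty=certainty,
                type_code=t,
            )
        )
        rows.append(row)
        type_codes.append(t)
    return ImputationResult(rows=rows, metrics=metrics, type_codes=type_codes)
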