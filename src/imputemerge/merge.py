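"""Merging many per-platform imputed datasets into one.

Each site/platform dataset is imputed separately (pre-imputation
merging fails for lack of overlapping markers), then the imputed
probability files are combined:

* datasets are **gated**: fewer than 100 samples, a non-genome-wide
  platform, or masked-analysis concordance below 80% excludes a
  dataset from the merge;
* markers are **cross-matched by position and alleles** rather than by
  label, and only markers of high quality in *all* eligible datasets
  (info score strictly above 0.7) are kept;
* the output **label** is the most common label among the inputs;
  plurality ties between rs-style labels go to the larger rs number;
  a label attached to more than one position drops every position
  bearing it;
* per-dataset rows are **allele-aligned** to the first (anchor)
  dataset: a reversed allele order swaps P(AA)↔P(BB) per sample and
  sends ``1 − exp_freq_a1`` into the frequency average;
* **info metrics** are merged per marker: ``snp_id`` becomes ``---``,
  ``type`` is the numeric minimum of the inputs, every other column is
  the equally weighted mean of the inputs with −1 sentinels ignored
  (all-−1 → −1), and the merged ``exp_freq_a1`` is reported for the
  minor allele;
* **duplicate samples** across datasets keep only the copy from the
  platform with the higher call rate (ties go to the earlier dataset
  in plan order, with a warning).
"""

from __future__ import annotations

import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .model import (
    UNDEFINED,
    GenotypeProbabilityRow,
    InfoMetricRow,
    MarkerKey,
    MarkerRecord,
    SampleInfo,
)


class MergeError(ValueError):
    pass


@dataclass
class ImputedDataset:
    """One platform's imputed output, ready for merging.

    ``probs`` has shape (n_markers, n_samples, 3); ``info`` aligns
    one-to-one with ``markers``.  ``platform_dense`` records whether
    the genotyping platform was dense and genome-wide;
    ``masked_concordance`` is the dataset's mean masked-analysis
    concordance (NaN when not measured).
    """

    dataset_id: str
    markers: list[MarkerRecord]
    probs: np.ndarray
    info: list[InfoMetricRow]
    samples: list[SampleInfo]
    platform_dense: bool = True
    masked_concordance: float = float("nan")

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.markers), len(self.samples), 3):
            raise MergeError(
                f"dataset {self.dataset_id}: probs shape {self.probs.shape} vs "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        if len(self.info) != len(self.markers):
            raise MergeError(
                f"dataset {self.dataset_id}: {len(self.info)} info rows for "
                f"{len(self.markers)} markers"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class MergePlan:
    """Everything decided before rows are combined."""

    dataset_ids: list[str]  # ordered; first eligible = alignment anchor
    eligible: dict[str, bool]
    exclusion_reasons: dict[str, list[str]]
    marker_keys: list[MarkerKey]  # intersection, sorted
    label_map: dict[MarkerKey, str]
    dropped_keys: dict[MarkerKey, str]  # key -> reason
    sample_winner: dict[str, str]  # sample_id -> winning dataset_id


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

def gate_datasets(
    datasets: list[ImputedDataset],
    min_samples: int = 100,
    min_concordance: float = 0.80,
) -> tuple[dict[str, bool], dict[str, list[str]]]:
    """Eligibility flags plus recorded exclusion reasons."""
    eligible: dict[str, bool] = {}
    reasons: dict[str, list[str]] = {}
    for ds in datasets:
        why = []
        if ds.n_samples < min_samples:
            why.append(f"only {ds.n_samples} samples (< {min_samples})")
        if not ds.platform_dense:
            why.append("platform is not dense genome-wide")
        if not np.isnan(ds.masked_concordance) and ds.masked_concordance < min_concordance:
            why.append(
                f"masked concordance {ds.masked_concordance:.3f} < {min_concordance}"
            )
        eligible[ds.dataset_id] = not why
        reasons[ds.dataset_id] = why
    return eligible, reasons


# ---------------------------------------------------------------------------
# Marker intersection and labeling
# ---------------------------------------------------------------------------

def intersect_markers(
    datasets: list[ImputedDataset],
    info_threshold: float = 0.7,
) -> set[MarkerKey]:
    """Marker keys present in every dataset with info strictly above 0.7."""
    if not datasets:
        return set()
    per_dataset = []
    for ds in datasets:
        keys = {
            m.key
            for m, inf in zip(ds.markers, ds.info)
            if inf.info > info_threshold
        }
        per_dataset.append(keys)
    return set.intersection(*per_dataset)


_RS_RE = re.compile(r"^rs(\d+)$")


def _label_rank(label: str) -> tuple:
    """Tie-break rank: rs labels by number, others lexicographically below."""
    m = _RS_RE.match(label)
    if m:
        return (1, int(m.group(1)), label)
    return (0, 0, label)


def resolve_labels(
    per_key_labels: dict[MarkerKey, list[str]],
) -> tuple[dict[MarkerKey, str], dict[MarkerKey, str]]:
    """Choose one output label per marker key.

    (1) the most common label wins; (2) plurality ties go to the larger
    rs number (lexicographically larger for non-rs labels); (3) any
    label attached to more than one distinct position drops *all*
    positions bearing it.

    Returns (label map, dropped keys with reasons).
    """
    label_map: dict[MarkerKey, str] = {}
    for key, labels in per_key_labels.items():
        counts = Counter(labels)
        top = max(counts.values())
        candidates = [lab for lab, c in counts.items() if c == top]
        label_map[key] = max(candidates, key=_label_rank)

    positions_by_label: dict[str, set[tuple[str, int]]] = defaultdict(set)
    for key, label in label_map.items():
        positions_by_label[label].add((key.chrom, key.pos))
    dropped: dict[MarkerKey, str] = {}
    for label, positions in positions_by_label.items():
        if len(positions) > 1:
            for key in [k for k, lab in label_map.items() if lab == label]:
                dropped[key] = (
                    f"label {label} maps to {len(positions)} distinct positions"
                )
    for key in dropped:
        del label_map[key]
    return label_map, dropped


# ---------------------------------------------------------------------------
# Allele alignment
# ---------------------------------------------------------------------------

def align_alleles(
    marker: MarkerRecord,
    probs: np.ndarray,
    anchor: MarkerRecord,
) -> tuple[np.ndarray, bool]:
    """Align one dataset's row to the anchor's allele order.

    Returns (aligned probabilities, reversed flag).  A reversed row has
    P(AA) and P(BB) swapped per sample.  Applying the swap twice is the
    identity.
    """
    if marker.alleles != anchor.alleles:
        raise MergeError(
            f"marker {marker.label}: alleles {sorted(marker.alleles)} vs anchor "
            f"{sorted(anchor.alleles)}"
        )
    if marker.allele_a == anchor.allele_a:
        return probs, False
    return probs[..., ::-1], True


# ---------------------------------------------------------------------------
# Info-row merging
# ---------------------------------------------------------------------------

def _sentinel_mean(values: list[float]) -> float:
    """Equal-weight mean ignoring −1 sentinels; all-−1 gives −1."""
    kept = [v for v in values if v != UNDEFINED]
    if not kept:
        return UNDEFINED
    return float(np.mean(kept))


def merge_info_rows(
    rows: list[InfoMetricRow],
    reversed_flags: list[bool],
    rs_id: str,
    position: int,
    minor_allele_orientation: bool = True,
) -> InfoMetricRow:
    """Merge one marker's per-dataset info rows.

    ``snp_id`` is always ``---``; ``type`` is the numeric minimum of
    the inputs; other columns are equally weighted means with −1 inputs
    ignored.  ``exp_freq_a1`` values from allele-reversed inputs enter
    the average as ``1 − value``; with ``minor_allele_orientation`` the
    averaged frequency is finally folded to the minor allele (≤ 0.5),
    otherwise it stays anchor-relative.
    """
    if len(rows) != len(reversed_flags):
        raise MergeError("one reversed flag required per input row")
    freqs = []
    for row, rev in zip(rows, reversed_flags):
        f = row.exp_freq_a1
        if f != UNDEFINED and rev:
            f = 1.0 - f
        freqs.append(f)
    exp_freq = _sentinel_mean(freqs)
    if minor_allele_orientation and exp_freq != UNDEFINED and exp_freq > 0.5:
        exp_freq = 1.0 - exp_freq
    return InfoMetricRow(
        snp_id="---",
        rs_id=rs_id,
        position=position,
        exp_freq_a1=exp_freq,
        info=_sentinel_mean([r.info for r in rows]),
        certainty=_sentinel_mean([r.certainty for r in rows]),
        type_code=min(r.type_code for r in rows),
        info_type0=_sentinel_mean([r.info_type0 for r in rows]),
        concord_type0=_sentinel_mean([r.concord_type0 for r in rows]),
        r2_type0=_sentinel_mean([r.r2_type0 for r in rows]),
    )


# ---------------------------------------------------------------------------
# Duplicate samples
# ---------------------------------------------------------------------------

def resolve_duplicate_samples(
    datasets: list[ImputedDataset],
) -> dict[str, str]:
    """One winning dataset per sample_id, by the higher call rate.

    A duplicate pair with missing call rates (or an exact tie) goes to
    the earlier dataset in plan order, with a warning.
    """
    occurrences: dict[str, list[tuple[int, str, float | None]]] = defaultdict(list)
    for order, ds in enumerate(datasets):
        for s in ds.samples:
            occurrences[s.sample_id].append((order, ds.dataset_id, s.call_rate))
    winners: dict[str, str] = {}
    for sample_id, occ in occurrences.items():
        if len(occ) == 1:
            winners[sample_id] = occ[0][1]
            continue
        rates = [r for _, _, r in occ]
        if any(r is None for r in rates) or len(set(rates)) < len(rates):
            best = max(occ, key=lambda t: (-1.0 if t[2] is None else t[2], -t[0]))
            known = [r for r in rates if r is not None]
            if any(r is None for r in rates) or (known and known.count(max(known)) > 1):
                warnings.warn(
                    f"sample {sample_id}: duplicate call rates tied or missing; "
                    f"keeping {best[1]} (first in plan order)",
                    stacklevel=2,
                )
            winners[sample_id] = best[1]
        else:
            winners[sample_id] = max(occ, key=lambda t: t[2])[1]
    return winners


# ---------------------------------------------------------------------------
# Full merge
# ---------------------------------------------------------------------------

def plan_merge(
    datasets: list[ImputedDataset],
    info_threshold: float = 0.7,
    min_samples: int = 100,
    min_concordance: float = 0.80,
) -> MergePlan:
    eligible, reasons = gate_datasets(datasets, min_samples, min_concordance)
    kept = [ds for ds in datasets if eligible[ds.dataset_id]]
    if not kept:
        raise MergeError(
            "no dataset is eligible for merging: "
            + "; ".join(f"{d}: {', '.join(r)}" for d, r in reasons.items())
        )
    keys = intersect_markers(kept, info_threshold)
    per_key_labels: dict[MarkerKey, list[str]] = defaultdict(list)
    for ds in kept:
        for m in ds.markers:
            if m.key in keys:
                per_key_labels[m.key].append(m.label)
    label_map, dropped = resolve_labels(per_key_labels)
    winners = resolve_duplicate_samples(kept)
    return MergePlan(
        dataset_ids=[ds.dataset_id for ds in datasets],
        eligible=eligible,
        exclusion_reasons=reasons,
        marker_keys=sorted(label_map, key=MarkerKey.sort_key),
        label_map=label_map,
        dropped_keys=dropped,
        sample_winner=winners,
    )


@dataclass
class MergedDataset:
    markers: list[MarkerRecord]
    probs: np.ndarray  # (n_markers, n_samples, 3)
    info: list[InfoMetricRow]
    samples: list[SampleInfo]
    plan: MergePlan = field(repr=False, default=None)

    def rows(self) -> list[GenotypeProbabilityRow]:
        return [
            GenotypeProbabilityRow(m, self.probs[i])
            for i, m in enumerate(self.markers)
        ]


def merge(
    datasets: list[ImputedDataset],
    plan: MergePlan | None = None,
    info_threshold: float = 0.7,
    min_samples: int = 100,
    min_concordance: float = 0.80,
    minor_allele_orientation: bool = True,
) -> MergedDataset:
    """Merge eligible datasets into one probability + info + roster set.

    One output row per surviving marker key, sorted by (chromosome,
    position); sample columns are the concatenation of each dataset's
    winning samples in plan order.
    """
    if plan is None:
        plan = plan_merge(datasets, info_threshold, min_samples, min_concordance)
    kept = [ds for ds in datasets if plan.eligible[ds.dataset_id]]

    # winning sample columns per dataset
    col_keep: dict[str, list[int]] = {}
    out_samples: list[SampleInfo] = []
    for ds in kept:
        cols = [
            j
            for j, s in enumerate(ds.samples)
            if plan.sample_winner.get(s.sample_id) == ds.dataset_id
        ]
        col_keep[ds.dataset_id] = cols
        out_samples.extend(ds.samples[j] for j in cols)

    key_index = [
        {m.key: i for i, m in enumerate(ds.markers)} for ds in kept
    ]
    n_out = len(plan.marker_keys)
    n_samples = len(out_samples)
    probs_out = np.zeros((n_out, n_samples, 3))
    markers_out: list[MarkerRecord] = []
    info_out: list[InfoMetricRow] = []

    for r, key in enumerate(plan.marker_keys):
        anchor_marker = kept[0].markers[key_index[0][key]]
        label = plan.label_map[key]
        col0 = 0
        info_rows: list[InfoMetricRow] = []
        reversed_flags: list[bool] = []
        for d, ds in enumerate(kept):
            i = key_index[d][key]
            aligned, rev = align_alleles(ds.markers[i], ds.probs[i], anchor_marker)
            cols = col_keep[ds.dataset_id]
            probs_out[r, col0 : col0 + len(cols), :] = aligned[cols, :]
            col0 += len(cols)
            info_rows.append(ds.info[i])
            reversed_flags.append(rev)
        markers_out.append(
            MarkerRecord(
                chrom=key.chrom,
                pos=key.pos,
                label=label,
                allele_a=anchor_marker.allele_a,
                allele_b=anchor_marker.allele_b,
                type_code=min(r_.type_code for r_ in info_rows),
            )
        )
        info_out.append(
            merge_info_rows(
                info_rows,
                reversed_flags,
                rs_id=label,
                position=key.pos,
                minor_allele_orientation=minor_allele_orientation,
            )
        )
    return MergedDataset(markers_out, probs_out, info_out, out_samples, plan)
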