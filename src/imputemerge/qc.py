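"""Post-merge quality control: filters and threshold summary tables.

The merged probabilistic genotypes are filtered and summarized along
three axes, mirroring standard post-imputation practice:

* **info score** — a per-marker quality filter at info > 0.7 (more
  liberal 0.3 and more conservative 0.9 variants are common);
* **call rate** — hard calls (argmax triplet when the max probability
  reaches a threshold, default 0.9) give per-marker and per-sample
  call rates, summarized at thresholds {0.95, 0.98, 0.99}; sample call
  rates are reported but samples are not removed;
* **MAF** — the minor-allele-frequency spectrum after the info and
  99% marker-call-rate filters, summarized at thresholds from 0.05
  down to 0.0001, with monomorphic markers excluded (a marker must
  carry at least one copy of the minor allele).

Each summary row satisfies dropped + remaining = total and the two
proportions sum to one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import InfoMetricRow

CALL_RATE_THRESHOLDS = (0.95, 0.98, 0.99)
MAF_THRESHOLDS = (0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001)


@dataclass(frozen=True)
class ThresholdSummary:
    threshold: float
    dropped: int
    remaining: int

    @property
    def total(self) -> int:
        return self.dropped + self.remaining

    @property
    def prop_dropped(self) -> float:
        return self.dropped / self.total if self.total else 0.0

    @property
    def prop_remaining(self) -> float:
        return self.remaining / self.total if self.total else 0.0


def hard_call(probs: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Best-guess genotypes from probability triplets.

    ``probs`` has shape (..., 3) ordered (AA, AB, BB); returns the
    argmax genotype index (equal to the allele-B count) when the max
    probability reaches ``threshold``, else -1 (missing).
    """
    probs = np.asarray(probs, dtype=float)
    best = probs.argmax(axis=-1)
    called = probs.max(axis=-1) >= threshold
    return np.where(called, best, -1).astype(np.int8)


def filter_info(
    info: list[InfoMetricRow], threshold: float = 0.7
) -> tuple[list[int], list[int]]:
    """Kept/dropped marker indices at info strictly above ``threshold``."""
    kept, dropped = [], []
    for i, row in enumerate(info):
        (kept if row.info > threshold else dropped).append(i)
    return kept, dropped


def _summaries(values: np.ndarray, thresholds) -> list[ThresholdSummary]:
    out = []
    for t in thresholds:
        dropped = int((values < t).sum())
        out.append(ThresholdSummary(t, dropped, int(values.size) - dropped))
    return out


def marker_call_rates(probs: np.ndarray, call_threshold: float = 0.9) -> np.ndarray:
    """Fraction of called samples per marker; probs is (M, N, 3)."""
    calls = hard_call(probs, call_threshold)
    if calls.shape[1] == 0:
        return np.zeros(calls.shape[0])
    return (calls != -1).mean(axis=1)


def sample_call_rates(probs: np.ndarray, call_threshold: float = 0.9) -> np.ndarray:
    calls = hard_call(probs, call_threshold)
    if calls.shape[0] == 0:
        return np.zeros(calls.shape[1])
    return (calls != -1).mean(axis=0)


def marker_call_rate_table(
    probs: np.ndarray,
    thresholds=CALL_RATE_THRESHOLDS,
    call_threshold: float = 0.9,
) -> list[ThresholdSummary]:
    """SNPs dropped/remaining at each marker call-rate threshold."""
    return _summaries(marker_call_rates(probs, call_threshold), thresholds)


def sample_call_rate_table(
    probs: np.ndarray,
    thresholds=CALL_RATE_THRESHOLDS,
    call_threshold: float = 0.9,
    marker_filter: float = 0.99,
) -> list[ThresholdSummary]:
    """Samples dropped/remaining per sample call-rate threshold.

    Markers with call rate below ``marker_filter`` (default 99%) are
    removed first; the per-sample rates are then summarized.  This is
    a report — samples are not removed from the data.
    """
    rates = marker_call_rates(probs, call_threshold)
    kept = probs[rates >= marker_filter]
    return _summaries(sample_call_rates(kept, call_threshold), thresholds)


def hard_call_maf(probs: np.ndarray, call_threshold: float = 0.9) -> np.ndarray:
    """Per-marker MAF from hard calls (NaN where nothing is callable)."""
    calls = hard_call(probs, call_threshold).astype(float)
    calls[calls == -1] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=1) / 2.0
    return np.minimum(freq, 1.0 - freq)


def dosage_maf(probs: np.ndarray) -> np.ndarray:
    """Per-marker MAF from expected dosages (alternative to hard calls)."""
    probs = np.asarray(probs, dtype=float)
    dose_b = probs[..., 1] + 2.0 * probs[..., 2]
    missing = ~np.any(probs != 0, axis=-1)
    dose_b = np.where(missing, np.nan, dose_b)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dose_b, axis=1) / 2.0
    return np.minimum(freq, 1.0 - freq)


def maf_table(
    probs: np.ndarray,
    info: list[InfoMetricRow],
    thresholds=MAF_THRESHOLDS,
    call_threshold: float = 0.9,
    info_threshold: float = 0.7,
    marker_filter: float = 0.99,
    use_dosage: bool = False,
) -> list[ThresholdSummary]:
    """MAF spectrum after the info and marker-call-rate filters.

    Monomorphic markers (no copy of a minor allele) are excluded from
    the totals; ``dropped`` counts markers with MAF strictly below each
    threshold.
    """
    kept_info, _ = filter_info(info, info_threshold)
    probs = probs[kept_info]
    rates = marker_call_rates(probs, call_threshold)
    probs = probs[rates >= marker_filter]
    maf = dosage_maf(probs) if use_dosage else hard_call_maf(probs, call_threshold)
    maf = maf[~np.isnan(maf) & (maf > 0)]
    return _summaries(maf, thresholds)


def qc_summary(
    probs: np.ndarray,
    info: list[InfoMetricRow],
    call_threshold: float = 0.9,
    info_threshold: float = 0.7,
) -> dict:
    """Machine-readable QC report covering all three table families."""
    kept, dropped = filter_info(info, info_threshold)
    filtered = probs[kept]
    return {
        "n_markers": int(probs.shape[0]),
        "n_samples": int(probs.shape[1]),
        "info_filter": {
            "threshold": info_threshold,
            "kept": len(kept),
            "dropped": len(dropped),
        },
        "marker_call_rate": [
            vars(s) | {"prop_dropped": s.prop_dropped, "prop_remaining": s.prop_remaining}
            for s in marker_call_rate_table(filtered, call_threshold=call_threshold)
        ],
        "sample_call_rate": [
            vars(s) | {"prop_dropped": s.prop_dropped, "prop_remaining": s.prop_remaining}
            for s in sample_call_rate_table(filtered, call_threshold=call_threshold)
        ],
        "maf": [
            vars(s) | {"prop_dropped": s.prop_dropped, "prop_remaining": s.prop_remaining}
            for s in maf_table(probs, info, call_threshold=call_threshold,
                               info_threshold=info_threshold)
        ],
    }
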