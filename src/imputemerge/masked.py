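"""Masked-genotype evaluation of imputation quality.

A masked analysis hides a subset of markers that were actually
genotyped, re-imputes them as though they were not, and scores the
imputed probabilities against the hidden truth.  Two scores are
computed per masked marker:

* **concordance** — fraction of hard-called imputed genotypes that
  match the truth, over samples with a non-missing truth genotype and
  a callable imputed triplet (max probability ≥ ``call_threshold``);
* **allelic R²** — squared Pearson correlation between the truth
  dosages (0/1/2 hard counts) and the imputed expected dosages
  ``2·P(AA) + 1·P(AB) + 0·P(BB)`` across individuals.

Concordance at rare markers is optimistic: always predicting the major
homozygote already exceeds 90% concordance when MAF < 5%, so both
scores should be read within MAF bins (see :func:`summarize_by_maf`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imputer import expected_dosage_triplets
from .model import HaplotypePanel, MarkerRecord


class MaskedEvalError(ValueError):
    pass


def expected_dosage(triplet: tuple[float, float, float]) -> float:
    """Expected allele-A dosage 2·P(AA) + 1·P(AB) + 0·P(BB)."""
    p_aa, p_ab, p_bb = triplet
    if p_aa == p_ab == p_bb == 0:
        return float("nan")
    return 2.0 * p_aa + 1.0 * p_ab + 0.0 * p_bb


@dataclass
class MaskedSnpReport:
    marker: MarkerRecord
    maf: float
    concordance: float  # NaN when no sample is callable
    allelic_r2: float  # NaN when undefined
    r_signed: float  # signed dosage correlation, for diagnostics
    n_samples: int


def mask_markers(
    panel: HaplotypePanel,
    fraction: float | None = None,
    explicit: list[str] | None = None,
    seed: int = 0,
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Split phased study data into (masked input, hidden truth).

    Either a ``fraction`` of markers is drawn reproducibly from
    ``seed``, or an ``explicit`` list of marker labels is masked.
    The masked panel (markers removed) is what the imputer sees; the
    truth panel retains the original data at the masked markers.
    """
    if (fraction is None) == (explicit is None):
        raise MaskedEvalError("specify exactly one of fraction / explicit")
    n = panel.n_markers
    if explicit is not None:
        labels = set(explicit)
        masked_idx = [i for i, m in enumerate(panel.markers) if m.label in labels]
        if len(masked_idx) != len(labels):
            found = {panel.markers[i].label for i in masked_idx}
            raise MaskedEvalError(f"unknown markers: {sorted(labels - found)}")
    else:
        if not 0.0 < fraction < 1.0:
            raise MaskedEvalError(f"mask fraction {fraction} outside (0,1)")
        n_mask = int(round(fraction * n))
        rng = np.random.default_rng(seed)
        masked_idx = sorted(rng.choice(n, size=n_mask, replace=False).tolist())
    masked_set = set(masked_idx)
    keep_idx = [i for i in range(n) if i not in masked_set]
    return panel.subset_markers(keep_idx), panel.subset_markers(masked_idx)


def concordance(
    truth: np.ndarray,
    imputed_probs: np.ndarray,
    call_threshold: float = 0.9,
) -> tuple[float, int]:
    """Hard-call concordance between truth genotypes and imputed triplets.

    ``truth`` holds genotypes in {0,1,2} (count of allele B; -1 or NaN
    missing); ``imputed_probs`` has shape (n_samples, 3) ordered
    (AA, AB, BB).  The best-guess genotype is the argmax triplet when
    its probability reaches ``call_threshold``, else no-call.  Returns
    (fraction of matches among called samples, number called); the
    fraction is NaN when nothing is callable.
    """
    truth = np.asarray(truth, dtype=float)
    probs = np.asarray(imputed_probs, dtype=float)
    best = probs.argmax(axis=1)
    callable_ = (probs.max(axis=1) >= call_threshold) & np.any(probs != 0, axis=1)
    usable = callable_ & ~np.isnan(truth) & (truth >= 0)
    n_called = int(usable.sum())
    if n_called == 0:
        return float("nan"), 0
    # genotype index 0=AA,1=AB,2=BB equals the allele-B count
    matches = (best[usable] == truth[usable]).sum()
    return float(matches / n_called), n_called


def allelic_r2(truth: np.ndarray, imputed_probs: np.ndarray) -> tuple[float, float]:
    """Squared (and signed) dosage correlation at one masked marker.

    ``truth`` is the hard allele count in {0,1,2}; imputed expected
    dosages come from the probability triplets.  Returns (r², r); both
    NaN when fewer than two usable samples remain or either vector is
    constant.
    """
    truth = np.asarray(truth, dtype=float)
    imputed = expected_dosage_triplets(np.asarray(imputed_probs, dtype=float))
    # expected_dosage_triplets counts allele A; convert to allele-B
    # dosage so both vectors count the same allele
    imputed = 2.0 - imputed
    usable = ~np.isnan(truth) & (truth >= 0) & ~np.isnan(imputed)
    if usable.sum() < 2:
        return float("nan"), float("nan")
    t, x = truth[usable], imputed[usable]
    if t.std() == 0 or x.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(t, x)[0, 1])
    return r * r, r


def evaluate_masked(
    truth_panel: HaplotypePanel,
    imputed_rows: dict[tuple, np.ndarray],
    call_threshold: float = 0.9,
) -> list[MaskedSnpReport]:
    """Score imputed triplets against the hidden truth panel.

    ``imputed_rows`` maps marker keys ``(chrom, pos, alleles)`` to
    (n_samples, 3) probability arrays in the truth panel's sample
    order and allele orientation.
    """
    reports = []
    truth_dosages = truth_panel.dosages()
    mafs = truth_panel.minor_allele_freq()
    for i, m in enumerate(truth_panel.markers):
        probs = imputed_rows.get((m.chrom, m.pos, m.alleles))
        if probs is None:
            continue
        truth = truth_dosages[i].astype(float)
        conc, n_called = concordance(truth, probs, call_threshold)
        r2, r = allelic_r2(truth, probs)
        reports.append(
            MaskedSnpReport(
                marker=m,
                maf=float(mafs[i]),
                concordance=conc,
                allelic_r2=r2,
                r_signed=r,
                n_samples=n_called,
            )
        )
    return reports


def summarize_by_maf(
    reports: list[MaskedSnpReport],
    bin_width: float = 0.1,
    infos: dict[str, float] | None = None,
) -> list[dict]:
    """Equal-weight per-bin means of concordance, R² and info by MAF.

    Bins are ``[k·w, (k+1)·w)`` over [0, 0.5]; undefined (NaN) values
    are excluded from the means; per-bin marker counts are reported.
    ``infos`` optionally maps marker labels to info scores to average
    alongside (−1 treated as undefined).
    """
    if not reports:
        raise MaskedEvalError("no masked-marker reports to summarize")
    n_bins = int(np.ceil(0.5 / bin_width))
    table = []
    for k in range(n_bins):
        lo, hi = k * bin_width, (k + 1) * bin_width
        members = [r for r in reports if lo <= r.maf < hi or (r.maf == 0.5 and hi >= 0.5)]
        conc = [r.concordance for r in members if not np.isnan(r.concordance)]
        r2 = [r.allelic_r2 for r in members if not np.isnan(r.allelic_r2)]
        info_vals = []
        if infos is not None:
            info_vals = [
                infos[r.marker.label]
                for r in members
                if r.marker.label in infos and infos[r.marker.label] != -1
            ]
        table.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_snps": len(members),
                "mean_concordance": float(np.mean(conc)) if conc else float("nan"),
                "mean_allelic_r2": float(np.mean(r2)) if r2 else float("nan"),
                "mean_info": float(np.mean(info_vals)) if info_vals else float("nan"),
            }
        )
    return table


def major_homozygote_concordance(truth: np.ndarray) -> float:
    """Concordance of the trivial always-major-homozygote predictor.

    A useful floor when reading concordance at rare markers: at
    MAF < 5% this predictor already exceeds 90%.
    """
    truth = np.asarray(truth, dtype=float)
    usable = ~np.isnan(truth) & (truth >= 0)
    if usable.sum() == 0:
        return float("nan")
    t = truth[usable]
    freq_b = t.mean() / 2.0
    major_genotype = 0.0 if freq_b < 0.5 else 2.0
    return float((t == major_genotype).mean())


def mergeable(reports: list[MaskedSnpReport], min_concordance: float = 0.80) -> bool:
    """Dataset-level gate: mean masked concordance must reach 80%."""
    conc = [r.concordance for r in reports if not np.isnan(r.concordance)]
    if not conc:
        return False
    return float(np.mean(conc)) >= min_concordance
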