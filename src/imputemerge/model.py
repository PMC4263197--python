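"""Core domain types shared by every pipeline stage.

The pipeline moves genotype data through a small set of containers:

* :class:`MarkerRecord` — one biallelic variant, with its chromosome,
  1-based position, allele pair and an optional panel-membership code.
* :class:`GenotypeProbabilityRow` — the three-genotype probability
  triplets (AA, AB, BB) for one marker across a sample roster.
* :class:`InfoMetricRow` — the per-marker quality metrics that accompany
  probabilistic genotype files (expected allele-1 frequency, info score,
  certainty, panel type and the masked-analysis columns), with ``-1`` as
  the only sanctioned "undefined" sentinel.
* :class:`HaplotypePanel` — a phased 0/1 haplotype matrix, two columns
  per diploid individual, used both for the reference panel and for
  phased study data.
* :class:`SampleInfo` / rosters — sample identity plus dataset
  provenance; probability files carry no sample ids themselves, so the
  roster is authoritative for column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

VALID_ALLELES = frozenset("ACGT")

#: Panel-membership codes: 0/1 reference-only (phased/unphased), 2
#: genotyped in the study (the imputation basis), 3 study-only.
TYPE_REF_ONLY = 0
TYPE_REF_UNPHASED = 1
TYPE_BASIS = 2
TYPE_STUDY_ONLY = 3

#: Sentinel for "undefined" in metric columns.
UNDEFINED = -1.0


class ModelError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass(frozen=True, order=True)
class MarkerRecord:
    """One biallelic SNV.

    Parameters
    ----------
    chrom : str
        Chromosome label ("1".."22").
    pos : int
        Base-pair position, 1-based.
    label : str
        Marker name (rs-style or platform-specific id).
    allele_a, allele_b : str
        The two alleles; ``allele_a`` is whichever allele the file lists
        first, with no major/minor convention implied.
    type_code : int or None
        Panel-membership code (0/1/2/3) when known.
    """

    chrom: str
    pos: int
    label: str
    allele_a: str
    allele_b: str
    type_code: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ModelError(f"marker {self.label}: position {self.pos} < 1")
        if self.allele_a == self.allele_b:
            raise ModelError(f"marker {self.label}: identical alleles {self.allele_a}")
        for allele in (self.allele_a, self.allele_b):
            if allele not in VALID_ALLELES:
                raise ModelError(
                    f"marker {self.label}: allele {allele!r} not one of A,C,G,T"
                )
        if self.type_code is not None and self.type_code not in (0, 1, 2, 3):
            raise ModelError(f"marker {self.label}: type_code {self.type_code}")

    @property
    def alleles(self) -> frozenset[str]:
        """Unordered allele set."""
        return frozenset((self.allele_a, self.allele_b))

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return self.alleles in (frozenset("AT"), frozenset("CG"))

    @property
    def key(self) -> "MarkerKey":
        return MarkerKey(self.chrom, self.pos, self.alleles)

    def with_alleles(self, allele_a: str, allele_b: str) -> "MarkerRecord":
        return replace(self, allele_a=allele_a, allele_b=allele_b)


@dataclass(frozen=True)
class MarkerKey:
    """Cross-dataset marker identity: position plus unordered alleles.

    Marker labels differ between platforms, so datasets are matched on
    (chromosome, position, allele pair) with allele order ignored.
    """

    chrom: str
    pos: int
    alleles: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", frozenset(self.alleles))

    def sort_key(self) -> tuple:
        return (_chrom_order(self.chrom), self.pos, tuple(sorted(self.alleles)))


def _chrom_order(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**6, chrom)


def marker_sort_key(marker: MarkerRecord) -> tuple:
    return (_chrom_order(marker.chrom), marker.pos, marker.label)


@dataclass
class GenotypeProbabilityRow:
    """Per-sample genotype probability triplets for one marker.

    ``probs`` has shape (n_samples, 3) ordered (AA, AB, BB) relative to
    ``marker.allele_a``/``allele_b``.  The all-zero triplet encodes a
    missing genotype.  Triplets are stored exactly as read; no silent
    renormalization.
    """

    marker: MarkerRecord
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ModelError(
                f"marker {self.marker.label}: probs shape {self.probs.shape}"
            )
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ModelError(f"marker {self.marker.label}: probability outside [0,1]")
        if np.any(self.probs.sum(axis=1) > 1 + 1e-3):
            raise ModelError(f"marker {self.marker.label}: triplet sums exceed 1")

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of samples with the all-zero (missing) triplet."""
        return ~self.probs.any(axis=1)


#: Column order of the ten-column info-metric file.
INFO_COLUMNS = (
    "snp_id",
    "rs_id",
    "position",
    "exp_freq_a1",
    "info",
    "certainty",
    "type",
    "info_type0",
    "concord_type0",
    "r2_type0",
)


@dataclass
class InfoMetricRow:
    """Per-marker quality metrics accompanying a probability file.

    Metric columns live in [0, 1]; ``-1`` means undefined and is the
    only permitted out-of-range value.
    """

    snp_id: str
    rs_id: str
    position: int
    exp_freq_a1: float
    info: float
    certainty: float
    type_code: int
    info_type0: float = UNDEFINED
    concord_type0: float = UNDEFINED
    r2_type0: float = UNDEFINED

    METRIC_FIELDS = (
        "exp_freq_a1",
        "info",
        "certainty",
        "info_type0",
        "concord_type0",
        "r2_type0",
    )

    def __post_init__(self) -> None:
        for name in self.METRIC_FIELDS:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0 or value == UNDEFINED):
                raise ModelError(
                    f"info row {self.rs_id}: {name}={value} outside [0,1] and not -1"
                )


@dataclass(frozen=True)
class SampleInfo:
    """One study sample with dataset provenance and an optional call rate."""

    sample_id: str
    dataset_id: str
    call_rate: float | None = None

    def __post_init__(self) -> None:
        if self.call_rate is not None and not 0.0 <= self.call_rate <= 1.0:
            raise ModelError(f"sample {self.sample_id}: call rate {self.call_rate}")


def check_roster(samples: Sequence[SampleInfo]) -> None:
    """Enforce roster uniqueness: sample_id unique within a dataset."""
    seen: set[tuple[str, str]] = set()
    for s in samples:
        key = (s.sample_id, s.dataset_id)
        if key in seen:
            raise ModelError(f"duplicate sample {s.sample_id} in {s.dataset_id}")
        seen.add(key)


@dataclass
class HaplotypePanel:
    """Phased haplotypes over an ordered marker list.

    ``haplotypes`` has shape (n_markers, 2 * n_individuals) with entries
    strictly in {0, 1}: 0 encodes ``allele_a``, 1 encodes ``allele_b``
    of the corresponding marker.  Columns 2i and 2i+1 are the two
    chromosome copies of individual ``sample_ids[i]``.
    """

    markers: list[MarkerRecord]
    haplotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ModelError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[0] != len(self.markers):
            raise ModelError(
                f"{len(self.markers)} markers but {self.haplotypes.shape[0]} rows"
            )
        if self.haplotypes.shape[1] % 2:
            raise ModelError("haplotype count must be even (two per individual)")
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ModelError("haplotype entries must be 0 or 1")
        keys = [marker_sort_key(m)[:2] for m in self.markers]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ModelError("markers must be strictly sorted by (chrom, pos)")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(self.n_individuals)]
        if len(self.sample_ids) != self.n_individuals:
            raise ModelError(
                f"{len(self.sample_ids)} sample ids for {self.n_individuals} individuals"
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[1] // 2

    def dosages(self) -> np.ndarray:
        """Diploid allele-B dosage matrix, shape (n_markers, n_individuals)."""
        return self.haplotypes[:, 0::2] + self.haplotypes[:, 1::2]

    def allele_b_freq(self) -> np.ndarray:
        """Allele-B frequency per marker across all haplotypes."""
        return self.haplotypes.mean(axis=1)

    def minor_allele_freq(self) -> np.ndarray:
        freq = self.allele_b_freq()
        return np.minimum(freq, 1.0 - freq)

    def subset_markers(self, indices: Iterable[int]) -> "HaplotypePanel":
        idx = list(indices)
        return HaplotypePanel(
            [self.markers[i] for i in idx],
            self.haplotypes[idx, :],
            list(self.sample_ids),
        )


@dataclass
class GenotypeDataset:
    """One platform's genotype data: hard calls plus provenance.

    ``genotypes`` has shape (n_markers, n_samples) with values in
    {0, 1, 2} counting copies of ``allele_b``, and -1 for missing.
    """

    dataset_id: str
    markers: list[MarkerRecord]
    genotypes: np.ndarray
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.markers), len(self.samples)):
            raise ModelError(
                f"dataset {self.dataset_id}: genotype matrix "
                f"{self.genotypes.shape} vs {len(self.markers)} markers "
                f"x {len(self.samples)} samples"
            )
        if self.genotypes.size and not np.isin(self.genotypes, (-1, 0, 1, 2)).all():
            raise ModelError(f"dataset {self.dataset_id}: genotypes outside {{-1,0,1,2}}")
        check_roster(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dosages(self) -> np.ndarray:
        """Float dosage matrix with missing entries as NaN."""
        d = self.genotypes.astype(float)
        d[self.genotypes == -1] = np.nan
        return d

    def marker_call_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return (self.genotypes != -1).mean(axis=1)

    def sample_call_rates(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return (self.genotypes != -1).mean(axis=0)

    def minor_allele_freq(self) -> np.ndarray:
        """Per-marker MAF from non-missing hard calls (NaN if all missing)."""
        d = self.dosages()
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(d, axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_markers(self, indices: Iterable[int]) -> "GenotypeDataset":
        idx = list(indices)
        return GenotypeDataset(
            self.dataset_id,
            [self.markers[i] for i in idx],
            self.genotypes[idx, :],
            list(self.samples),
        )
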