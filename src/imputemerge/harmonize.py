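"""Genome-build conversion and strand harmonization.

Genotyping platforms report alleles on inconsistent strands and, at
times, on stale genome builds.  Before imputation every study dataset
must agree with the reference panel on both.  Two stages handle this:

1. **Coordinate conversion** — a precomputed old-build → new-build
   table is applied in four steps: drop markers with indeterminate
   mappings, update marker names, update chromosomes, update positions;
   the result is re-sorted by (chromosome, position).
2. **Strand checking** — alleles are switched to their complementary
   alleles (A↔T, C↔G) based on three criteria: the observed alleles,
   the minor allele frequencies, and the LD pattern within 100-SNP
   windows.  Markers whose MAF and LD patterns are inconsistent and
   cannot be resolved by flipping are discarded.

A strand flip relabels a marker's alleles with their complements; the
0/1 (or dosage) encoding is untouched, because the encoding follows the
relabeled alleles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model import (
    GenotypeDataset,
    HaplotypePanel,
    MarkerRecord,
    marker_sort_key,
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class HarmonizeError(ValueError):
    pass


def complement(alleles: tuple[str, str]) -> tuple[str, str]:
    """Complement an allele pair (A↔T, C↔G); an involution."""
    try:
        return (_COMPLEMENT[alleles[0]], _COMPLEMENT[alleles[1]])
    except KeyError as exc:
        raise HarmonizeError(f"unsupported allele {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordinateMapEntry:
    """One marker's old-build → new-build mapping.

    ``status`` is ``mapped`` or ``unmapped``; unmapped entries carry no
    new coordinates.
    """

    old_chrom: str
    old_pos: int
    old_label: str
    new_chrom: str | None = None
    new_pos: int | None = None
    new_label: str | None = None
    status: str = "mapped"

    def __post_init__(self) -> None:
        if self.status not in ("mapped", "unmapped"):
            raise HarmonizeError(f"bad map status {self.status!r}")
        if self.status == "mapped" and (self.new_chrom is None or self.new_pos is None):
            raise HarmonizeError(
                f"mapped entry for {self.old_label} lacks new coordinates"
            )


class CoordinateMap:
    """Lookup table keyed by (old_chrom, old_pos, old_label)."""

    def __init__(self, entries: list[CoordinateMapEntry]):
        self._table: dict[tuple[str, int, str], CoordinateMapEntry] = {}
        for e in entries:
            key = (e.old_chrom, e.old_pos, e.old_label)
            if key in self._table:
                raise HarmonizeError(f"duplicate map entry for {key}")
            self._table[key] = e

    def lookup(self, marker: MarkerRecord) -> CoordinateMapEntry | None:
        return self._table.get((marker.chrom, marker.pos, marker.label))

    def __len__(self) -> int:
        return len(self._table)


def read_coordinate_map(path: str | os.PathLike) -> CoordinateMap:
    """Read the 7-column tab-separated conversion table.

    Columns: old_chrom, old_pos, old_label, new_chrom, new_pos,
    new_label, status.  Unmapped rows use ``.`` for the new columns.
    """
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise HarmonizeError(
                    f"{path}: line {lineno}: expected 7 tab-separated fields"
                )
            status = fields[6]
            if status == "unmapped":
                entries.append(
                    CoordinateMapEntry(fields[0], int(fields[1]), fields[2],
                                       status="unmapped")
                )
            else:
                entries.append(
                    CoordinateMapEntry(
                        fields[0], int(fields[1]), fields[2],
                        fields[3], int(fields[4]), fields[5], status,
                    )
                )
    return CoordinateMap(entries)


def write_coordinate_map(
    path: str | os.PathLike, entries: list[CoordinateMapEntry]
) -> None:
    with open(path, "w") as fh:
        for e in entries:
            if e.status == "unmapped":
                new = (".", ".", ".")
            else:
                new = (e.new_chrom, str(e.new_pos), e.new_label or e.old_label)
            fh.write("\t".join([e.old_chrom, str(e.old_pos), e.old_label,
                                *new, e.status]) + "\n")


def apply_coordinate_map(
    markers: list[MarkerRecord],
    cmap: CoordinateMap,
) -> tuple[list[MarkerRecord], list[int], list[MarkerRecord]]:
    """Convert marker coordinates to the new build.

    Markers that are unmapped (or absent from the table) are dropped.
    Surviving markers get updated names, chromosomes and positions, and
    are re-sorted by (chromosome, position).

    Returns
    -------
    (mapped, order, dropped)
        ``mapped`` — converted markers in sorted order; ``order`` — for
        each output marker, its index in the input list (so data rows
        can be carried along); ``dropped`` — input markers removed.
    """
    converted: list[tuple[MarkerRecord, int]] = []
    dropped: list[MarkerRecord] = []
    for i, m in enumerate(markers):
        entry = cmap.lookup(m)
        if entry is None or entry.status == "unmapped":
            dropped.append(m)
            continue
        converted.append(
            (
                MarkerRecord(
                    chrom=entry.new_chrom,
                    pos=entry.new_pos,
                    label=entry.new_label or m.label,
                    allele_a=m.allele_a,
                    allele_b=m.allele_b,
                    type_code=m.type_code,
                ),
                i,
            )
        )
    converted.sort(key=lambda pair: marker_sort_key(pair[0]))
    seen: dict[tuple, str] = {}
    for m, _ in converted:
        key = (m.chrom, m.pos, m.alleles)
        if key in seen:
            raise HarmonizeError(
                f"markers {seen[key]} and {m.label} both map to "
                f"{m.chrom}:{m.pos} with alleles {sorted(m.alleles)}"
            )
        seen[key] = m.label
    mapped = [m for m, _ in converted]
    order = [i for _, i in converted]
    return mapped, order, dropped


def liftover_dataset(
    dataset: GenotypeDataset, cmap: CoordinateMap
) -> tuple[GenotypeDataset, list[MarkerRecord]]:
    """Apply a coordinate map to a dataset, reordering genotype rows."""
    mapped, order, dropped = apply_coordinate_map(dataset.markers, cmap)
    return (
        GenotypeDataset(dataset.dataset_id, mapped,
                        dataset.genotypes[order, :], dataset.samples),
        dropped,
    )


# ---------------------------------------------------------------------------
# Pre-harmonization marker QC
# ---------------------------------------------------------------------------

def prefilter_markers(
    dataset: GenotypeDataset,
    call_rate: float = 0.95,
    maf: float = 0.05,
    drop_palindromic: bool = False,
) -> GenotypeDataset:
    """Input-data QC applied before strand checking.

    Removes markers with call rate below ``call_rate`` or minor allele
    frequency below ``maf``; optionally also removes palindromic (A/T,
    C/G) markers, whose strand can never be verified from alleles alone.
    """
    rates = dataset.marker_call_rates()
    mafs = dataset.minor_allele_freq()
    keep = []
    for i, m in enumerate(dataset.markers):
        if rates[i] < call_rate:
            continue
        if np.isnan(mafs[i]) or mafs[i] < maf:
            continue
        if drop_palindromic and m.is_palindromic:
            continue
        keep.append(i)
    return dataset.subset_markers(keep)


# ---------------------------------------------------------------------------
# Strand checking
# ---------------------------------------------------------------------------

class StrandAction(Enum):
    KEEP = "keep"
    FLIP = "flip"
    DISCARD = "discard"


class StrandBasis(Enum):
    ALLELE_MATCH = "allele_match"
    MAF = "maf"
    LD = "ld"


@dataclass(frozen=True)
class StrandDecision:
    marker: MarkerRecord
    action: StrandAction
    basis: StrandBasis
    detail: str = ""


@dataclass
class StrandNeighbor:
    """Study/reference dosage vectors for one flanking marker.

    ``orientation`` is +1 when the study allele encoding (after any
    strand complement) lines up with the reference allele order, -1
    when reversed, so correlation signs compare like with like.
    """

    study: np.ndarray
    ref: np.ndarray
    orientation: int = 1


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return np.nan
    x, y = x[mask], y[mask]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _minor_allele(freq_b: float, marker: MarkerRecord) -> str | None:
    if np.isnan(freq_b) or freq_b == 0.5:
        return None
    return marker.allele_b if freq_b < 0.5 else marker.allele_a


def classify_strand(
    study_marker: MarkerRecord,
    study_dosages: np.ndarray,
    ref_marker: MarkerRecord,
    ref_freq_b: float,
    ref_dosages: np.ndarray | None = None,
    neighbors: list[StrandNeighbor] | None = None,
    maf_ambiguity_bound: float = 0.4,
    ld_r_min: float = 0.2,
    min_informative: int = 3,
) -> StrandDecision:
    """Decide keep / flip / discard for one study marker.

    Decision procedure:

    1. study allele set equals the reference set, non-palindromic → keep;
    2. equals the complemented reference set, non-palindromic → flip;
    3. palindromic: if both study and reference MAF ≤
       ``maf_ambiguity_bound``, match the study minor allele against the
       reference minor allele (keep) or its complement (flip);
    4. MAF uninformative → arbitrate by LD: compare signs of dosage
       correlations with flanking non-palindromic markers in study vs
       reference; a strict majority of informative neighbors
       (|r_ref| ≥ ``ld_r_min``) with inverted sign → flip, with
       consistent sign → keep;
    5. otherwise, or when allele sets are incompatible even after
       complementing, discard.

    ``study_dosages`` counts copies of ``study_marker.allele_b`` (NaN
    for missing); ``ref_freq_b`` / ``ref_dosages`` describe
    ``ref_marker.allele_b`` in the reference panel.
    """
    study_set = study_marker.alleles
    ref_set = ref_marker.alleles
    comp_ref_set = frozenset(complement(tuple(ref_set)))

    if not study_marker.is_palindromic:
        if study_set == ref_set:
            return StrandDecision(study_marker, StrandAction.KEEP,
                                  StrandBasis.ALLELE_MATCH, "alleles match")
        if study_set == comp_ref_set:
            return StrandDecision(study_marker, StrandAction.FLIP,
                                  StrandBasis.ALLELE_MATCH,
                                  "alleles match after complement")
        return StrandDecision(study_marker, StrandAction.DISCARD,
                              StrandBasis.ALLELE_MATCH,
                              "allele sets incompatible")

    if study_set != ref_set:
        # palindromic sets are complement-invariant; a mismatch is fatal
        return StrandDecision(study_marker, StrandAction.DISCARD,
                              StrandBasis.ALLELE_MATCH,
                              "allele sets incompatible")

    study_dosages = np.asarray(study_dosages, dtype=float)
    if np.any(~np.isnan(study_dosages)):
        study_freq_b = float(np.nanmean(study_dosages)) / 2.0
        study_maf = min(study_freq_b, 1.0 - study_freq_b)
    else:
        study_freq_b = study_maf = np.nan
    ref_maf = min(ref_freq_b, 1.0 - ref_freq_b)

    if (
        not np.isnan(study_maf)
        and study_maf <= maf_ambiguity_bound
        and ref_maf <= maf_ambiguity_bound
    ):
        study_minor = _minor_allele(study_freq_b, study_marker)
        ref_minor = _minor_allele(ref_freq_b, ref_marker)
        if study_minor is not None and ref_minor is not None:
            if study_minor == ref_minor:
                return StrandDecision(study_marker, StrandAction.KEEP,
                                      StrandBasis.MAF,
                                      f"minor alleles agree ({study_minor})")
            if study_minor == _COMPLEMENT[ref_minor]:
                return StrandDecision(
                    study_marker, StrandAction.FLIP, StrandBasis.MAF,
                    f"study minor {study_minor} is the complement of "
                    f"reference minor {ref_minor}",
                )

    # --- LD arbitration -----------------------------------------------
    if not neighbors or ref_dosages is None:
        return StrandDecision(study_marker, StrandAction.DISCARD,
                              StrandBasis.LD, "no informative neighbors")
    # Alignment of the written study allele order with the reference
    # order under the keep (same-strand) hypothesis.  For palindromic
    # markers the allele letters always literally match one of the
    # reference alleles.
    target_sign = 1 if study_marker.allele_b == ref_marker.allele_b else -1
    inverted = consistent = 0
    for nb in neighbors:
        r_ref = _safe_corr(np.asarray(ref_dosages, dtype=float), nb.ref)
        if np.isnan(r_ref) or abs(r_ref) < ld_r_min:
            continue
        r_study = _safe_corr(study_dosages, np.asarray(nb.study, dtype=float))
        if np.isnan(r_study) or r_study == 0:
            continue
        expected = target_sign * np.sign(r_ref) * nb.orientation
        if np.sign(r_study) == expected:
            consistent += 1
        else:
            inverted += 1
    informative = inverted + consistent
    if informative < min_informative:
        return StrandDecision(
            study_marker, StrandAction.DISCARD, StrandBasis.LD,
            f"only {informative} informative neighbors",
        )
    if inverted * 2 > informative:
        return StrandDecision(
            study_marker, StrandAction.FLIP, StrandBasis.LD,
            f"{inverted}/{informative} neighbors with inverted LD sign",
        )
    if consistent * 2 > informative:
        return StrandDecision(
            study_marker, StrandAction.KEEP, StrandBasis.LD,
            f"{consistent}/{informative} neighbors with consistent LD sign",
        )
    return StrandDecision(
        study_marker, StrandAction.DISCARD, StrandBasis.LD,
        f"LD signs tied ({inverted} inverted vs {consistent} consistent)",
    )


def _neighbor_orientation(study: MarkerRecord, ref: MarkerRecord) -> int | None:
    """Orientation of a non-palindromic matched neighbor, or None."""
    if study.is_palindromic or ref.is_palindromic:
        return None
    if study.alleles == ref.alleles:
        return 1 if study.allele_b == ref.allele_b else -1
    if frozenset(complement((study.allele_a, study.allele_b))) == ref.alleles:
        return 1 if _COMPLEMENT[study.allele_b] == ref.allele_b else -1
    return None


def classify_dataset_strand(
    dataset: GenotypeDataset,
    ref: HaplotypePanel,
    window: int = 100,
    maf_ambiguity_bound: float = 0.4,
    ld_r_min: float = 0.2,
    min_informative: int = 3,
) -> list[StrandDecision]:
    """Strand decisions for every marker of a study dataset.

    Study and reference markers are matched by (chromosome, position);
    study markers with no reference counterpart are discarded.  For
    palindromic markers needing LD arbitration, up to ``window``
    nearest non-palindromic matched markers serve as neighbors.
    """
    ref_index = {(m.chrom, m.pos): i for i, m in enumerate(ref.markers)}
    study_dosages = dataset.dosages()
    ref_dosage_mat = ref.dosages().astype(float)
    ref_freqs = ref.allele_b_freq()

    matched: list[tuple[int, int, int | None]] = []  # (study idx, ref idx, orientation)
    for i, m in enumerate(dataset.markers):
        j = ref_index.get((m.chrom, m.pos))
        if j is not None:
            matched.append((i, j, _neighbor_orientation(m, ref.markers[j])))
    # candidate neighbors: matched, non-palindromic, allele-compatible
    neighbor_pool = [(i, j, o) for i, j, o in matched if o is not None]

    decisions: list[StrandDecision] = []
    matched_ref = {i: (j, o) for i, j, o in matched}
    for i, m in enumerate(dataset.markers):
        if i not in matched_ref:
            decisions.append(
                StrandDecision(m, StrandAction.DISCARD,
                               StrandBasis.ALLELE_MATCH,
                               "no reference marker at this position")
            )
            continue
        j, _ = matched_ref[i]
        neighbors = None
        if m.is_palindromic:
            pool = [(si, ri, o) for si, ri, o in neighbor_pool if si != i]
            pool.sort(key=lambda t: abs(t[0] - i))
            neighbors = [
                StrandNeighbor(study_dosages[si], ref_dosage_mat[ri], o)
                for si, ri, o in pool[:window]
            ]
        decisions.append(
            classify_strand(
                m,
                study_dosages[i],
                ref.markers[j],
                float(ref_freqs[j]),
                ref_dosages=ref_dosage_mat[j],
                neighbors=neighbors,
                maf_ambiguity_bound=maf_ambiguity_bound,
                ld_r_min=ld_r_min,
                min_informative=min_informative,
            )
        )
    return decisions


def apply_strand_decisions(
    data: GenotypeDataset | HaplotypePanel,
    decisions: list[StrandDecision],
) -> GenotypeDataset | HaplotypePanel:
    """Apply keep/flip/discard decisions to genotypes or haplotypes.

    Flipped markers get complemented allele labels; the 0/1/dosage
    encoding is preserved (its meaning follows the relabeled alleles).
    Discarded markers are removed.  Decisions must cover exactly the
    markers present.
    """
    by_marker = {(d.marker.chrom, d.marker.pos, d.marker.label): d for d in decisions}
    markers = data.markers
    for m in markers:
        if (m.chrom, m.pos, m.label) not in by_marker:
            raise HarmonizeError(f"no strand decision for marker {m.label}")
    if len(by_marker) != len(markers):
        extra = len(by_marker) - len(markers)
        raise HarmonizeError(f"{extra} strand decisions for unknown markers")

    keep_idx: list[int] = []
    new_markers: list[MarkerRecord] = []
    for i, m in enumerate(markers):
        d = by_marker[(m.chrom, m.pos, m.label)]
        if d.action is StrandAction.DISCARD:
            continue
        if d.action is StrandAction.FLIP:
            a, b = complement((m.allele_a, m.allele_b))
            m = m.with_alleles(a, b)
        keep_idx.append(i)
        new_markers.append(m)

    if isinstance(data, GenotypeDataset):
        return GenotypeDataset(data.dataset_id, new_markers,
                               data.genotypes[keep_idx, :], data.samples)
    return HaplotypePanel(new_markers, data.haplotypes[keep_idx, :],
                          list(data.sample_ids))
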