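"""Chromosome partitioning for parallel imputation, and result stitching.

Two segmentation schemes are supported:

* **SNPlets** — fixed blocks of consecutive markers (default 30,000)
  with a fixed marker-count buffer (default 700) at each end, the
  scheme used for BEAGLE-style imputation of large datasets.
* **Genomic windows** — fixed base-pair windows (default 6 Mb) starting
  at the first imputation target, with base-pair buffers (default
  250 kb), the IMPUTE2-style scheme.  Windows overlapping the
  centromere, terminal remnants, and windows without any study-typed
  (type-2) marker are merged into the segment immediately upstream.

After per-segment imputation, :func:`stitch_segments` removes the
buffer regions so each imputed marker has results from exactly one
segment, and records which segment each marker came from.

Cores are half-open intervals internally — ``[start, end)`` in marker
indices (SNPlet) or base pairs (genomic) — which makes the
disjoint-cover invariant directly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import GenotypeProbabilityRow, MarkerRecord, marker_sort_key


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    """One core interval plus its buffered extent (all half-open)."""

    core_start: int
    core_end: int
    buffer_start: int
    buffer_end: int

    def __post_init__(self) -> None:
        if not (self.buffer_start <= self.core_start < self.core_end <= self.buffer_end):
            raise SegmentationError(
                f"inconsistent segment bounds {self.buffer_start} <= "
                f"{self.core_start} < {self.core_end} <= {self.buffer_end}"
            )


@dataclass
class SegmentPlan:
    """Ordered cores with buffers covering one chromosome's targets."""

    scheme: str  # "snplet" (marker indices) or "genomic_window" (base pairs)
    chrom: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        if self.scheme not in ("snplet", "genomic_window"):
            raise SegmentationError(f"unknown scheme {self.scheme!r}")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.core_start != a.core_end:
                raise SegmentationError(
                    f"cores not contiguous: [{a.core_start},{a.core_end}) then "
                    f"[{b.core_start},{b.core_end})"
                )

    def owner(self, marker_index: int, marker: MarkerRecord) -> int | None:
        """Index of the segment whose core owns a marker, or None."""
        coord = marker_index if self.scheme == "snplet" else marker.pos
        for k, seg in enumerate(self.segments):
            if seg.core_start <= coord < seg.core_end:
                return k
        return None


def _check_sorted(markers: Sequence[MarkerRecord]) -> None:
    keys = [marker_sort_key(m)[:2] for m in markers]
    if any(b <= a for a, b in zip(keys, keys[1:])):
        raise SegmentationError("markers must be sorted by (chrom, pos)")
    if len({m.chrom for m in markers}) > 1:
        raise SegmentationError("segmentation plans cover a single chromosome")


def plan_snplets(
    markers: Sequence[MarkerRecord],
    core_size: int = 30_000,
    buffer_size: int = 700,
) -> SegmentPlan:
    """Partition markers into fixed-size blocks with marker-count buffers.

    Every core holds exactly ``core_size`` markers except the last;
    buffers of ``buffer_size`` markers are truncated at chromosome ends.
    Intervals are in marker indices, half-open.
    """
    _check_sorted(markers)
    n = len(markers)
    chrom = markers[0].chrom if markers else "NA"
    segments = []
    for start in range(0, n, core_size):
        end = min(start + core_size, n)
        segments.append(
            Segment(
                core_start=start,
                core_end=end,
                buffer_start=max(0, start - buffer_size),
                buffer_end=min(n, end + buffer_size),
            )
        )
    return SegmentPlan("snplet", chrom, segments)


def plan_genomic_windows(
    markers: Sequence[MarkerRecord],
    chrom_length: int | None = None,
    centromere: tuple[int, int] | None = None,
    window: int = 6_000_000,
    buffer: int = 250_000,
) -> SegmentPlan:
    """Partition a chromosome into base-pair windows with bp buffers.

    Windows of ``window`` bp begin at the first imputation target.  Any
    window overlapping the centromere interval, any terminal remnant
    shorter than a full window, and any window without a study-typed
    (type-2) marker is merged into the segment immediately upstream (a
    violating first window merges downstream instead).  Buffers of
    ``buffer`` bp flank each core, truncated at chromosome ends.
    """
    _check_sorted(markers)
    if not markers:
        return SegmentPlan("genomic_window", "NA", [])
    chrom = markers[0].chrom
    first = markers[0].pos
    last = markers[-1].pos
    if chrom_length is None:
        chrom_length = last
    if centromere is not None and not (
        1 <= centromere[0] <= centromere[1] <= chrom_length
    ):
        raise SegmentationError(f"centromere {centromere} outside chromosome")

    # full windows from the first target; half-open [start, end)
    bounds: list[tuple[int, int]] = []
    start = first
    while start <= last:
        bounds.append((start, start + window))
        start += window
    # terminal remnant: a final window not fully covering `window` bp of
    # span is merged upstream (when an upstream window exists)
    if len(bounds) > 1 and bounds[-1][0] + window > last + 1:
        prev = bounds[-2]
        bounds[-2] = (prev[0], bounds[-1][1])
        bounds.pop()

    def overlaps_centromere(b: tuple[int, int]) -> bool:
        if centromere is None:
            return False
        lo, hi = centromere
        return b[0] <= hi and lo < b[1]

    merged: list[tuple[int, int]] = []
    for b in bounds:
        if merged and overlaps_centromere(b):
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)

    # each window must contain at least one type-2 (study-genotyped)
    # marker; windows with type codes absent are treated as typed
    def has_basis(b: tuple[int, int]) -> bool:
        return any(
            b[0] <= m.pos < b[1]
            and (m.type_code is None or m.type_code == 2)
            for m in markers
        )

    final: list[tuple[int, int]] = []
    for b in merged:
        if final and not has_basis(b):
            final[-1] = (final[-1][0], b[1])
        else:
            final.append(b)
    # a first window with no basis markers merges downstream
    while len(final) > 1 and not has_basis(final[0]):
        final[0] = (final[0][0], final[1][1])
        del final[1]

    end_cap = max(chrom_length, last) + 1
    segments = [
        Segment(
            core_start=s,
            core_end=min(e, end_cap) if min(e, end_cap) > s else e,
            buffer_start=max(1, s - buffer),
            buffer_end=min(end_cap, min(e, end_cap) + buffer),
        )
        for s, e in final
    ]
    return SegmentPlan("genomic_window", chrom, segments)


def segment_marker_indices(
    plan: SegmentPlan,
    markers: Sequence[MarkerRecord],
    segment_index: int,
    include_buffer: bool = True,
) -> list[int]:
    """Marker indices falling in a segment (buffered extent by default)."""
    seg = plan.segments[segment_index]
    lo = seg.buffer_start if include_buffer else seg.core_start
    hi = seg.buffer_end if include_buffer else seg.core_end
    if plan.scheme == "snplet":
        return list(range(lo, min(hi, len(markers))))
    return [i for i, m in enumerate(markers) if lo <= m.pos < hi]


def stitch_segments(
    per_segment_rows: Sequence[Iterable[tuple[int, GenotypeProbabilityRow]]],
    plan: SegmentPlan,
) -> list[tuple[GenotypeProbabilityRow, int]]:
    """Concatenate per-segment outputs, dropping buffer-region rows.

    ``per_segment_rows[k]`` yields ``(marker_index, row)`` pairs for
    segment ``k``, marker_index being the marker's index in the full
    target list (used for SNPlet ownership).  Rows whose marker falls
    outside segment ``k``'s core are buffer copies and are discarded,
    so each marker ends up with results from exactly one segment.

    Returns ``(row, originating_segment)`` pairs sorted by position.
    Raises on a marker owned by two cores; warns (via the returned gap
    list being checked by callers) is not done here — a core marker
    missing from its segment's output raises ``SegmentationError``.
    """
    if len(per_segment_rows) != len(plan.segments):
        raise SegmentationError(
            f"{len(per_segment_rows)} outputs for {len(plan.segments)} segments"
        )
    out: dict[tuple[str, int, str], tuple[GenotypeProbabilityRow, int]] = {}
    for k, rows in enumerate(per_segment_rows):
        seg = plan.segments[k]
        for marker_index, row in rows:
            coord = marker_index if plan.scheme == "snplet" else row.marker.pos
            if not (seg.core_start <= coord < seg.core_end):
                continue  # buffer copy
            key = (row.marker.chrom, row.marker.pos, row.marker.label)
            if key in out:
                raise SegmentationError(
                    f"marker {row.marker.label} owned by segments "
                    f"{out[key][1]} and {k}: cores overlap"
                )
            out[key] = (row, k)
    stitched = sorted(out.values(), key=lambda t: marker_sort_key(t[0].marker))
    return stitched


def plan_to_table(plan: SegmentPlan) -> list[dict]:
    """Plan as records for TSV emission (inclusive emitted intervals)."""
    rows = []
    for k, seg in enumerate(plan.segments):
        rows.append(
            {
                "segment": k,
                "chrom": plan.chrom,
                "scheme": plan.scheme,
                "core_start": seg.core_start,
                "core_end": seg.core_end - 1,
                "buffer_start": seg.buffer_start,
                "buffer_end": seg.buffer_end - 1,
            }
        )
    return rows
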