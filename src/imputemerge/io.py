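"""Readers and writers for the whitespace-delimited genotype formats.

Formats covered (all plain text, whitespace-delimited, no quoting):

* Oxford GEN probability files — five leading columns then three
  probability columns per sample.  Two dialects exist in the wild for
  the first column: stock IMPUTE2 output puts a secondary snp_id there
  (``impute2_5col``), while some merge tooling puts the chromosome
  (``chrom_first``).  An explicit ``dialect`` flag selects between them,
  default ``impute2_5col``.
* IMPUTE2 info-metric files — ten columns with a header line.
* SHAPEIT haps files — five marker columns then one 0/1 column per
  haplotype.
* Oxford sample files — the two-line header ``ID_1 ID_2 missing`` /
  ``0 0 0``.
* PLINK text pedigrees (.ped/.map).

Every reader/writer pair round-trips field-for-field; probabilities are
never renormalized on I/O.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Sequence

import numpy as np

from .model import (
    INFO_COLUMNS,
    GenotypeProbabilityRow,
    HaplotypePanel,
    InfoMetricRow,
    MarkerRecord,
    SampleInfo,
    check_roster,
)

GEN_DIALECTS = ("impute2_5col", "chrom_first")


class FormatError(ValueError):
    """Malformed file content; the message names the offending line."""


def _fmt(value: float, decimals: int) -> str:
    """Format a metric/probability; the -1 sentinel prints without decimals."""
    if value == -1:
        return "-1"
    return f"{value:.{decimals}f}"


# ---------------------------------------------------------------------------
# GEN probability files
# ---------------------------------------------------------------------------

def read_gen(
    path: str | os.PathLike,
    dialect: str = "impute2_5col",
    chrom: str = "0",
) -> tuple[list[GenotypeProbabilityRow], list[MarkerRecord]]:
    """Read a GEN file into probability rows plus the marker list.

    Rows must have 5 + 3*N fields.  With dialect ``impute2_5col`` the
    columns are ``snp_id rs_id pos alleleA alleleB``; the chromosome is
    not in the file and is taken from ``chrom``.  With ``chrom_first``
    the first column is the chromosome itself.
    """
    if dialect not in GEN_DIALECTS:
        raise ValueError(f"unknown GEN dialect {dialect!r}")
    rows: list[GenotypeProbabilityRow] = []
    markers: list[MarkerRecord] = []
    n_fields = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if (len(fields) - 5) % 3 or len(fields) < 5:
                raise FormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, "
                    "expected 5 + 3*N"
                )
            if n_fields is None:
                n_fields = len(fields)
            elif len(fields) != n_fields:
                raise FormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, "
                    f"previous rows had {n_fields}"
                )
            if dialect == "chrom_first":
                marker_chrom, label = fields[0], fields[1]
            else:
                marker_chrom, label = chrom, fields[1]
            marker = MarkerRecord(
                chrom=marker_chrom,
                pos=int(fields[2]),
                label=label,
                allele_a=fields[3],
                allele_b=fields[4],
            )
            probs = np.array([float(x) for x in fields[5:]], dtype=float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise FormatError(
                    f"{path}: line {lineno}: probability outside [0,1]"
                )
            rows.append(GenotypeProbabilityRow(marker, probs.reshape(-1, 3)))
            markers.append(marker)
    return rows, markers


def write_gen(
    path: str | os.PathLike,
    rows: Iterable[GenotypeProbabilityRow],
    dialect: str = "impute2_5col",
    snp_id: str = "---",
    decimals: int = 3,
) -> None:
    """Write probability rows as a GEN file.

    With ``impute2_5col`` the first column is ``snp_id`` (conventionally
    ``---``); with ``chrom_first`` it is the marker's chromosome.
    """
    if dialect not in GEN_DIALECTS:
        raise ValueError(f"unknown GEN dialect {dialect!r}")
    n_samples = None
    with open(path, "w") as fh:
        for row in rows:
            if n_samples is None:
                n_samples = row.n_samples
            elif row.n_samples != n_samples:
                raise FormatError(
                    f"{path}: row {row.marker.label} has {row.n_samples} "
                    f"samples, previous rows had {n_samples}"
                )
            m = row.marker
            first = m.chrom if dialect == "chrom_first" else snp_id
            lead = [first, m.label, str(m.pos), m.allele_a, m.allele_b]
            body = [_fmt(p, decimals) for p in row.probs.ravel()]
            fh.write(" ".join(lead + body) + "\n")


# ---------------------------------------------------------------------------
# Info-metric files
# ---------------------------------------------------------------------------

def read_info(path: str | os.PathLike) -> list[InfoMetricRow]:
    """Read a ten-column info-metric file (header line required)."""
    rows: list[InfoMetricRow] = []
    with open(path) as fh:
        header = fh.readline().split()
        if tuple(header) != INFO_COLUMNS:
            raise FormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(INFO_COLUMNS):
                raise FormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, "
                    f"expected {len(INFO_COLUMNS)}"
                )
            rows.append(
                InfoMetricRow(
                    snp_id=fields[0],
                    rs_id=fields[1],
                    position=int(fields[2]),
                    exp_freq_a1=float(fields[3]),
                    info=float(fields[4]),
                    certainty=float(fields[5]),
                    type_code=int(fields[6]),
                    info_type0=float(fields[7]),
                    concord_type0=float(fields[8]),
                    r2_type0=float(fields[9]),
                )
            )
    return rows


def write_info(
    path: str | os.PathLike,
    rows: Iterable[InfoMetricRow],
    decimals: int = 3,
) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(INFO_COLUMNS) + "\n")
        for r in rows:
            fields = [
                r.snp_id,
                r.rs_id,
                str(r.position),
                _fmt(r.exp_freq_a1, decimals),
                _fmt(r.info, decimals),
                _fmt(r.certainty, decimals),
                str(r.type_code),
                _fmt(r.info_type0, decimals),
                _fmt(r.concord_type0, decimals),
                _fmt(r.r2_type0, decimals),
            ]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Haps / sample files
# ---------------------------------------------------------------------------

def read_haps(
    path: str | os.PathLike,
    sample_ids: Sequence[str] | None = None,
) -> HaplotypePanel:
    """Read a SHAPEIT-style haps file into a phased panel."""
    markers: list[MarkerRecord] = []
    columns: list[np.ndarray] = []
    n_haps = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 5:
                raise FormatError(f"{path}: line {lineno}: fewer than 5 fields")
            markers.append(
                MarkerRecord(
                    chrom=fields[0],
                    label=fields[1],
                    pos=int(fields[2]),
                    allele_a=fields[3],
                    allele_b=fields[4],
                )
            )
            alleles = fields[5:]
            if n_haps is None:
                n_haps = len(alleles)
            elif len(alleles) != n_haps:
                raise FormatError(
                    f"{path}: line {lineno}: {len(alleles)} haplotype "
                    f"columns, previous rows had {n_haps}"
                )
            if any(a not in ("0", "1") for a in alleles):
                raise FormatError(f"{path}: line {lineno}: non-binary allele")
            columns.append(np.array([int(a) for a in alleles], dtype=np.int8))
    haps = (
        np.vstack(columns) if columns else np.zeros((0, n_haps or 0), dtype=np.int8)
    )
    return HaplotypePanel(markers, haps, list(sample_ids) if sample_ids else [])


def write_haps(path: str | os.PathLike, panel: HaplotypePanel) -> None:
    with open(path, "w") as fh:
        for i, m in enumerate(panel.markers):
            lead = [m.chrom, m.label, str(m.pos), m.allele_a, m.allele_b]
            body = [str(int(a)) for a in panel.haplotypes[i]]
            fh.write(" ".join(lead + body) + "\n")


def read_sample(path: str | os.PathLike) -> list[SampleInfo]:
    """Read a two-header-line Oxford sample file.

    ``ID_1`` carries the dataset id, ``ID_2`` the sample id and
    ``missing`` the sample missingness (1 - call rate).
    """
    samples: list[SampleInfo] = []
    with open(path) as fh:
        header = fh.readline().split()
        type_line = fh.readline().split()
        if header[:3] != ["ID_1", "ID_2", "missing"] or type_line[:3] != ["0", "0", "0"]:
            raise FormatError(f"{path}: missing the two-line Oxford header")
        for lineno, line in enumerate(fh, start=3):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 fields")
            missing = fields[2]
            call_rate = None if missing == "NA" else 1.0 - float(missing)
            samples.append(
                SampleInfo(sample_id=fields[1], dataset_id=fields[0], call_rate=call_rate)
            )
    check_roster(samples)
    return samples


def write_sample(path: str | os.PathLike, samples: Sequence[SampleInfo]) -> None:
    check_roster(samples)
    with open(path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in samples:
            missing = "NA" if s.call_rate is None else f"{1.0 - s.call_rate:.4f}"
            fh.write(f"{s.dataset_id} {s.sample_id} {missing}\n")


# ---------------------------------------------------------------------------
# PLINK text pedigrees
# ---------------------------------------------------------------------------

def read_plink_text(
    prefix: str | os.PathLike,
) -> tuple[list[MarkerRecord], np.ndarray, list[SampleInfo]]:
    """Read PLINK text files ``prefix.ped`` + ``prefix.map``.

    Returns (markers, genotype matrix, samples).  The genotype matrix
    has shape (n_markers, n_samples) counting copies of each marker's
    ``allele_b``; missing genotypes ("0 0") are -1.  Allele order per
    marker is fixed by first observation in the .ped file.

    Markers monomorphic in the file expose only one allele, so their
    allele pair cannot be reconstructed; they are dropped with a
    warning (they carry no information and would fail any MAF filter).
    """
    prefix = os.fspath(prefix)
    raw_map: list[tuple[str, str, int]] = []
    with open(prefix + ".map") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise FormatError(f"{prefix}.map: line {lineno}: expected 4 fields")
            raw_map.append((fields[0], fields[1], int(fields[3])))

    n_markers = len(raw_map)
    samples: list[SampleInfo] = []
    allele_calls: list[list[tuple[str, str]]] = []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{prefix}.ped: line {lineno}: {len(fields)} fields, "
                    f"expected {6 + 2 * n_markers}"
                )
            samples.append(SampleInfo(sample_id=fields[1], dataset_id=fields[0]))
            calls = [
                (fields[6 + 2 * i], fields[7 + 2 * i]) for i in range(n_markers)
            ]
            allele_calls.append(calls)
    check_roster(samples)

    markers: list[MarkerRecord] = []
    rows: list[np.ndarray] = []
    for i, (chrom, label, pos) in enumerate(raw_map):
        observed: list[str] = []
        for calls in allele_calls:
            for a in calls[i]:
                if a != "0" and a not in observed:
                    observed.append(a)
        if len(observed) < 2:
            warnings.warn(
                f"{prefix}: marker {label} is monomorphic in this file; "
                "allele pair unrecoverable, marker dropped",
                stacklevel=2,
            )
            continue
        if len(observed) > 2:
            raise FormatError(f"{prefix}: marker {label} is not biallelic")
        allele_a, allele_b = observed
        markers.append(
            MarkerRecord(chrom=chrom, label=label, pos=pos,
                         allele_a=allele_a, allele_b=allele_b)
        )
        row = np.full(len(samples), -1, dtype=np.int8)
        for j, calls in enumerate(allele_calls):
            a1, a2 = calls[i]
            if a1 == "0" or a2 == "0":
                continue
            row[j] = (a1 == allele_b) + (a2 == allele_b)
        rows.append(row)
    genotypes = (
        np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return markers, genotypes, samples


def write_plink_text(
    prefix: str | os.PathLike,
    markers: Sequence[MarkerRecord],
    genotypes: np.ndarray,
    samples: Sequence[SampleInfo],
) -> None:
    """Write PLINK text files; dosages {0,1,2} map back to allele pairs."""
    prefix = os.fspath(prefix)
    genotypes = np.asarray(genotypes)
    if genotypes.shape != (len(markers), len(samples)):
        raise FormatError(
            f"{prefix}: genotype matrix {genotypes.shape} inconsistent with "
            f"{len(markers)} markers x {len(samples)} samples"
        )
    with open(prefix + ".map", "w") as fh:
        for m in markers:
            fh.write(f"{m.chrom} {m.label} 0 {m.pos}\n")
    pair = {
        -1: lambda m: ("0", "0"),
        0: lambda m: (m.allele_a, m.allele_a),
        1: lambda m: (m.allele_a, m.allele_b),
        2: lambda m: (m.allele_b, m.allele_b),
    }
    with open(prefix + ".ped", "w") as fh:
        for j, s in enumerate(samples):
            fields = [s.dataset_id, s.sample_id, "0", "0", "0", "-9"]
            for i, m in enumerate(markers):
                fields.extend(pair[int(genotypes[i, j])](m))
            fh.write(" ".join(fields) + "\n")
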