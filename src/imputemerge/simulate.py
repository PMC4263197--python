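"""Seeded synthetic fixtures emulating a multi-platform genotyping study.

The generator builds, from one seed:

* a **phased reference panel** with block-LD structure — per-marker
  ancestral allele frequencies drawn uniformly, subpopulation
  frequencies drawn around them with a Balding–Nichols divergence
  parameter F, founder haplotypes per subpopulation, and panel
  haplotypes produced by mosaic copying between founders with a
  per-marker switch rate (switch rate 0 copies one founder end to
  end);
* **study individuals** as pairs of mosaic copies of the panel's
  haplotypes;
* several **platforms**, each observing an overlapping subset of the
  markers, with injected complement strand flips on a recorded subset
  of non-palindromic markers, positions shifted to an "old build" with
  a matching coordinate-conversion table (including some unmapped
  markers), duplicate samples shared between platforms, and random
  missingness;
* a **truth store** recording every injected artifact, so each
  pipeline stage's recovery can be verified.

Identical configuration and seed give identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .harmonize import CoordinateMapEntry, CoordinateMap, complement
from .model import (
    GenotypeDataset,
    HaplotypePanel,
    MarkerRecord,
    SampleInfo,
)

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults describe a desk-scale version of a multi-site study:
    a few hundred reference haplotypes with block LD, three platforms
    typing overlapping halves of the marker set, a 2% strand-flip
    injection rate confined to non-palindromic markers, a constant
    build offset with a small unmapped fraction, a handful of
    duplicate samples, and 2% missingness.
    """

    n_ref_haplotypes: int = 200
    n_study_samples: int = 60  # per platform
    n_markers: int = 600
    chrom: str = "20"
    chrom_length: int = 6_000_000
    switch_rate: float = 0.02  # mosaic switch probability per marker
    error_rate: float = 0.001  # allele copy error
    n_platforms: int = 3
    platform_fraction: float = 0.5  # fraction of markers each platform types
    platform_overlap: float = 0.6  # fraction of a platform's markers shared by all
    flip_rate: float = 0.02  # strand-flip injections (non-palindromic only)
    palindromic_fraction: float = 0.1
    build_offset: int = 1000  # old-build positions = new - offset
    unmapped_fraction: float = 0.02
    n_duplicates: int = 5  # samples genotyped on two platforms
    missing_rate: float = 0.02
    n_subpops: int = 2
    divergence: float = 0.05  # Balding–Nichols F
    n_founders: int = 8  # per subpopulation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("switch_rate", "error_rate", "platform_fraction",
                     "platform_overlap", "flip_rate", "palindromic_fraction",
                     "unmapped_fraction", "missing_rate", "divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class TruthStore:
    """Everything injected, for downstream verification."""

    study_haplotypes: HaplotypePanel  # all study individuals, true phase
    platform_markers: dict[str, list[int]]  # panel marker indices per platform
    flipped: dict[str, list[str]]  # per platform: labels emitted strand-flipped
    unmapped: list[str]  # labels absent from the new build
    duplicates: list[tuple[str, str, str]]  # (sample_id, platform_a, platform_b)
    build_offset: int
    sample_platforms: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_unique_samples(self) -> int:
        return len(self.sample_platforms)


def _mosaic(
    rng: np.random.Generator,
    templates: np.ndarray,  # (n_markers, n_templates)
    n_out: int,
    switch_rate: float,
    error_rate: float,
) -> np.ndarray:
    n_markers, n_templates = templates.shape
    out = np.empty((n_markers, n_out), dtype=np.int8)
    for h in range(n_out):
        src = rng.integers(n_templates)
        for i in range(n_markers):
            if i and rng.random() < switch_rate:
                src = rng.integers(n_templates)
            out[i, h] = templates[i, src]
    if error_rate > 0:
        flip = rng.random(out.shape) < error_rate
        out[flip] = 1 - out[flip]
    return out


def simulate_reference(config: SimulationConfig) -> HaplotypePanel:
    """Phased reference panel with block LD and population structure."""
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    positions = np.sort(
        rng.choice(
            np.arange(config.build_offset + 1, config.chrom_length),
            size=m, replace=False,
        )
    )
    n_palindromic = int(round(config.palindromic_fraction * m))
    pal_idx = set(rng.choice(m, size=n_palindromic, replace=False).tolist())
    markers = []
    for i in range(m):
        pool = _PALINDROMIC_PAIRS if i in pal_idx else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        markers.append(
            MarkerRecord(chrom=config.chrom, pos=int(positions[i]),
                         label=f"rs{1000 + i}", allele_a=a, allele_b=b)
        )

    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = config.divergence
    haps_per_pop = config.n_ref_haplotypes // config.n_subpops
    blocks = []
    for _ in range(config.n_subpops):
        if f > 0:
            shape1 = p_anc * (1 - f) / f
            shape2 = (1 - p_anc) * (1 - f) / f
            p_sub = rng.beta(shape1, shape2)
        else:
            p_sub = p_anc
        founders = (rng.random((m, config.n_founders)) < p_sub[:, None]).astype(np.int8)
        blocks.append(
            _mosaic(rng, founders, haps_per_pop,
                    config.switch_rate, config.error_rate)
        )
    haps = np.hstack(blocks)
    ids = [f"ref{i}" for i in range(haps.shape[1] // 2)]
    return HaplotypePanel(markers, haps, ids)


def simulate_study(
    config: SimulationConfig,
    panel: HaplotypePanel,
) -> tuple[list[GenotypeDataset], list[CoordinateMapEntry], TruthStore]:
    """Per-platform genotype datasets plus coordinate map and truth store.

    Every platform's emitted markers carry old-build positions (shifted
    down by ``build_offset``) and, on the injected subset, strand-
    complemented allele labels.  A coordinate table mapping old → new
    positions accompanies them, with ``unmapped_fraction`` of markers
    marked unmapped.  ``n_duplicates`` samples appear on two platforms
    under the same id with independently drawn missingness.
    """
    rng = np.random.default_rng(config.seed + 1)
    m = panel.n_markers

    # --- study individuals: mosaic pairs of panel haplotypes ----------
    n_unique = config.n_platforms * config.n_study_samples - config.n_duplicates
    if n_unique < config.n_study_samples:
        raise ValueError("more duplicates than one platform's sample count")
    study_haps = _mosaic(rng, panel.haplotypes, 2 * n_unique,
                         config.switch_rate, 0.0)
    sample_ids = [f"ind{i:04d}" for i in range(n_unique)]
    truth_panel = HaplotypePanel(list(panel.markers), study_haps, sample_ids)

    # --- platform sample assignment -----------------------------------
    per_platform_samples: list[list[int]] = []
    cursor = 0
    for p in range(config.n_platforms):
        fresh = config.n_study_samples - (config.n_duplicates if p == 1 else 0)
        per_platform_samples.append(list(range(cursor, cursor + fresh)))
        cursor += fresh
    duplicates: list[tuple[str, str, str]] = []
    if config.n_duplicates and config.n_platforms >= 2:
        # the first few samples of platform 0 reappear on platform 1
        for d in range(config.n_duplicates):
            per_platform_samples[1].append(per_platform_samples[0][d])
            duplicates.append(
                (sample_ids[per_platform_samples[0][d]], "platform0", "platform1")
            )

    # --- platform marker subsets with a shared core --------------------
    platform_size = int(round(config.platform_fraction * m))
    core_size = int(round(config.platform_overlap * platform_size))
    core = sorted(rng.choice(m, size=core_size, replace=False).tolist())
    rest = [i for i in range(m) if i not in set(core)]
    platform_markers: dict[str, list[int]] = {}
    for p in range(config.n_platforms):
        extra = sorted(
            rng.choice(len(rest), size=platform_size - core_size,
                       replace=False).tolist()
        )
        platform_markers[f"platform{p}"] = sorted(core + [rest[i] for i in extra])

    # --- coordinate map and unmapped markers ---------------------------
    n_unmapped = int(round(config.unmapped_fraction * m))
    unmapped_idx = set(rng.choice(m, size=n_unmapped, replace=False).tolist())
    entries: list[CoordinateMapEntry] = []
    for i, marker in enumerate(panel.markers):
        old_pos = marker.pos - config.build_offset
        if i in unmapped_idx:
            entries.append(
                CoordinateMapEntry(marker.chrom, old_pos, marker.label,
                                   status="unmapped")
            )
        else:
            entries.append(
                CoordinateMapEntry(marker.chrom, old_pos, marker.label,
                                   marker.chrom, marker.pos, marker.label)
            )
    unmapped_labels = [panel.markers[i].label for i in sorted(unmapped_idx)]

    # --- emit per-platform datasets ------------------------------------
    dosage_all = truth_panel.dosages()  # (m, n_unique)
    datasets: list[GenotypeDataset] = []
    flipped: dict[str, list[str]] = {}
    sample_platforms: dict[str, list[str]] = {s: [] for s in sample_ids}
    for p in range(config.n_platforms):
        pid = f"platform{p}"
        midx = platform_markers[pid]
        cols = per_platform_samples[p]
        geno = dosage_all[np.ix_(midx, cols)].astype(np.int8)
        if config.missing_rate > 0:
            miss = rng.random(geno.shape) < config.missing_rate
            geno = np.where(miss, np.int8(-1), geno)
        flip_labels: list[str] = []
        emitted: list[MarkerRecord] = []
        for local, i in enumerate(midx):
            marker = panel.markers[i]
            a, b = marker.allele_a, marker.allele_b
            if not marker.is_palindromic and rng.random() < config.flip_rate:
                a, b = complement((a, b))
                flip_labels.append(marker.label)
            emitted.append(
                MarkerRecord(chrom=marker.chrom,
                             pos=marker.pos - config.build_offset,
                             label=marker.label, allele_a=a, allele_b=b)
            )
        samples = []
        for j, c in enumerate(cols):
            call_rate = float((geno[:, j] != -1).mean()) if len(midx) else 0.0
            samples.append(SampleInfo(sample_id=sample_ids[c], dataset_id=pid,
                                      call_rate=call_rate))
            sample_platforms[sample_ids[c]].append(pid)
        flipped[pid] = flip_labels
        datasets.append(GenotypeDataset(pid, emitted, geno, samples))

    truth = TruthStore(
        study_haplotypes=truth_panel,
        platform_markers=platform_markers,
        flipped=flipped,
        unmapped=unmapped_labels,
        duplicates=duplicates,
        build_offset=config.build_offset,
        sample_platforms=sample_platforms,
    )
    return datasets, entries, truth


def coordinate_map_for(entries: list[CoordinateMapEntry]) -> CoordinateMap:
    return CoordinateMap(entries)
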