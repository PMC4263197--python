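import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")

from imputemerge.model import (
    GenotypeProbabilityRow,
    HaplotypePanel,
    InfoMetricRow,
    MarkerRecord,
    SampleInfo,
)

NONPAL = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G"),
          ("G", "A"), ("C", "A"), ("C", "T"), ("G", "T")]


def make_markers(n, chrom="1", start=100, spacing=100, rng=None, labels=None):
    """Sorted non-palindromic markers with deterministic allele pairs."""
    markers = []
    for i in range(n):
        a, b = NONPAL[i % len(NONPAL)] if rng is None else NONPAL[rng.integers(len(NONPAL))]
        markers.append(
            MarkerRecord(
                chrom=chrom,
                pos=start + i * spacing,
                label=labels[i] if labels else f"rs{i + 1}",
                allele_a=a,
                allele_b=b,
            )
        )
    return markers


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rows(rng):
    """Three markers x two samples of probability rows."""
    markers = make_markers(3)
    rows = []
    for m in markers:
        p = rng.dirichlet([1, 1, 1], size=2).round(3)
        p[p.sum(axis=1) > 1.0] /= p[p.sum(axis=1) > 1.0].sum(axis=1, keepdims=True)
        rows.append(GenotypeProbabilityRow(m, p))
    return rows


def random_info_row(rng, pos, label):
    def metric():
        return -1.0 if rng.random() < 0.2 else float(np.round(rng.random(), 3))

    return InfoMetricRow(
        snp_id="---",
        rs_id=label,
        position=pos,
        exp_freq_a1=metric(),
        info=metric(),
        certainty=metric(),
        type_code=int(rng.integers(0, 4)),
        info_type0=metric(),
        concord_type0=metric(),
        r2_type0=metric(),
    )


def make_panel(markers, rng, n_haplotypes=20):
    haps = rng.integers(0, 2, size=(len(markers), n_haplotypes)).astype(np.int8)
    return HaplotypePanel(markers, haps)


def make_roster(n, dataset_id="ds1", rng=None):
    return [
        SampleInfo(
            sample_id=f"s{i}",
            dataset_id=dataset_id,
            call_rate=None if rng is None else float(np.round(rng.uniform(0.9, 1.0), 4)),
        )
        for i in range(n)
    ]
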