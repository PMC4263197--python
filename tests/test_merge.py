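"""Cross-matching, labeling, alignment, metric-averaging and merge rules."""

import numpy as np
import pytest

from imputemerge.merge import (
    ImputedDataset,
    MergeError,
    align_alleles,
    gate_datasets,
    intersect_markers,
    merge,
    merge_info_rows,
    plan_merge,
    resolve_duplicate_samples,
    resolve_labels,
)
from imputemerge.model import (
    InfoMetricRow,
    MarkerKey,
    MarkerRecord,
    SampleInfo,
)

from conftest import make_markers


def _info(label, pos, info=0.9, exp_freq=0.3, type_code=0, **kw):
    return InfoMetricRow("---", label, pos, exp_freq, info, 0.9, type_code, **kw)


def _dataset(dataset_id, markers, rng, n_samples=120, info_values=None,
             concordance=0.95, dense=True, sample_ids=None, call_rates=None):
    probs = rng.dirichlet([1, 1, 1], size=(len(markers), n_samples))
    info = [
        _info(m.label, m.pos,
              info=0.9 if info_values is None else info_values[i])
        for i, m in enumerate(markers)
    ]
    samples = [
        SampleInfo(
            sample_ids[j] if sample_ids else f"{dataset_id}_s{j}",
            dataset_id,
            call_rates[j] if call_rates else 0.99,
        )
        for j in range(n_samples)
    ]
    return ImputedDataset(dataset_id, markers, probs, info, samples,
                          platform_dense=dense, masked_concordance=concordance)


class TestGateDatasets:
    def test_small_dataset_excluded(self, rng):
        ds = _dataset("chop_omni", make_markers(5), rng, n_samples=32)
        eligible, reasons = gate_datasets([ds])
        assert not eligible["chop_omni"]
        assert "32 samples" in reasons["chop_omni"][0]

    def test_boundary_dataset_included(self, rng):
        ds = _dataset("ok", make_markers(5), rng, n_samples=100, concordance=0.85)
        eligible, _ = gate_datasets([ds])
        assert eligible["ok"]

    @pytest.mark.parametrize(
        "kw,reason_part",
        [
            (dict(dense=False), "dense"),
            (dict(concordance=0.79), "concordance"),
        ],
    )
    def test_exclusion_reasons(self, rng, kw, reason_part):
        ds = _dataset("d", make_markers(5), rng, **kw)
        eligible, reasons = gate_datasets([ds])
        assert not eligible["d"]
        assert any(reason_part in r for r in reasons["d"])

    def test_all_failing_merge_refused(self, rng):
        ds = _dataset("d", make_markers(5), rng, n_samples=10)
        with pytest.raises(MergeError, match="no dataset"):
            plan_merge([ds])


class TestIntersectMarkers:
    def test_info_exactly_at_threshold_excluded(self, rng):
        markers = make_markers(3)
        d1 = _dataset("a", markers, rng, info_values=[0.9, 0.70, 0.9])
        d2 = _dataset("b", markers, rng, info_values=[0.9, 0.9, 0.69])
        keys = intersect_markers([d1, d2])
        assert keys == {markers[0].key}

    def test_single_dataset_all_high_info(self, rng):
        markers = make_markers(4)
        d = _dataset("a", markers, rng, info_values=[0.9, 0.5, 0.71, 0.7])
        assert intersect_markers([d]) == {markers[0].key, markers[2].key}

    def test_matches_brute_force_oracle(self, rng):
        markers = make_markers(50)
        infos = [rng.uniform(0.4, 1.0, size=50) for _ in range(3)]
        subsets = [sorted(rng.choice(50, size=35, replace=False)) for _ in range(3)]
        datasets = [
            _dataset(f"d{k}", [markers[i] for i in subsets[k]], rng,
                     info_values=[infos[k][i] for i in subsets[k]])
            for k in range(3)
        ]
        keys = intersect_markers(datasets)
        oracle = {
            markers[i].key
            for i in range(50)
            if all(i in subsets[k] and infos[k][i] > 0.7 for k in range(3))
        }
        assert keys == oracle

    def test_cross_match_by_position_not_label(self, rng):
        m1 = [MarkerRecord("1", 100, "rs1", "A", "G")]
        m2 = [MarkerRecord("1", 100, "kgp99", "G", "A")]  # same key
        d1 = _dataset("a", m1, rng)
        d2 = _dataset("b", m2, rng)
        assert len(intersect_markers([d1, d2])) == 1


class TestResolveLabels:
    KEY = MarkerKey("1", 100, frozenset("AG"))
    KEY2 = MarkerKey("1", 200, frozenset("AG"))

    def test_plurality_wins(self):
        label_map, dropped = resolve_labels({self.KEY: ["rs5", "rs5", "kgp11"]})
        assert label_map[self.KEY] == "rs5" and not dropped

    def test_tie_larger_rs_number_wins(self):
        label_map, _ = resolve_labels({self.KEY: ["rs5", "rs7"]})
        assert label_map[self.KEY] == "rs7"
        label_map, _ = resolve_labels({self.KEY: ["rs10", "rs9"]})
        assert label_map[self.KEY] == "rs10"  # numeric, not lexicographic

    def test_tie_non_rs_lexicographically_larger(self):
        label_map, _ = resolve_labels({self.KEY: ["kgp2", "kgp11"]})
        assert label_map[self.KEY] == "kgp2"

    def test_rs_outranks_non_rs_on_tie(self):
        label_map, _ = resolve_labels({self.KEY: ["rs5", "kgp9"]})
        assert label_map[self.KEY] == "rs5"

    def test_label_at_two_positions_drops_both(self):
        label_map, dropped = resolve_labels(
            {self.KEY: ["rs9"], self.KEY2: ["rs9"]}
        )
        assert label_map == {}
        assert set(dropped) == {self.KEY, self.KEY2}

    def test_randomized_against_counting_oracle(self, rng):
        labels_pool = [f"rs{i}" for i in range(1, 8)]
        for _ in range(30):
            labels = [labels_pool[i] for i in rng.integers(0, 7, size=5)]
            label_map, _ = resolve_labels({self.KEY: labels})
            # oracle: max count, then max rs number
            from collections import Counter
            counts = Counter(labels)
            best = max(counts.items(),
                       key=lambda kv: (kv[1], int(kv[0][2:])))[0]
            assert label_map[self.KEY] == best


class TestAlignAlleles:
    def test_reversed_order_swaps_homozygote_probs(self, rng):
        anchor = MarkerRecord("1", 100, "rs1", "A", "G")
        other = MarkerRecord("1", 100, "rs1", "G", "A")
        probs = rng.dirichlet([1, 1, 1], size=4)
        aligned, rev = align_alleles(other, probs, anchor)
        assert rev
        np.testing.assert_array_equal(aligned, probs[:, ::-1])

    def test_identical_order_identity(self, rng):
        anchor = MarkerRecord("1", 100, "rs1", "A", "G")
        probs = rng.dirichlet([1, 1, 1], size=4)
        aligned, rev = align_alleles(anchor, probs, anchor)
        assert not rev
        np.testing.assert_array_equal(aligned, probs)

    def test_double_reversal_involution(self, rng):
        anchor = MarkerRecord("1", 100, "rs1", "A", "G")
        other = MarkerRecord("1", 100, "rs1", "G", "A")
        probs = rng.dirichlet([1, 1, 1], size=4)
        once, _ = align_alleles(other, probs, anchor)
        twice, _ = align_alleles(anchor, once, other)
        np.testing.assert_array_equal(twice, probs)

    def test_incompatible_alleles_rejected(self, rng):
        anchor = MarkerRecord("1", 100, "rs1", "A", "G")
        other = MarkerRecord("1", 100, "rs1", "A", "C")
        with pytest.raises(MergeError):
            align_alleles(other, np.zeros((2, 3)), anchor)


class TestMergeInfoRows:
    def test_worked_example_half_sentinel_third(self):
        """Metric values {0.5, -1, 0.3} average to 0.4 with the -1
        ignored under the equal-weight rule."""
        rows = [
            _info("rs1", 100, info=0.5),
            _info("rs1", 100, info=-1.0),
            _info("rs1", 100, info=0.3),
        ]
        merged = merge_info_rows(rows, [False] * 3, "rs1", 100)
        assert merged.info == pytest.approx(0.4)
        assert merged.snp_id == "---"

    def test_single_dataset_keeps_values(self):
        row = _info("rs1", 100, info=0.88, exp_freq=0.21, type_code=2)
        merged = merge_info_rows([row], [False], "rs1", 100)
        assert merged.info == pytest.approx(0.88)
        assert merged.exp_freq_a1 == pytest.approx(0.21)
        assert merged.type_code == 2 and merged.snp_id == "---"

    def test_type_is_numeric_minimum(self):
        rows = [_info("rs1", 100, type_code=t) for t in (2, 0, 3)]
        merged = merge_info_rows(rows, [False] * 3, "rs1", 100)
        assert merged.type_code == 0

    def test_all_sentinel_column_stays_sentinel(self):
        rows = [_info("rs1", 100, info=-1.0) for _ in range(3)]
        merged = merge_info_rows(rows, [False] * 3, "rs1", 100)
        assert merged.info == -1.0

    def test_reversed_freq_subtracted_from_one(self):
        rows = [_info("rs1", 100, exp_freq=0.2), _info("rs1", 100, exp_freq=0.9)]
        merged = merge_info_rows(rows, [False, True], "rs1", 100,
                                 minor_allele_orientation=False)
        # reversed 0.9 enters as 0.1 -> mean(0.2, 0.1)
        assert merged.exp_freq_a1 == pytest.approx(0.15)

    def test_minor_allele_orientation_folds_above_half(self):
        rows = [_info("rs1", 100, exp_freq=0.8), _info("rs1", 100, exp_freq=0.9)]
        merged = merge_info_rows(rows, [False, False], "rs1", 100)
        assert merged.exp_freq_a1 == pytest.approx(1 - 0.85)

    def test_random_vectors_vs_filter_then_mean_oracle(self, rng):
        for _ in range(25):
            values = [
                -1.0 if rng.random() < 0.3 else float(np.round(rng.random(), 3))
                for _ in range(4)
            ]
            rows = [_info("rs1", 100, info=v) for v in values]
            merged = merge_info_rows(rows, [False] * 4, "rs1", 100)
            kept = [v for v in values if v != -1.0]
            expected = float(np.mean(kept)) if kept else -1.0
            assert merged.info == pytest.approx(expected)


class TestResolveDuplicates:
    def _two(self, rng, rates):
        markers = make_markers(3)
        d1 = _dataset("a", markers, rng, n_samples=2,
                      sample_ids=["dup", "x"], call_rates=[rates[0], 0.9])
        d2 = _dataset("b", markers, rng, n_samples=2,
                      sample_ids=["dup", "y"], call_rates=[rates[1], 0.9])
        return d1, d2

    def test_higher_call_rate_wins(self, rng):
        d1, d2 = self._two(rng, (0.98, 0.99))
        winners = resolve_duplicate_samples([d1, d2])
        assert winners["dup"] == "b"

    def test_no_duplicates_identity(self, rng):
        markers = make_markers(3)
        d1 = _dataset("a", markers, rng, n_samples=2)
        winners = resolve_duplicate_samples([d1])
        assert all(v == "a" for v in winners.values())

    def test_exact_tie_first_dataset_wins_with_warning(self, rng):
        d1, d2 = self._two(rng, (0.99, 0.99))
        with pytest.warns(UserWarning, match="dup"):
            winners = resolve_duplicate_samples([d1, d2])
        assert winners["dup"] == "a"


class TestMerge:
    def test_self_merge_doubles_samples_keeps_metrics(self, rng):
        markers = make_markers(6)
        d1 = _dataset("a", markers, rng)
        d2 = _dataset("b", markers, rng)
        merged = merge([d1, d2])
        assert len(merged.samples) == d1.n_samples + d2.n_samples
        assert len(merged.markers) == 6
        for out, src in zip(merged.info, d1.info):
            assert out.info == pytest.approx(src.info)  # mean of equal values

    def test_overlap_count_matches_oracle(self, rng):
        markers = make_markers(40)
        idx1 = sorted(rng.choice(40, size=30, replace=False))
        idx2 = sorted(rng.choice(40, size=30, replace=False))
        inf1 = rng.uniform(0.5, 1.0, size=40)
        inf2 = rng.uniform(0.5, 1.0, size=40)
        d1 = _dataset("a", [markers[i] for i in idx1], rng,
                      info_values=[inf1[i] for i in idx1])
        d2 = _dataset("b", [markers[i] for i in idx2], rng,
                      info_values=[inf2[i] for i in idx2])
        merged = merge([d1, d2])
        oracle = sum(
            1
            for i in range(40)
            if i in idx1 and i in idx2 and inf1[i] > 0.7 and inf2[i] > 0.7
        )
        assert len(merged.markers) == oracle

    def test_anchor_reversed_dataset_merges_identically(self, rng):
        """Reversing the second dataset's allele order leaves the merged
        probabilities unchanged (reversal involution)."""
        markers = make_markers(5)
        d1 = _dataset("a", markers, rng)
        d2 = _dataset("b", markers, rng)
        merged_plain = merge([d1, d2])
        reversed_markers = [
            m.with_alleles(m.allele_b, m.allele_a) for m in markers
        ]
        d2_rev = ImputedDataset(
            "b", reversed_markers, d2.probs[:, :, ::-1], d2.info, d2.samples,
            masked_concordance=d2.masked_concordance,
        )
        merged_rev = merge([d1, d2_rev])
        np.testing.assert_allclose(merged_rev.probs, merged_plain.probs)
        assert [m.label for m in merged_rev.markers] == [
            m.label for m in merged_plain.markers
        ]

    def test_duplicate_sample_columns_dropped(self, rng):
        markers = make_markers(4)
        d1 = _dataset("a", markers, rng, n_samples=110,
                      sample_ids=[f"s{j}" for j in range(110)],
                      call_rates=[0.99] * 110)
        d2 = _dataset("b", markers, rng, n_samples=110,
                      sample_ids=[f"s{j}" for j in range(5)]
                      + [f"t{j}" for j in range(105)],
                      call_rates=[0.995] * 5 + [0.99] * 105)
        merged = merge([d1, d2])
        ids = [s.sample_id for s in merged.samples]
        assert len(ids) == len(set(ids)) == 215
        # the five duplicates came from b, the higher-call-rate copy
        from_b = {s.sample_id for s in merged.samples if s.dataset_id == "b"}
        assert {f"s{j}" for j in range(5)} <= from_b

    def test_merged_freq_reported_for_minor_allele(self, rng):
        markers = make_markers(8)
        d1 = _dataset("a", markers, rng)
        d2 = _dataset("b", markers, rng)
        for ds in (d1, d2):
            for row in ds.info:
                row.exp_freq_a1 = float(rng.uniform(0, 1))
        merged = merge([d1, d2])
        for row in merged.info:
            assert row.exp_freq_a1 <= 0.5

    def test_merged_marker_count_bounded_by_min_dataset(self, rng):
        markers = make_markers(30)
        d1 = _dataset("a", markers[:25], rng,
                      info_values=list(rng.uniform(0.5, 1.0, 25)))
        d2 = _dataset("b", markers[5:], rng,
                      info_values=list(rng.uniform(0.5, 1.0, 25)))
        merged = merge([d1, d2])
        bound = min(
            sum(r.info > 0.7 for r in d1.info),
            sum(r.info > 0.7 for r in d2.info),
        )
        assert len(merged.markers) <= bound
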