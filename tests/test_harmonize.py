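"""Coordinate conversion and strand-harmonization behavior."""

import itertools

import numpy as np
import pytest

from imputemerge.harmonize import (
    CoordinateMap,
    CoordinateMapEntry,
    HarmonizeError,
    StrandAction,
    StrandBasis,
    StrandNeighbor,
    apply_coordinate_map,
    apply_strand_decisions,
    classify_dataset_strand,
    classify_strand,
    complement,
    liftover_dataset,
    prefilter_markers,
    read_coordinate_map,
    write_coordinate_map,
)
from imputemerge.model import GenotypeDataset, MarkerRecord
from imputemerge.simulate import SimulationConfig, simulate_reference, simulate_study

from conftest import make_markers, make_roster


class TestComplement:
    # independent lookup oracle over all 12 ordered non-identical pairs
    ORACLE = {"A": "T", "T": "A", "C": "G", "G": "C"}

    @pytest.mark.parametrize(
        "pair", [p for p in itertools.permutations("ACGT", 2)]
    )
    def test_exhaustive_against_lookup(self, pair):
        assert complement(pair) == (self.ORACLE[pair[0]], self.ORACLE[pair[1]])

    def test_involution(self):
        for pair in itertools.permutations("ACGT", 2):
            assert complement(complement(pair)) == pair

    def test_palindromic_pair_keeps_unordered_set(self):
        assert set(complement(("A", "T"))) == {"A", "T"}

    def test_non_acgt_rejected(self):
        with pytest.raises(HarmonizeError):
            complement(("A", "N"))


class TestCoordinateMap:
    def test_unmapped_marker_dropped(self):
        markers = make_markers(2)
        cmap = CoordinateMap(
            [
                CoordinateMapEntry("1", 100, "rs1", "1", 1100, "rs1"),
                CoordinateMapEntry("1", 200, "rs2", status="unmapped"),
            ]
        )
        mapped, order, dropped = apply_coordinate_map(markers, cmap)
        assert [m.label for m in mapped] == ["rs1"]
        assert [m.label for m in dropped] == ["rs2"]
        assert len(mapped) + len(dropped) == len(markers)

    def test_identity_map_is_identity_after_sort(self):
        markers = make_markers(5)
        cmap = CoordinateMap(
            [
                CoordinateMapEntry(m.chrom, m.pos, m.label, m.chrom, m.pos, m.label)
                for m in markers
            ]
        )
        mapped, order, dropped = apply_coordinate_map(markers, cmap)
        assert mapped == markers and dropped == [] and order == list(range(5))

    def test_against_table_join_oracle(self, rng):
        """100 markers, 10 unmapped, 5 renamed, vs an independent dict join."""
        markers = make_markers(100)
        unmapped = set(rng.choice(100, size=10, replace=False).tolist())
        renamed = set(rng.choice(sorted(set(range(100)) - unmapped), size=5,
                                 replace=False).tolist())
        entries = []
        for i, m in enumerate(markers):
            if i in unmapped:
                entries.append(CoordinateMapEntry(m.chrom, m.pos, m.label,
                                                  status="unmapped"))
            else:
                new_label = f"rsNEW{i}" if i in renamed else m.label
                entries.append(
                    CoordinateMapEntry(m.chrom, m.pos, m.label,
                                       m.chrom, m.pos + 5000, new_label)
                )
        mapped, order, dropped = apply_coordinate_map(markers, CoordinateMap(entries))

        # oracle: plain dict join, independently sorted
        oracle = {}
        for m, e in zip(markers, entries):
            if e.status == "mapped":
                oracle[(e.new_chrom, e.new_pos)] = e.new_label
        assert len(mapped) == 90 and len(dropped) == 10
        assert sum(m.label.startswith("rsNEW") for m in mapped) == 5
        assert {(m.chrom, m.pos): m.label for m in mapped} == oracle
        assert [(m.chrom, m.pos) for m in mapped] == sorted(
            (c, p) for c, p in oracle
        )

    def test_collision_error_names_both(self):
        markers = [
            MarkerRecord("1", 100, "rs1", "A", "G"),
            MarkerRecord("1", 200, "rs2", "G", "A"),
        ]
        entries = [
            CoordinateMapEntry("1", 100, "rs1", "1", 500, "rs1"),
            CoordinateMapEntry("1", 200, "rs2", "1", 500, "rs2"),
        ]
        with pytest.raises(HarmonizeError, match="rs1.*rs2"):
            apply_coordinate_map(markers, CoordinateMap(entries))

    def test_tsv_round_trip(self, tmp_path):
        entries = [
            CoordinateMapEntry("1", 100, "rs1", "1", 1100, "rs1"),
            CoordinateMapEntry("1", 200, "rs2", status="unmapped"),
        ]
        path = tmp_path / "map.tsv"
        write_coordinate_map(path, entries)
        cmap = read_coordinate_map(path)
        assert len(cmap) == 2
        assert cmap.lookup(MarkerRecord("1", 100, "rs1", "A", "G")).new_pos == 1100
        assert cmap.lookup(MarkerRecord("1", 200, "rs2", "A", "G")).status == "unmapped"

    def test_liftover_reorders_genotype_rows(self, rng):
        markers = make_markers(3)
        genotypes = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8)
        ds = GenotypeDataset("d", markers, genotypes, make_roster(2))
        # reverse the positions so sorting inverts row order
        entries = [
            CoordinateMapEntry(m.chrom, m.pos, m.label, m.chrom, 1000 - m.pos, m.label)
            for m in markers
        ]
        lifted, dropped = liftover_dataset(ds, CoordinateMap(entries))
        assert [m.label for m in lifted.markers] == ["rs3", "rs2", "rs1"]
        np.testing.assert_array_equal(lifted.genotypes, genotypes[::-1])


def _pal(freq_minor_on_A, n=200, rng=None, allele_a="A", allele_b="T"):
    """Palindromic marker + dosages with given frequency of allele A."""
    marker = MarkerRecord("1", 5000, "rsP", allele_a, allele_b)
    freq_b = 1.0 - freq_minor_on_A
    dosages = rng.binomial(2, freq_b, size=n).astype(float)
    return marker, dosages


class TestClassifyStrand:
    REF = MarkerRecord("1", 5000, "rsP", "A", "G")

    def test_matching_alleles_keep(self, rng):
        study = MarkerRecord("1", 5000, "rsP", "A", "G")
        d = classify_strand(study, np.ones(10), self.REF, 0.3)
        assert d.action is StrandAction.KEEP and d.basis is StrandBasis.ALLELE_MATCH

    def test_complementary_alleles_flip(self, rng):
        study = MarkerRecord("1", 5000, "rsP", "T", "C")
        d = classify_strand(study, np.ones(10), self.REF, 0.3)
        assert d.action is StrandAction.FLIP

    def test_incompatible_alleles_discard(self):
        study = MarkerRecord("1", 5000, "rsP", "A", "C")
        d = classify_strand(study, np.ones(10), self.REF, 0.3)
        assert d.action is StrandAction.DISCARD

    @pytest.mark.parametrize(
        "study_freq_A,ref_minor_is_A,expected",
        [
            # hand-computed truth table over the four palindromic orientations:
            # study minor allele vs reference minor allele (A/T pair)
            (0.10, True, StrandAction.KEEP),   # both minors are A
            (0.10, False, StrandAction.FLIP),  # study minor A, ref minor T=comp(A)
            (0.90, True, StrandAction.FLIP),   # study minor T, ref minor A
            (0.90, False, StrandAction.KEEP),  # both minors are T
        ],
    )
    def test_palindromic_maf_truth_table(self, rng, study_freq_A,
                                         ref_minor_is_A, expected):
        marker = MarkerRecord("1", 5000, "rsP", "A", "T")
        ref = MarkerRecord("1", 5000, "rsP", "A", "T")
        # dosages count allele T (allele_b); freq of A = 1 - freq_b
        n = 5000
        dosages = rng.binomial(2, 1.0 - study_freq_A, size=n).astype(float)
        ref_freq_b = 0.89 if ref_minor_is_A else 0.11  # freq of T
        d = classify_strand(marker, dosages, ref, ref_freq_b)
        assert d.action is expected and d.basis is StrandBasis.MAF

    def test_palindromic_high_maf_no_neighbors_discarded(self, rng):
        marker = MarkerRecord("1", 5000, "rsP", "A", "T")
        ref = MarkerRecord("1", 5000, "rsP", "A", "T")
        dosages = rng.binomial(2, 0.5, size=500).astype(float)
        d = classify_strand(marker, dosages, ref, 0.5, neighbors=None)
        assert d.action is StrandAction.DISCARD and d.basis is StrandBasis.LD
        assert "neighbors" in d.detail

    def _ld_setup(self, rng, invert_study):
        """Palindromic target at MAF ~0.5 with 5 correlated neighbors."""
        n_ref, n_study = 300, 300
        marker = MarkerRecord("1", 5000, "rsP", "A", "T")
        ref = MarkerRecord("1", 5000, "rsP", "A", "T")
        ref_target = rng.binomial(2, 0.5, size=n_ref).astype(float)
        study_target = rng.binomial(2, 0.5, size=n_study).astype(float)
        neighbors = []
        for _ in range(5):
            noise_r = rng.binomial(1, 0.1, size=n_ref)
            noise_s = rng.binomial(1, 0.1, size=n_study)
            nb_ref = np.clip(ref_target + noise_r - noise_r * (ref_target > 0), 0, 2)
            base = 2 - study_target if invert_study else study_target
            nb_study = np.clip(base + noise_s - noise_s * (base > 0), 0, 2)
            neighbors.append(StrandNeighbor(nb_study, nb_ref, orientation=1))
        return marker, study_target, ref, ref_target, neighbors

    def test_ld_consistent_sign_keeps(self, rng):
        m, sd, ref, rd, nbs = self._ld_setup(rng, invert_study=False)
        d = classify_strand(m, sd, ref, 0.5, ref_dosages=rd, neighbors=nbs)
        assert d.action is StrandAction.KEEP and d.basis is StrandBasis.LD

    def test_ld_inverted_sign_flips(self, rng):
        m, sd, ref, rd, nbs = self._ld_setup(rng, invert_study=True)
        d = classify_strand(m, sd, ref, 0.5, ref_dosages=rd, neighbors=nbs)
        assert d.action is StrandAction.FLIP and d.basis is StrandBasis.LD

    def test_deterministic(self, rng):
        m, sd, ref, rd, nbs = self._ld_setup(rng, invert_study=False)
        d1 = classify_strand(m, sd, ref, 0.5, ref_dosages=rd, neighbors=nbs)
        d2 = classify_strand(m, sd, ref, 0.5, ref_dosages=rd, neighbors=nbs)
        assert d1 == d2


class TestApplyDecisions:
    def test_all_keep_is_identity(self, rng):
        markers = make_markers(4)
        ds = GenotypeDataset("d", markers,
                             rng.integers(0, 3, (4, 3)).astype(np.int8),
                             make_roster(3))
        decisions = [
            classify_strand(m, np.ones(3), m, 0.3) for m in markers
        ]
        out = apply_strand_decisions(ds, decisions)
        assert out.markers == markers
        np.testing.assert_array_equal(out.genotypes, ds.genotypes)

    def test_discarded_marker_absent(self, rng):
        markers = make_markers(3)
        ds = GenotypeDataset("d", markers,
                             rng.integers(0, 3, (3, 2)).astype(np.int8),
                             make_roster(2))
        from imputemerge.harmonize import StrandDecision
        decisions = [
            StrandDecision(markers[0], StrandAction.KEEP, StrandBasis.ALLELE_MATCH),
            StrandDecision(markers[1], StrandAction.DISCARD, StrandBasis.LD),
            StrandDecision(markers[2], StrandAction.KEEP, StrandBasis.ALLELE_MATCH),
        ]
        out = apply_strand_decisions(ds, decisions)
        assert [m.label for m in out.markers] == ["rs1", "rs3"]

    def test_unknown_marker_decision_rejected(self, rng):
        markers = make_markers(2)
        ds = GenotypeDataset("d", markers[:1],
                             np.zeros((1, 2), dtype=np.int8), make_roster(2))
        from imputemerge.harmonize import StrandDecision
        decisions = [
            StrandDecision(m, StrandAction.KEEP, StrandBasis.ALLELE_MATCH)
            for m in markers
        ]
        with pytest.raises(HarmonizeError):
            apply_strand_decisions(ds, decisions)


class TestFlipRecovery:
    def test_injected_flips_recovered_exactly(self):
        """Every complement flip injected on non-palindromic markers is
        detected, and applying the decisions restores the panel's
        allele sets exactly."""
        cfg = SimulationConfig(seed=7, n_markers=400, n_ref_haplotypes=120,
                               n_study_samples=50, flip_rate=0.05,
                               build_offset=0, unmapped_fraction=0.0,
                               missing_rate=0.0)
        panel = simulate_reference(cfg)
        datasets, _, truth = simulate_study(cfg, panel)
        panel_alleles = {(m.chrom, m.pos): m.alleles for m in panel.markers}
        total_injected = total_flagged = 0
        for ds in datasets:
            injected = set(truth.flipped[ds.dataset_id])
            decisions = classify_dataset_strand(ds, panel)
            flagged = {d.marker.label for d in decisions
                       if d.action is StrandAction.FLIP}
            assert injected <= flagged
            non_pal_flagged = {
                d.marker.label for d in decisions
                if d.action is StrandAction.FLIP and not d.marker.is_palindromic
            }
            assert non_pal_flagged == injected
            total_injected += len(injected)
            total_flagged += len(non_pal_flagged)
            harmonized = apply_strand_decisions(ds, decisions)
            for m in harmonized.markers:
                assert m.alleles == panel_alleles[(m.chrom, m.pos)]
        assert total_injected > 0  # the fixture really injected flips

    def test_zero_flip_rate_all_keep_for_nonpalindromic(self):
        cfg = SimulationConfig(seed=8, n_markers=200, n_ref_haplotypes=80,
                               n_study_samples=40, flip_rate=0.0,
                               build_offset=0, unmapped_fraction=0.0,
                               palindromic_fraction=0.0, missing_rate=0.0)
        panel = simulate_reference(cfg)
        datasets, _, _ = simulate_study(cfg, panel)
        for ds in datasets:
            decisions = classify_dataset_strand(ds, panel)
            assert all(d.action is StrandAction.KEEP for d in decisions)


class TestPrefilter:
    def test_call_rate_and_maf_filters(self, rng):
        markers = make_markers(3)
        genotypes = np.array(
            [
                [0, 1, 2, 1, 0, 1, 2, 1, 0, 1],      # fine
                [-1, -1, -1, -1, 0, 1, 2, 1, 0, 1],  # call rate 0.6
                [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],      # MAF 0
            ],
            dtype=np.int8,
        )
        ds = GenotypeDataset("d", markers, genotypes, make_roster(10))
        out = prefilter_markers(ds, call_rate=0.95, maf=0.05)
        assert [m.label for m in out.markers] == ["rs1"]

    def test_palindromic_prefilter_optional(self, rng):
        markers = [
            MarkerRecord("1", 100, "rs1", "A", "T"),
            MarkerRecord("1", 200, "rs2", "A", "G"),
        ]
        genotypes = np.tile([0, 1, 2, 1], (2, 1)).astype(np.int8)
        ds = GenotypeDataset("d", markers, genotypes, make_roster(4))
        assert len(prefilter_markers(ds).markers) == 2
        out = prefilter_markers(ds, drop_palindromic=True)
        assert [m.label for m in out.markers] == ["rs2"]
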