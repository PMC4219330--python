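"""Relative accessibility, range binning and the exposure parsers."""

import numpy as np
import pytest

from exposloc.exposure import (
    AMINO_ACIDS,
    DEFAULT_RANGE_BOUNDARIES,
    DEFAULT_SABLE_MAP,
    DegeneratePartitionError,
    ParseError,
    ProfileConsistencyError,
    RangeBoundaries,
    SableMap,
    assign_range,
    build_profile,
    derive_ranges,
    load_max_accessibility,
    map_sable_to_range,
    parse_dssp,
    parse_sable,
    read_sable_file,
    relative_accessibility,
)

TABLE = load_max_accessibility()


class TestRelativeAccessibility:
    def test_zero_accessibility_is_fully_buried(self):
        for aa in "AGW":
            assert relative_accessibility(0.0, aa) == 0.0

    def test_tabulated_maximum_is_fully_exposed(self):
        assert relative_accessibility(TABLE["G"], "G") == pytest.approx(1.0)

    def test_above_maximum_clamps_to_one(self):
        assert relative_accessibility(2 * TABLE["A"], "A") == 1.0

    def test_midpoint(self):
        assert relative_accessibility(TABLE["K"] / 2, "K") == pytest.approx(0.5)

    def test_unknown_code_returns_skip_signal(self):
        assert relative_accessibility(10.0, "X") is None
        assert relative_accessibility(10.0, "B") is None

    def test_negative_accessibility_rejected(self):
        with pytest.raises(ValueError):
            relative_accessibility(-1.0, "A")

    def test_custom_table_must_be_complete_and_positive(self, tmp_path):
        import json

        p = tmp_path / "tab.json"
        p.write_text(json.dumps({aa: 100.0 for aa in AMINO_ACIDS[:-1]}))
        with pytest.raises(ValueError, match="missing"):
            load_max_accessibility(p)


class TestAssignRange:
    @pytest.mark.parametrize("rsa,expected", [
        (0.0, 1), (0.005, 1),
        (0.01, 2), (0.05, 2),
        (0.08, 3), (0.20, 3),
        (0.21, 4), (0.30, 4),
        (0.37, 5), (0.5, 5),
        (0.57, 6), (0.9, 6), (1.0, 6),
    ])
    def test_boundary_convention(self, rsa, expected):
        # left-closed/right-open intervals, last interval closed
        assert assign_range(rsa) == expected

    @pytest.mark.parametrize("rsa", [-0.1, 1.0001])
    def test_out_of_domain_rejected(self, rsa):
        with pytest.raises(ValueError):
            assign_range(rsa)

    def test_custom_boundaries(self):
        bounds = RangeBoundaries((0.0, 0.5, 1.0))
        assert assign_range(0.49, bounds) == 1
        assert assign_range(0.5, bounds) == 2

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            RangeBoundaries((0.1, 0.5, 1.0))
        with pytest.raises(ValueError):
            RangeBoundaries((0.0, 0.5, 0.4, 1.0))


class TestDeriveRanges:
    def test_uniform_sample_gives_near_equal_counts(self, rng):
        values = rng.uniform(0, 1, 3000)
        bounds = derive_ranges(values, k=6)
        counts = np.bincount([assign_range(v, bounds) for v in values])[1:]
        assert counts.sum() == 3000
        assert counts.max() - counts.min() <= 1

    def test_single_range_is_unit_interval(self, rng):
        assert derive_ranges(rng.uniform(0, 1, 10), k=1).cuts == (0.0, 1.0)

    def test_too_few_distinct_values_is_degenerate(self):
        with pytest.raises(DegeneratePartitionError):
            derive_ranges([0.1, 0.1, 0.9], k=6)

    def test_recovers_reference_boundaries_from_matching_sample(self, rng):
        # Sample with equal mass uniform within each packaged interval; the
        # 6-quantile cuts must land near the packaged boundaries.
        cuts = DEFAULT_RANGE_BOUNDARIES.cuts
        parts = [rng.uniform(cuts[i], cuts[i + 1], 10000) for i in range(6)]
        values = np.concatenate(parts)
        derived = derive_ranges(values, k=6)
        assert np.allclose(derived.cuts[1:-1], cuts[1:-1], atol=0.02)


class TestSableMap:
    def test_default_map_by_enumeration(self):
        # totality, monotonicity and surjectivity over all 10 scores
        targets = [map_sable_to_range(s) for s in range(10)]
        assert targets == [1, 2, 3, 4, 5, 6, 6, 6, 6, 6]
        assert all(b >= a for a, b in zip(targets, targets[1:]))
        assert set(targets) == {1, 2, 3, 4, 5, 6}

    @pytest.mark.parametrize("score,expected", [(0, 1), (4, 5), (9, 6)])
    def test_reference_mappings(self, score, expected):
        assert map_sable_to_range(score) == expected

    @pytest.mark.parametrize("score", [-1, 10])
    def test_out_of_bounds_rejected(self, score):
        with pytest.raises(ValueError):
            map_sable_to_range(score)

    def test_invalid_maps_rejected(self):
        with pytest.raises(ValueError):
            SableMap((1, 2, 3, 4, 5, 6, 6, 6, 6))  # not total
        with pytest.raises(ValueError):
            SableMap((1, 2, 3, 4, 5, 6, 5, 6, 6, 6))  # not monotone
        with pytest.raises(ValueError):
            SableMap((1, 1, 3, 3, 4, 5, 5, 5, 5, 6))  # not surjective

    def test_inverse_partitions_scores(self):
        scores = [s for r in range(1, 7) for s in DEFAULT_SABLE_MAP.inverse(r)]
        assert sorted(scores) == list(range(10))


class TestParseDssp:
    def test_tsv_dialect_round_trip(self, tmp_path):
        p = tmp_path / "x.dssp.tsv"
        p.write_text("1\tA\t50.0\n2\tC\t10.5\n3\tD\t0.0\n")
        assert parse_dssp(p) == [(1, "A", 50.0), (2, "C", 10.5), (3, "D", 0.0)]

    def test_genuine_dssp_layout(self):
        def row(serial, num, aa, acc):
            return (f"{serial:5d}{num:5d} A {aa}".ljust(34) + f"{acc:4d}")

        lines = [
            "==== Secondary Structure Definition by the program DSSP ====",
            "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O",
            row(1, 1, "M", 120),
            row(2, 2, "a", 35),       # half-cystine bridge code -> C
            "    3        !             0   0    0",  # chain break
            row(4, 4, "G", 7),
        ]
        assert parse_dssp(lines) == [(1, "M", 120.0), (2, "C", 35.0), (4, "G", 7.0)]

    def test_lowercase_cysteine_in_tsv(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("1\tb\t12.0\n")
        assert parse_dssp(p) == [(1, "C", 12.0)]

    def test_empty_body(self):
        assert parse_dssp(["# comment only", ""]) == []

    def test_malformed_row_reports_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_dssp(["1\tA\t5.0", "2\tA"])


class TestParseSable:
    def test_basic_record(self):
        assert parse_sable([">p1", "ACD", "059"]) == [
            (1, "A", 0), (2, "C", 5), (3, "D", 9)]

    def test_wrapped_lines_and_no_header(self):
        triples = parse_sable(["ACDE", "FG", "012345"])
        assert [t[2] for t in triples] == [0, 1, 2, 3, 4, 5]
        assert "".join(t[1] for t in triples) == "ACDEFG"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParseError, match="scores"):
            parse_sable([">p1", "ACD", "05"])

    def test_mixed_content_line_rejected(self):
        with pytest.raises(ParseError):
            parse_sable([">p1", "ACD", "0a9"])

    def test_multi_record_file(self):
        records = read_sable_file([">a", "AC", "01", ">b", "DD", "99"])
        assert set(records) == {"a", "b"}
        assert records["b"] == [(1, "D", 9), (2, "D", 9)]


class TestBuildProfile:
    def test_structure_source_bins_by_rsa(self):
        acc = TABLE["A"] * 0.30  # rsa 0.30 -> range 4
        profile = build_profile("p", "AAA", [(1, "A", acc), (2, "A", 0.0)])
        assert [(r.position, r.range_index) for r in profile.residues] == [
            (1, 4), (2, 1)]
        assert profile.residues[0].rsa == pytest.approx(0.30)

    def test_predicted_source_maps_scores(self):
        profile = build_profile("p", "ACD", [(1, "A", 0), (2, "C", 5), (3, "D", 9)],
                                source="predicted")
        assert [r.range_index for r in profile.residues] == [1, 6, 6]
        assert all(r.rsa is None for r in profile.residues)

    def test_position_beyond_sequence_rejected(self):
        with pytest.raises(ProfileConsistencyError):
            build_profile("p", "AC", [(3, "A", 1.0)])

    def test_sequence_mismatch_rejected(self):
        with pytest.raises(ProfileConsistencyError):
            build_profile("p", "AC", [(2, "A", 1.0)])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ProfileConsistencyError):
            build_profile("p", "AA", [(1, "A", 1.0), (1, "A", 2.0)])

    def test_unknown_codes_skipped_but_kept_in_sequence(self):
        profile = build_profile("p", "AXC", [(1, "A", 5.0), (2, "X", 5.0),
                                             (3, "C", 5.0)])
        assert [r.position for r in profile.residues] == [1, 3]
        assert len(profile) == 3

    def test_range_partition_property(self, rng):
        # the six ranges partition the covered residues
        from conftest import random_profile

        for _ in range(20):
            profile = random_profile(rng, length=int(rng.integers(1, 80)))
            by_range = {r: [] for r in range(1, 7)}
            for rec in profile.residues:
                by_range[rec.range_index].append(rec.position)
            union = sorted(p for ps in by_range.values() for p in ps)
            assert union == sorted(r.position for r in profile.residues)
            for r, positions in by_range.items():
                for pos in positions:
                    rec = profile.residues[pos - 1]
                    assert assign_range(rec.rsa) == r
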