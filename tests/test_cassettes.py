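"""Cassette discovery, co-orientation scoring and span statistics."""
import numpy as np
import pytest

from virocycle.cassettes import (
    Cassette,
    CassetteConfig,
    cassette_span_stats,
    chance_co_orientation,
    co_orientation_score,
    discover_cassettes,
    overlap_fraction,
    relative_orientation_states,
)
from virocycle.debruijn import ParameterError
from virocycle.families import ProteinFamily
from virocycle.orfs import Orf


def _family(fid, contigs, members=None):
    members = members or [f"{fid}@{c}" for c in contigs]
    return ProteinFamily(fid, members, frozenset(contigs))


class TestOverlapFraction:
    def test_subset_scores_one(self):
        assert overlap_fraction({1, 2, 3, 4, 5}, {1, 2, 3, 4}) == 1.0

    def test_disjoint_zero_identical_one(self):
        assert overlap_fraction({1, 2}, {3, 4}) == 0.0
        assert overlap_fraction({1, 2}, {1, 2}) == 1.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = frozenset(rng.choice(30, size=rng.integers(1, 12), replace=False).tolist())
            b = frozenset(rng.choice(30, size=rng.integers(1, 12), replace=False).tolist())
            x, y = overlap_fraction(a, b), overlap_fraction(b, a)
            assert x == y and 0 <= x <= 1

    def test_empty_set_rejected(self):
        with pytest.raises(ParameterError):
            overlap_fraction(set(), {1})


class TestDiscoverCassettes:
    def test_two_cooccurring_families_merge(self):
        fams = [_family("family_a", range(10)), _family("family_b", range(10))]
        cas = discover_cassettes(fams)
        assert len(cas) == 1
        assert cas[0].families == frozenset({"family_a", "family_b"})
        assert cas[0].contig_set == frozenset(range(10))

    def test_smaller_family_fully_contained_merges_third_stays_out(self):
        fams = [
            _family("family_a", range(10)),
            _family("family_b", range(5)),  # overlap 1.0 with a
            _family("family_c", range(11, 20)),
        ]
        cas = discover_cassettes(fams)
        assert len(cas) == 1
        assert cas[0].families == frozenset({"family_a", "family_b"})
        assert cas[0].contig_set == frozenset(range(5))  # intersection semantics

    def test_half_overlap_below_threshold_no_cassette(self):
        fams = [_family("family_a", {1, 2, 3, 4}), _family("family_b", {1, 2, 5, 6})]
        assert discover_cassettes(fams) == []

    def test_exact_threshold_merges(self):
        fams = [_family("family_a", {1, 2, 3, 4, 5}), _family("family_b", {1, 2, 3, 4, 9})]
        assert len(discover_cassettes(fams, CassetteConfig(overlap_threshold=0.80))) == 1

    def test_order_invariance(self):
        fams = [
            _family("family_a", range(8)),
            _family("family_b", range(8)),
            _family("family_c", range(4, 12)),
        ]
        out1 = discover_cassettes(fams)
        out2 = discover_cassettes(list(reversed(fams)))
        assert [(c.families, c.contig_set) for c in out1] == [
            (c.families, c.contig_set) for c in out2
        ]

    def test_merging_never_grows_contig_sets(self):
        fams = [
            _family("family_a", range(10)),
            _family("family_b", range(8)),
            _family("family_c", range(6)),
        ]
        cas = discover_cassettes(fams)
        for c in cas:
            for f in fams:
                if f.family_id in c.families:
                    assert c.contig_set <= f.contig_set


def _orientation_fixture(states):
    """One family pair over len(states) contigs with given strand pairs."""
    orfs, mem_a, mem_b = [], [], []
    contigs = []
    for i, (sa, sb) in enumerate(states):
        cid = f"c{i}"
        contigs.append(cid)
        orfs.append(Orf(f"a@{cid}", cid, 0, 303, sa, "M" * 100))
        orfs.append(Orf(f"b@{cid}", cid, 400, 703, sb, "M" * 100))
        mem_a.append(f"a@{cid}")
        mem_b.append(f"b@{cid}")
    fams = [
        ProteinFamily("family_a", mem_a, frozenset(contigs)),
        ProteinFamily("family_b", mem_b, frozenset(contigs)),
    ]
    cassette = Cassette("cassette_x", frozenset({"family_a", "family_b"}), frozenset(contigs))
    return cassette, fams, orfs


class TestCoOrientation:
    def test_four_relative_orientations(self):
        states = relative_orientation_states()
        assert len(states) == 4
        assert len(set(states)) == 4

    def test_uniformly_co_oriented_scores_one(self):
        cassette, fams, orfs = _orientation_fixture([("+", "+")] * 5)
        assert co_orientation_score(cassette, fams, orfs) == 1.0

    def test_two_of_three_modal(self):
        cassette, fams, orfs = _orientation_fixture([("+", "+"), ("+", "+"), ("+", "-")])
        assert co_orientation_score(cassette, fams, orfs) == pytest.approx(2 / 3)

    def test_chance_level_approaches_one_quarter(self, rng):
        # modest n here; the asymptotic check runs in the acceptance suite
        score = chance_co_orientation(20000, rng)
        assert abs(score - 0.25) < 0.02


def test_tsv_exports_round_numbers(tmp_path):
    from virocycle.cassettes import write_cassette_summary_tsv, write_cassettes_tsv

    cassette, fams, orfs = _orientation_fixture([("+", "+")] * 3)
    cassettes = [cassette]
    p1 = tmp_path / "cassettes.tsv"
    p2 = tmp_path / "summary.tsv"
    write_cassettes_tsv(p1, cassettes, fams, orfs)
    lengths = {f"c{i}": 2000 for i in range(3)}
    write_cassette_summary_tsv(p2, cassettes, fams, orfs, lengths)
    lines = p1.read_text().splitlines()
    assert lines[0].startswith("cassette_id\tfamily_id")
    assert len(lines) == 1 + 2 * 3  # 2 families x 3 contigs
    summary = p2.read_text().splitlines()[1].split("\t")
    assert summary[1:4] == ["2", "3", "1.0000"]


class TestSpanStats:
    def test_disjoint_orfs_sum(self):
        cassette, fams, orfs = _orientation_fixture([("+", "+")])
        stats = cassette_span_stats(cassette, fams, orfs, {"c0": 2000})
        bp, frac = stats.per_contig["c0"]
        assert bp == 303 + 303
        assert frac == pytest.approx(606 / 2000)

    def test_overlapping_orfs_union_not_sum(self):
        orfs = [
            Orf("a@c0", "c0", 0, 300, "+", "M" * 99),
            Orf("b@c0", "c0", 150, 450, "+", "M" * 99),
            Orf("a@c1", "c1", 0, 300, "+", "M" * 99),
            Orf("b@c1", "c1", 150, 450, "+", "M" * 99),
        ]
        fams = [
            ProteinFamily("family_a", ["a@c0", "a@c1"], frozenset({"c0", "c1"})),
            ProteinFamily("family_b", ["b@c0", "b@c1"], frozenset({"c0", "c1"})),
        ]
        cassette = Cassette("x", frozenset({"family_a", "family_b"}), frozenset({"c0", "c1"}))
        stats = cassette_span_stats(cassette, fams, orfs, {"c0": 1000, "c1": 1000})
        assert stats.per_contig["c0"][0] == 450

    def test_full_coverage_fraction_one(self):
        orfs = [
            Orf("a@c0", "c0", 0, 600, "+", "M" * 199),
            Orf("b@c0", "c0", 0, 600, "+", "M" * 199),
            Orf("a@c1", "c1", 0, 600, "+", "M" * 199),
            Orf("b@c1", "c1", 0, 600, "+", "M" * 199),
        ]
        fams = [
            ProteinFamily("family_a", ["a@c0", "a@c1"], frozenset({"c0", "c1"})),
            ProteinFamily("family_b", ["b@c0", "b@c1"], frozenset({"c0", "c1"})),
        ]
        cassette = Cassette("x", frozenset({"family_a", "family_b"}), frozenset({"c0", "c1"}))
        stats = cassette_span_stats(cassette, fams, orfs, {"c0": 600, "c1": 600})
        assert stats.per_contig["c0"] == (600, 1.0)
        assert stats.mean_covered_fraction == 1.0
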