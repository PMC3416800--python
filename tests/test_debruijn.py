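"""De Bruijn graph construction, simplification and contig extraction."""
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virocycle.debruijn import (
    Contig,
    DeBruijnGraph,
    EmptyInputError,
    ParameterError,
    SimplifyParams,
    build_graph,
    canonical,
    connected_components,
    count_bubbles,
    extract_contigs,
    revcomp,
    simplify,
)

from conftest import random_seq, swap_base, tile_reads


def brute_canonical_counts(seqs, k):
    """Independent oracle: per-window canonical kmer counting in plain Python."""
    counts = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) <= set("ACGT"):
                counts[canonical(km)] += 1
    return dict(counts)


dna = st.text(alphabet="ACGT", min_size=30, max_size=120)


class TestBuildGraph:
    def test_single_read_single_edge(self):
        g = build_graph(["ACGTG"], 5)
        assert g.edges == {"ACGTG": 1}
        assert g.nodes() == {canonical("ACGT"), canonical("CGTG")}

    def test_node_labels_have_length_k_minus_1(self, rng):
        g = build_graph([random_seq(60, rng)], 5)
        assert all(len(n) == 4 for n in g.nodes())

    def test_two_unrelated_genomes_give_disjoint_subgraphs(self, rng):
        a, b = random_seq(200, rng), random_seq(200, rng)
        g = build_graph([a, b], 23)
        assert connected_components(g) == 2

    @pytest.mark.parametrize("bad_k", [4, 22, 3, 65])
    def test_invalid_k_rejected(self, bad_k, rng):
        with pytest.raises(ParameterError):
            build_graph([random_seq(100, rng)], bad_k)

    def test_k_longer_than_reads_rejected(self):
        with pytest.raises(ParameterError):
            build_graph(["ACGTACGTAC"], 11)

    def test_empty_read_set_rejected(self):
        with pytest.raises(EmptyInputError):
            build_graph([], 21)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seqs=st.lists(dna, min_size=1, max_size=4), k=st.sampled_from([5, 7, 11, 21]))
    def test_counts_match_brute_force(self, seqs, k):
        assert build_graph(seqs, k).edges == brute_canonical_counts(seqs, k)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seqs=st.lists(dna, min_size=1, max_size=4), k=st.sampled_from([7, 21]))
    def test_reverse_complement_invariance(self, seqs, k):
        assert build_graph(seqs, k).edges == build_graph([revcomp(s) for s in seqs], k).edges

    def test_n_containing_kmers_skipped(self):
        g = build_graph(["ACGTGNACGTG"], 5)
        # only windows clear of the N survive: positions 0 and 6
        assert g.total_coverage == 2

    def test_edge_count_conservation(self, rng):
        seqs = [random_seq(100, rng) for _ in range(20)]
        k = 31
        g = build_graph(seqs, k)
        assert g.total_coverage == sum(len(s) - k + 1 for s in seqs)


class TestSimplify:
    def test_low_coverage_edges_removed(self):
        g = DeBruijnGraph(5, {"ACGTG": 1, "CGTGA": 3})
        s = simplify(g, SimplifyParams(min_edge_coverage=2))
        assert canonical("ACGTG") not in s.edges
        assert s.edges[canonical("CGTGA")] == 3

    def test_dead_end_spur_clipped(self, rng):
        backbone = random_seq(300, rng)
        spur = backbone[:40] + "T" if backbone[40] != "T" else backbone[:40] + "A"
        g = build_graph([backbone] * 5 + [spur], 21)
        s = simplify(g, SimplifyParams(min_edge_coverage=1))
        contigs = extract_contigs(s)
        assert len(contigs) == 1
        assert contigs[0].sequence in (backbone, revcomp(backbone))

    def test_bubble_collapses_to_majority_branch(self, rng):
        genome = random_seq(300, rng)
        variant = swap_base(genome, 150)
        g = build_graph([genome] * 10 + [variant], 21)
        s = simplify(g, SimplifyParams(min_edge_coverage=1))
        contigs = extract_contigs(s)
        assert len(contigs) == 1
        assert contigs[0].sequence in (genome, revcomp(genome))

    def test_idempotent(self, rng):
        genome = random_seq(400, rng)
        reads = [genome[i : i + 80] for i in range(0, 320, 13)]
        reads.append(swap_base(genome, 200)[150:250])
        g = build_graph(reads, 21)
        once = simplify(g)
        twice = simplify(once)
        assert once.edges == twice.edges

    def test_empty_graph_passes_through(self):
        assert simplify(DeBruijnGraph(21, {})).edges == {}


class TestExtractContigs:
    def test_circular_genome_recovered_up_to_rotation_and_rc(self, small_genome):
        reads = tile_reads(small_genome, circular=True)  # 5x deterministic tiling
        g = simplify(build_graph(reads, 31), SimplifyParams(min_edge_coverage=1))
        contigs = extract_contigs(g)
        assert [c.is_circular for c in contigs] == [True]
        c = contigs[0]
        assert len(c) == len(small_genome)
        doubled = small_genome + small_genome
        assert c.sequence in doubled or revcomp(c.sequence) in doubled

    def test_linear_genome_single_linear_contig(self, small_genome):
        reads = tile_reads(small_genome, circular=False)
        g = simplify(build_graph(reads, 31), SimplifyParams(min_edge_coverage=1))
        contigs = extract_contigs(g)
        assert len(contigs) == 1
        assert not contigs[0].is_circular
        assert contigs[0].sequence in (small_genome, revcomp(small_genome))

    def test_two_unrelated_genomes_two_contigs(self, rng):
        a, b = random_seq(600, rng), random_seq(600, rng)
        g = simplify(build_graph([a, b], 31), SimplifyParams(min_edge_coverage=1))
        contigs = extract_contigs(g)
        assert len(contigs) == 2
        for seq in (a, b):
            assert any(c.sequence in (seq, revcomp(seq)) for c in contigs)

    def test_contig_kmers_equal_graph_edges(self, rng):
        a = random_seq(500, rng)
        g = simplify(build_graph([a], 21), SimplifyParams(min_edge_coverage=1))
        contigs = extract_contigs(g)
        kmers = set()
        for c in contigs:
            seq = c.sequence + c.sequence[:20] if c.is_circular else c.sequence
            kmers.update(canonical(seq[i : i + 21]) for i in range(len(seq) - 20))
        assert kmers == set(g.edges)

    def test_deterministic_ids_and_order(self, rng):
        a, b = random_seq(600, rng), random_seq(400, rng)
        g = simplify(build_graph([a, b], 21), SimplifyParams(min_edge_coverage=1))
        c1 = extract_contigs(g)
        c2 = extract_contigs(g)
        assert [(c.contig_id, c.sequence) for c in c1] == [
            (c.contig_id, c.sequence) for c in c2
        ]
        assert len(c1[0]) >= len(c1[1])


def _snp_haplotypes(rng, spacing=25):
    """Four genomes identical except three biallelic sites *spacing* bp apart."""
    base = random_seq(180, rng)
    positions = [50, 50 + spacing, 50 + 2 * spacing]
    haplotypes = []
    for bits in [(0, 0, 0), (1, 1, 1), (0, 1, 0), (1, 0, 1)]:
        s = base
        for p, bit in zip(positions, bits):
            if bit:
                s = swap_base(s, p)
        haplotypes.append(s)
    return haplotypes


class TestBubblesAndComponents:
    def test_three_snps_three_bubbles_at_k23(self, rng):
        haps = _snp_haplotypes(rng)
        assert count_bubbles(build_graph(haps, 23)) == 3

    def test_three_snps_not_three_simple_bubbles_at_k27(self, rng):
        haps = _snp_haplotypes(rng)
        # polymorphic windows overlap at k=27: no three independent bubbles
        assert count_bubbles(build_graph(haps, 27)) != 3

    def test_single_genome_no_bubbles(self, rng):
        assert count_bubbles(build_graph([random_seq(300, rng)], 23)) == 0

    def test_shared_segment_joins_at_k23_not_k27(self, rng):
        a = random_seq(200, rng)
        b = random_seq(200, rng)
        # splice a 25 bp stretch of `a` into `b`, forcing different flanks so
        # no accidental 26-mer spans the junctions
        seg = a[75:100]
        flank_l = "A" if a[74] != "A" else "C"
        flank_r = "A" if a[100] != "A" else "C"
        spliced = b[:79] + flank_l + seg + flank_r + b[106:]
        g23 = build_graph([a, spliced], 23)
        g27 = build_graph([a, spliced], 27)
        assert connected_components(g23) == 1
        assert connected_components(g27) == 2

    def test_empty_graph_zero_components(self):
        assert connected_components(DeBruijnGraph(23, {})) == 0
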