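"""Community generation, read simulation, spike-ins and recovery metric."""
import numpy as np
import pytest
from scipy import stats

from virocycle.debruijn import ParameterError, revcomp
from virocycle.simulate import (
    CommunitySpec,
    DesignError,
    SpikeInDesign,
    generate_community,
    recovery_fraction,
    simulate_reads,
    spike_in,
)


def _spec(**kw):
    base = dict(n_genomes=5, length_range=(2000, 4000), seed=1)
    base.update(kw)
    return CommunitySpec(**base)


class TestGenerateCommunity:
    def test_deterministic_per_seed(self):
        g1, a1 = generate_community(_spec())
        g2, a2 = generate_community(_spec())
        assert g1 == g2
        assert np.array_equal(a1, a2)

    def test_abundances_sum_to_one(self):
        _g, ab = generate_community(_spec(abundance_model="power-law"))
        assert abs(ab.sum() - 1) < 1e-12
        _g, ab = generate_community(_spec(abundance_model="uniform"))
        assert abs(ab.sum() - 1) < 1e-12

    def test_circular_fraction_one_flags_all(self):
        genomes, _ab = generate_community(_spec(circular_fraction=1.0))
        assert all(circ for _gid, _seq, circ in genomes)

    def test_genomes_are_repeat_free_at_the_screen_length(self):
        genomes, _ab = generate_community(_spec(n_genomes=2))
        from virocycle.debruijn import build_graph

        for _gid, seq, _c in genomes:
            g = build_graph([seq], 63)
            assert max(g.edges.values()) == 1

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ParameterError):
            CommunitySpec(n_genomes=1, length_range=(500, 600))
        with pytest.raises(ParameterError):
            _spec(error_rate=0.5)


class TestSimulateReads:
    def test_coverage_close_to_expectation(self):
        spec = _spec(n_genomes=1, length_range=(8000, 8000), error_rate=0.0)
        genomes, ab = generate_community(spec)
        n_pairs = 800  # 2*100*800/8000 = 20x
        reads = simulate_reads(genomes, ab, n_pairs, spec)
        base_count = sum(len(p.seq1) + len(p.seq2) for p in reads)
        assert base_count / 8000 == pytest.approx(20, rel=0.10)

    def test_origin_fractions_match_binomial(self):
        spec = _spec(n_genomes=2, length_range=(2000, 2000), error_rate=0.0,
                     circular_fraction=0.0)
        genomes, _ab = generate_community(spec)
        n_pairs = 4000
        reads, truth = simulate_reads(
            genomes, [0.9, 0.1], n_pairs, spec, with_truth=True
        )
        n1 = sum(1 for g in truth.values() if g == "genome_01")
        sd = np.sqrt(n_pairs * 0.9 * 0.1)
        assert abs(n1 - 0.9 * n_pairs) < 3 * sd

    def test_error_free_reads_are_exact_substrings(self):
        spec = _spec(n_genomes=1, length_range=(3000, 3000), error_rate=0.0,
                     circular_fraction=1.0)
        genomes, ab = generate_community(spec)
        reads = simulate_reads(genomes, ab, 150, spec)
        doubled = genomes[0][1] * 2
        for p in reads:
            for s in (p.seq1, p.seq2):
                assert s in doubled or revcomp(s) in doubled

    def test_error_rate_observed(self):
        import edlib

        spec = _spec(n_genomes=1, length_range=(3000, 3000), error_rate=0.01,
                     circular_fraction=0.0)
        genomes, ab = generate_community(spec)
        reads = simulate_reads(genomes, ab, 500, spec)
        genome = genomes[0][1]
        mismatches = bases = 0
        for p in reads:
            for s in (p.seq1, p.seq2):
                ed = min(
                    edlib.align(q, genome, mode="HW", task="distance")["editDistance"]
                    for q in (s, revcomp(s))
                )
                mismatches += ed
                bases += len(s)
        ci = stats.binomtest(mismatches, bases).proportion_ci(0.999)
        assert ci.low < 0.01 < ci.high, mismatches / bases

    def test_tiny_insert_rejected(self):
        with pytest.raises(ParameterError):
            _spec(insert_mean=150)




class TestSpikeIn:
    def _pools(self):
        spec = _spec(n_genomes=2, length_range=(2000, 2500), seed=3)
        genomes, ab = generate_community(spec)
        bg = simulate_reads(genomes, ab, 2200, spec, seed=10)
        t_spec = _spec(n_genomes=1, length_range=(3000, 3000), seed=4)
        tg, tab = generate_community(t_spec)
        target = simulate_reads(tg, tab, 400, t_spec, seed=11)
        return bg, target

    def test_mixture_composition_exact(self):
        bg, target = self._pools()
        design = SpikeInDesign(total_reads=4000, spike_counts=(500,), replicates=1, seed=2)
        mix = spike_in(bg, target, design)[500][0]
        assert mix.n_reads == 4000
        n_spike = sum(1 for p in mix if p.read_id.startswith("sp:"))
        assert 2 * n_spike == 500

    def test_zero_spike_gives_background_only(self):
        bg, target = self._pools()
        design = SpikeInDesign(total_reads=4000, spike_counts=(0,), replicates=1, seed=2)
        mix = spike_in(bg, target, design)[0][0]
        assert all(p.read_id.startswith("bg:") for p in mix)

    def test_replicates_distinct_but_reproducible(self):
        bg, target = self._pools()
        design = SpikeInDesign(total_reads=4000, spike_counts=(200,), replicates=3, seed=7)
        reps_a = spike_in(bg, target, design)[200]
        reps_b = spike_in(bg, target, design)[200]
        ids = [frozenset(p.read_id for p in rep) for rep in reps_a]
        assert len(set(ids)) == 3  # distinct mixtures
        for ra, rb in zip(reps_a, reps_b):
            assert [p.read_id for p in ra] == [p.read_id for p in rb]

    def test_oversized_spike_rejected(self):
        bg, target = self._pools()
        design = SpikeInDesign(total_reads=4000, spike_counts=(2000,), replicates=1, seed=2)
        with pytest.raises(DesignError):
            spike_in(bg, target, design)


class TestRecoveryFraction:
    def test_full_reference_contig_scores_one(self, rng):
        from conftest import random_seq

        ref = random_seq(4000, rng)
        assert recovery_fraction([ref], ref) == 1.0

    def test_no_matching_contig_scores_zero(self, rng):
        from conftest import random_seq

        ref = random_seq(4000, rng)
        other = random_seq(2000, rng)
        assert recovery_fraction([other], ref) == 0.0

    def test_half_reference_scores_half(self, rng):
        from conftest import random_seq

        ref = random_seq(4000, rng)
        assert recovery_fraction([ref[:2000]], ref) == 0.5

    def test_rotated_contig_counts_for_circular_reference(self, rng):
        from conftest import random_seq

        ref = random_seq(3000, rng)
        rotated = ref[1500:] + ref[:1500]
        assert recovery_fraction([rotated], ref, circular_reference=True) == 1.0
        assert recovery_fraction([rotated], ref, circular_reference=False) < 1.0
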