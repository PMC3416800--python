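"""Desk-scale reference benchmarks shipped with the package.

These reproduce, at a scale that runs in minutes on one CPU, the two
experiments the pipeline is built around: recovery of a single clean
circular genome, and recovery of a low-abundance spiked genome mixed
into a background community at fixed read counts (4x10^4 reads total;
spike counts of 500/1000/1500/1798 reads against a 7,996 bp circular
target give 6/13/19/23X coverage of the target).

The background community is 22 linear genomes of 4.5-5.5 kb at uniform
abundance (~35X each): deep enough that the background fills the top-20
retention in the first iteration and the spiked genome is assembled at
its own optimal kmer in a later iteration, preserving the scale
separation between community and spike that the benchmark probes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assemble import run_optitdba
from .kmers import AssemblyConfig
from .simulate import (
    CommunitySpec,
    SpikeInDesign,
    generate_community,
    recovery_fraction,
    simulate_reads,
    spike_in,
)

SPIKE_TOTAL_READS = 40_000
SPIKE_COUNTS = (500, 1000, 1500, 1798)
SPIKE_COVERAGE_LABELS = {500: "6x", 1000: "13x", 1500: "19x", 1798: "23x"}
TARGET_LENGTH = 7_996  # the papillomavirus type 6b genome length
TRIAL_SUBSAMPLE = 10_000


@dataclass
class SpikeRun:
    spike_count: int
    replicate: int
    recovery: float
    n_iterations: int
    reads_conserved: bool


def clean_circular_benchmark(seed: int = 0):
    """Assemble one repeat-free 2.5 kb circular genome at ~20X error-free
    coverage; returns (genome, AssemblyResult, recovery_fraction)."""
    spec = CommunitySpec(
        n_genomes=1, length_range=(2500, 2500), circular_fraction=1.0,
        error_rate=0.0, seed=seed + 5,
    )
    genomes, ab = generate_community(spec)
    reads = simulate_reads(genomes, ab, 250, spec)  # 2*100*250/2500 = 20x
    result = run_optitdba(reads, AssemblyConfig(seed=seed + 11))
    recovery = recovery_fraction(result.contigs, genomes[0][1], circular_reference=True)
    return genomes[0][1], result, recovery


def spike_benchmark_inputs(seed: int = 0):
    """Background/target read pools and the mixture design."""
    bg_spec = CommunitySpec(
        n_genomes=22, length_range=(4500, 5500), circular_fraction=0.0,
        abundance_model="uniform", error_rate=0.001, seed=seed + 101,
    )
    bg_genomes, bg_ab = generate_community(bg_spec)
    bg_reads = simulate_reads(bg_genomes, bg_ab, 21_000, bg_spec)
    target_spec = CommunitySpec(
        n_genomes=1, length_range=(TARGET_LENGTH, TARGET_LENGTH),
        circular_fraction=1.0, error_rate=0.001, seed=seed + 202,
    )
    target_genomes, target_ab = generate_community(target_spec)
    target_reads = simulate_reads(target_genomes, target_ab, 1_000, target_spec)
    design = SpikeInDesign(
        total_reads=SPIKE_TOTAL_READS, spike_counts=SPIKE_COUNTS,
        replicates=3, seed=seed + 303,
    )
    return bg_reads, target_reads, target_genomes[0][1], design


def spike_benchmark(seed: int = 0, replicates: int | None = None) -> list[SpikeRun]:
    """Assemble every spike-in mixture and measure target recovery."""
    bg_reads, target_reads, target_genome, design = spike_benchmark_inputs(seed)
    if replicates is not None:
        design.replicates = replicates
    mixtures = spike_in(bg_reads, target_reads, design)
    runs: list[SpikeRun] = []
    for count in design.spike_counts:
        for r, mix in enumerate(mixtures[count]):
            config = AssemblyConfig(seed=seed + 7, trial_subsample=TRIAL_SUBSAMPLE)
            result = run_optitdba(mix, config)
            recovery = recovery_fraction(
                result.contigs, target_genome, circular_reference=True
            )
            conserved = mix.n_reads == (
                sum(it.reads_mapped for it in result.iterations)
                + result.unassembled_reads.n_reads
            )
            runs.append(
                SpikeRun(
                    spike_count=count,
                    replicate=r,
                    recovery=recovery,
                    n_iterations=len(result.iterations),
                    reads_conserved=conserved,
                )
            )
    return runs


def mean_recovery_by_count(runs: list[SpikeRun]) -> dict[int, float]:
    out: dict[int, list[float]] = {}
    for run in runs:
        out.setdefault(run.spike_count, []).append(run.recovery)
    return {count: float(np.mean(v)) for count, v in sorted(out.items())}


_AA = "ACDEFGHIKLMNPQRSTVWY"


def planted_cassette_benchmark(seed: int = 0, n_contigs: int = 20,
                               randomize_orientation: bool = False,
                               with_decoys: bool = True):
    """Synthetic contigs carrying three conserved co-oriented families.

    Every contig carries a mutated copy (~80% identity to the founder) of
    each of three proteins in a fixed order and orientation pattern, plus
    two unique decoy ORFs.  Runs the full downstream chain — family
    clustering, cassette agglomeration, co-orientation scoring — and
    returns (cassettes, families, orfs, score of the first cassette).
    """
    from .cassettes import co_orientation_score, discover_cassettes
    from .families import cluster_families
    from .orfs import Orf

    rng = np.random.default_rng(seed + 404)

    def protein(n):
        return "".join(_AA[i] for i in rng.integers(0, 20, n))

    def mutate(aa, frac=0.20):
        out = list(aa)
        for i in rng.choice(len(aa), size=int(frac * len(aa)), replace=False):
            out[i] = _AA[int(rng.integers(0, 20))]
        return "".join(out)

    from .families import align_identity

    founders = [protein(150), protein(120), protein(180)]
    pattern = ("+", "+", "-")  # conserved orientation of the three genes
    accepted: list[str] = list(founders)

    def decoy(n=100, ceiling=0.26):
        # decoys are unrelated by construction: resample until far from
        # every founder and every previous decoy
        for _try in range(100):
            aa = protein(n)
            if all(align_identity(aa, other) < ceiling for other in accepted):
                accepted.append(aa)
                return aa
        raise RuntimeError("could not draw an unrelated decoy protein")

    orfs = []
    for c in range(n_contigs):
        cid = f"contig_{c:02d}"
        pos = 100
        for f, founder in enumerate(founders):
            if randomize_orientation:
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = pattern[f]
            aa = mutate(founder)
            span = 3 * (len(aa) + 1)
            orfs.append(Orf(f"{cid}_fam{f}", cid, pos, pos + span, strand, aa))
            pos += span + 50
        if with_decoys:
            for d in range(2):
                aa = decoy()
                orfs.append(Orf(f"{cid}_decoy{d}", cid, pos, pos + 303, "+", aa))
                pos += 353
    families = cluster_families(orfs, identity_threshold=0.30)
    cassettes = discover_cassettes(families)
    score = None
    if cassettes:
        score = co_orientation_score(cassettes[0], families, orfs)
        cassettes[0].co_orientation = score
    return cassettes, families, orfs, score
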