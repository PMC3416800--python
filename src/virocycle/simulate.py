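"""Synthetic viral communities, paired reads, spike-ins and recovery.

The generator emulates the kind of data the assembler targets: a
community of 5-50 circular or linear viral genomes (2-50 kb), skewed
abundances, 100 bp paired-end reads with substitution errors, and a
low-abundance spiked genome mixed at fixed read counts for benchmarking
genome recovery.  Genomes are repeat-screened (no long kmer occurs
twice, on either strand, within a genome) so assembly ground truth is
unambiguous.

All generators are pure functions of their spec and seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .debruijn import Contig, ParameterError, revcomp
from .io import ReadPair, ReadSet

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """Repeat screening failed within the retry budget."""


class DesignError(ValueError):
    """A spike-in design is infeasible for the provided read pools."""


@dataclass
class CommunitySpec:
    """Generative description of a synthetic virome."""

    n_genomes: int
    length_range: tuple[int, int] = (2000, 50000)
    circular_fraction: float = 0.5
    abundance_model: str = "power-law"  # or "uniform"
    power_exponent: float = 1.5
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ParameterError("n_genomes must be >= 1")
        lo, hi = self.length_range
        if lo > hi or lo < 10 * self.read_length:
            raise ParameterError(
                f"genome lengths must be >= 10 x read_length ({10 * self.read_length})"
            )
        if not 0 <= self.error_rate < 0.1:
            raise ParameterError("error_rate must be in [0, 0.1)")
        if not 0 <= self.circular_fraction <= 1:
            raise ParameterError("circular_fraction must be in [0, 1]")
        if self.abundance_model not in ("uniform", "power-law"):
            raise ParameterError("abundance_model must be 'uniform' or 'power-law'")
        if self.insert_mean < 2 * self.read_length:
            raise ParameterError("insert_mean must be >= 2 x read_length")


@dataclass
class SpikeInDesign:
    """Mix a known genome's reads into a background at fixed counts."""

    total_reads: int
    spike_counts: tuple[int, ...] = (500, 1000, 1500, 1798)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c >= self.total_reads for c in self.spike_counts):
            raise DesignError("each spike count must be below total_reads")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")


def _random_screened_genome(length: int, screen_k: int, rng: np.random.Generator,
                            max_tries: int = 25) -> str:
    """Uniform-ACGT genome with no canonical screen_k-mer occurring twice
    (the doubled sequence is screened so circular use is also repeat-free)."""
    from . import _kmerenc as ke

    for _try in range(max_tries):
        seq = _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        _keys, counts = ke.count_canonical([seq + seq[: screen_k - 1]], screen_k)
        if counts.size and counts.max() == 1:
            return seq
    raise GenerationError(
        f"could not draw a repeat-free genome of {length} bp in {max_tries} tries"
    )


def generate_community(spec: CommunitySpec):
    """Draw genomes and abundances for a community spec.

    Returns (genomes, abundances): genomes as (id, sequence, is_circular)
    tuples and abundances as simplex weights.  Power-law abundances fall
    as rank^-a, so genome_01 is the most abundant.
    """
    rng = np.random.default_rng(spec.seed)
    screen_k = 62  # one less than the largest assembly kmer
    genomes = []
    for i in range(spec.n_genomes):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _random_screened_genome(length, screen_k, rng)
        circular = bool(rng.random() < spec.circular_fraction)
        genomes.append((f"genome_{i + 1:02d}", seq, circular))
    if spec.abundance_model == "uniform":
        ab = np.full(spec.n_genomes, 1.0 / spec.n_genomes)
    else:
        w = np.arange(1, spec.n_genomes + 1, dtype=float) ** (-spec.power_exponent)
        ab = w / w.sum()
    return genomes, ab


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hit.size == 0:
        return seq
    code = {65: 0, 67: 1, 71: 2, 84: 3}
    for i in hit:
        old = code[int(arr[i])]
        arr[i] = _ALPHABET[(old + int(rng.integers(1, 4))) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(genomes, abundances, n_pairs: int, spec: CommunitySpec,
                   seed: int | None = None, with_truth: bool = False):
    """Paired-end reads from a community.

    Fragments are drawn by abundance; circular genomes are sampled across
    the origin; mates come from opposite strands at the insert distance;
    substitution errors strike each base independently at ``error_rate``.
    Expected per-genome coverage is 2 * read_length * n_pairs * abundance
    / genome_length.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    if spec.insert_mean < 2 * spec.read_length:
        raise ParameterError("insert_mean must be >= 2 x read_length")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    ab = np.asarray(abundances, dtype=float)
    ab = ab / ab.sum()
    rl = spec.read_length
    picks = rng.choice(len(genomes), size=n_pairs, p=ab)
    inserts = np.clip(
        np.rint(rng.normal(spec.insert_mean, spec.insert_sd, size=n_pairs)).astype(int),
        2 * rl,
        None,
    )
    pairs = []
    truth: dict[str, str] = {}
    for i in range(n_pairs):
        gid, gseq, circular = genomes[picks[i]]
        L = len(gseq)
        insert = int(min(inserts[i], L))
        if circular:
            start = int(rng.integers(0, L))
            frag = (gseq + gseq)[start : start + insert]
        else:
            start = int(rng.integers(0, L - insert + 1))
            frag = gseq[start : start + insert]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        r1 = _inject_errors(frag[:rl], spec.error_rate, rng)
        r2 = _inject_errors(revcomp(frag[-rl:]), spec.error_rate, rng)
        rid = f"pair{i:07d}"
        pairs.append(ReadPair(rid, r1, r2))
        truth[rid] = gid
    reads = ReadSet(pairs)
    return (reads, truth) if with_truth else reads


def spike_in(background: ReadSet, target: ReadSet, design: SpikeInDesign) -> dict[int, list[ReadSet]]:
    """Seeded spike-in mixtures.

    For every spike count, ``replicates`` mixtures are drawn: each holds
    exactly ``total_reads`` reads of which exactly ``spike_count`` come
    from the target pool, sampled without replacement with pairs kept
    intact.  Read ids are prefixed bg:/sp: so provenance stays visible.
    Returns {spike_count: [ReadSet, ...]}.
    """
    out: dict[int, list[ReadSet]] = {}
    for count in design.spike_counts:
        if count % 2 or design.total_reads % 2:
            raise DesignError("read counts must be even (reads are paired)")
        sp_pairs = count // 2
        bg_pairs = (design.total_reads - count) // 2
        if sp_pairs > len(target):
            raise DesignError(f"spike count {count} exceeds the target pool")
        if bg_pairs > len(background):
            raise DesignError("background pool too small for the design")
        reps = []
        for r in range(design.replicates):
            rng = np.random.default_rng(design.seed + 1000 * r + count)
            bg_idx = np.sort(rng.choice(len(background), size=bg_pairs, replace=False))
            sp_idx = np.sort(rng.choice(len(target), size=sp_pairs, replace=False))
            mixed = [
                ReadPair(f"bg:{p.read_id}", p.seq1, p.seq2, p.qual1, p.qual2)
                for p in (background[int(i)] for i in bg_idx)
            ] + [
                ReadPair(f"sp:{p.read_id}", p.seq1, p.seq2, p.qual1, p.qual2)
                for p in (target[int(i)] for i in sp_idx)
            ]
            reps.append(ReadSet(mixed))
        out[count] = reps
    return out


def recovery_fraction(contigs, reference_genome: str, *, min_identity: float = 0.95,
                      min_len: int = 500, circular_reference: bool = False) -> float:
    """Longest reference-matching contig length over the reference length.

    A contig matches when its best gapped alignment to the reference (or
    its reverse complement; against the doubled reference when the
    reference is circular, so rotated assemblies count) reaches
    ``min_identity`` over at least ``min_len`` bp.  Capped at 1.
    """
    if not reference_genome:
        raise ParameterError("empty reference genome")
    target = reference_genome * 2 if circular_reference else reference_genome
    best = 0
    for c in contigs:
        seq = c.sequence if isinstance(c, Contig) else str(c)
        if len(seq) < min_len or len(seq) > len(target):
            continue
        max_ed = int((1 - min_identity) * len(seq))
        for q in (seq, revcomp(seq)):
            res = edlib.align(q, target, mode="HW", task="distance", k=max_ed)
            if res["editDistance"] >= 0:
                best = max(best, len(seq))
                break
    return min(1.0, best / len(reference_genome))
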