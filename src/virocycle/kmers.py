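"""Kmer scanning and selection for the iterative assembly loop.

Every iteration assembles a snapshot of the remaining reads across a
descending range of odd kmers.  Assemblies producing a circular contig
above the completion length win outright (the largest such kmer is
taken, since longer kmers resolve short repeats better); otherwise the
kmer whose twenty most read-supported contigs have the greatest
cumulative length wins, after discarding contigs under 1 kb.
"""
from __future__ import annotations

from dataclasses import dataclass

from .debruijn import Contig, ParameterError, SimplifyParams
from .io import write_tsv

DEFAULT_KMER_RANGE = (63, 59, 55, 51, 47, 43, 39, 35, 31, 27, 23, 19)


class NoUsableAssemblyError(RuntimeError):
    """No kmer produced a circular contig or any scoring contig; the
    iterative loop treats this as its termination signal."""


@dataclass
class KmerScore:
    """Outcome of one trial assembly."""

    k: int
    has_circular: bool
    top_cumulative_length: int
    n_contigs: int = 0

    def __post_init__(self) -> None:
        if self.top_cumulative_length < 0:
            raise ParameterError("top_cumulative_length must be >= 0")


@dataclass
class AssemblyConfig:
    """Tunables of the iterative loop.

    ``trial_subsample`` caps (in reads, drawn as whole pairs) how much
    data the per-kmer trial assemblies see; the full read set is always
    used for the real assembly and for read subtraction.
    """

    kmer_range: tuple[int, ...] = DEFAULT_KMER_RANGE
    top_n: int = 20
    min_contig_len: int = 1000
    circular_min_len: int = 2000
    trial_subsample: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        ks = tuple(self.kmer_range)
        if not ks or any(k % 2 == 0 for k in ks):
            raise ParameterError("kmer_range must be non-empty odd integers")
        if list(ks) != sorted(ks, reverse=True):
            raise ParameterError("kmer_range must be descending")
        for name in ("top_n", "min_contig_len", "circular_min_len", "trial_subsample"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        self.kmer_range = ks


def trial_assemble(reads, k: int, simplify_params: SimplifyParams | None = None,
                   map_params=None) -> tuple[list[Contig], dict[str, int]]:
    """Assemble at one kmer and attach mapped-read support to each contig."""
    from .assemble import MapParams, _support_counts, assemble_at, map_reads

    contigs = assemble_at(reads, k, simplify_params)
    if not contigs:
        return [], {}
    mp = map_params or MapParams(seed_length=k)
    mapping = map_reads(reads, contigs, mp)
    support = _support_counts(mapping)
    for c in contigs:
        c.read_support = support.get(c.contig_id, 0)
    return contigs, support


def score_assembly(contigs: list[Contig], config: AssemblyConfig, k: int | None = None) -> KmerScore:
    """Score one trial: circularity flag plus cumulative top-N length.

    Contigs shorter than ``min_contig_len`` are excluded before ranking
    the remainder by read support (descending).
    """
    if k is None:
        k = contigs[0].kmer_used if contigs else 0
    has_circular = any(
        c.is_circular and len(c) >= config.circular_min_len for c in contigs
    )
    eligible = sorted(
        (c for c in contigs if len(c) >= config.min_contig_len),
        key=lambda c: (-c.read_support, c.contig_id),
    )
    top = eligible[: config.top_n]
    return KmerScore(
        k=k,
        has_circular=has_circular,
        top_cumulative_length=sum(len(c) for c in top),
        n_contigs=len(contigs),
    )


def choose_kmer(scores: list[KmerScore]) -> int:
    """Pick the winning kmer from a set of trial scores.

    Circular assemblies take precedence and the largest circular-yielding
    kmer wins; otherwise the kmer maximising cumulative top-N length wins,
    ties broken toward the larger kmer.  Raises
    :class:`NoUsableAssemblyError` when nothing scored (loop termination).
    """
    if not scores:
        raise ParameterError("choose_kmer needs at least one score")
    circular = [s.k for s in scores if s.has_circular]
    if circular:
        return max(circular)
    best = max(scores, key=lambda s: (s.top_cumulative_length, s.k))
    if best.top_cumulative_length == 0:
        raise NoUsableAssemblyError("no circular contig and all scores zero")
    return best.k


def write_score_table(path, rows) -> None:
    """Per-iteration kmer scan log: (iteration, KmerScore) rows as TSV."""
    write_tsv(
        path,
        ("iteration", "k", "has_circular", "n_contigs", "top_cumulative_length"),
        (
            (it, s.k, str(s.has_circular).lower(), s.n_contigs, s.top_cumulative_length)
            for it, s in rows
        ),
    )
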