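"""The iterative assembly loop and its read mapper.

Each iteration picks the kmer that best assembles a (possibly
subsampled) snapshot of the remaining reads, assembles the full set at
that kmer, retains any circular contigs above the completion length
plus the ``top_n`` contigs ranked by mapped-read support, subtracts
every read pair with at least one mapped mate, and repeats until either
no reads map or no contig reaches the retention length.  A final
assembly of whatever remains is appended so the leftover structure is
reported even though it never won retention.

The mapper is a deterministic seed-and-extend aligner: exact seed words
are matched through a sorted numpy index, candidate placements are then
scored with banded edit-distance alignment (edlib), and a read maps when
its best placement reaches the identity floor.  Circular contigs are
virtually extended past the origin so junction-spanning reads map.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import edlib
import numpy as np

from . import _kmerenc as ke
from .debruijn import (
    Contig,
    DeBruijnGraph,
    EmptyInputError,
    ParameterError,
    SimplifyParams,
    build_graph,
    extract_contigs,
    revcomp,
)
from .io import ReadSet

logger = logging.getLogger("virocycle")

SIZE_CLASSES = (("<1kb", 0, 1000), ("1-3kb", 1000, 3000), ("3-10kb", 3000, 10000), (">10kb", 10000, None))


@dataclass
class MapParams:
    """Read-mapping thresholds.

    ``seed_length`` defaults to the kmer of the assembly being mapped
    against (resolved by the callers); ``min_identity`` is the fraction
    of the read that must survive the best gapped alignment.
    """

    min_identity: float = 0.95
    seed_length: int | None = None
    allow_rc: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ParameterError("min_identity must be in (0, 1]")


@dataclass
class IterationRecord:
    """Bookkeeping for one pass of the loop."""

    iteration: int
    k_chosen: int
    n_contigs_retained: int
    n_circular: int
    reads_mapped: int
    reads_remaining: int


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    iterations: list[IterationRecord]
    unassembled_reads: ReadSet


def _mate_records(reads) -> list[tuple[str, str]]:
    """Flatten a ReadSet into (mate_id, sequence); plain (id, seq) pairs
    pass through so single sequences can be mapped too."""
    if isinstance(reads, ReadSet):
        out = []
        for p in reads:
            out.append((f"{p.read_id}/1", p.seq1))
            out.append((f"{p.read_id}/2", p.seq2))
        return out
    return [(rid, seq.upper()) for rid, seq in reads]


class _ContigIndex:
    """Sorted seed-word index over a set of contigs."""

    def __init__(self, contigs: list[Contig], seed_length: int, max_read_len: int):
        self.s = seed_length
        self.contigs = sorted(contigs, key=lambda c: c.contig_id)
        self.vseqs: list[str] = []
        for c in self.contigs:
            v = c.sequence
            if c.is_circular:
                # extend past the origin so junction reads seed and align
                v = v + v[: min(len(c.sequence), max_read_len - 1)]
            self.vseqs.append(v)
        codes = ke.concat_encoded(self.vseqs)
        fwd, _rev, valid = ke.window_keys(codes, seed_length)
        # absolute window position -> (contig index, offset)
        bounds = np.cumsum([0] + [len(v) + 1 for v in self.vseqs])
        pos = np.nonzero(valid)[0]
        keys = fwd[valid]
        order = np.lexsort((keys["lo"], keys["hi"]))
        self.keys = keys[order]
        abs_pos = pos[order]
        self.contig_idx = (np.searchsorted(bounds, abs_pos, side="right") - 1).astype(np.int64)
        self.offset = abs_pos - bounds[self.contig_idx]

    def lookup(self, query_keys: np.ndarray, cap: int = 8):
        """Exact index matches for each query key, fully vectorised.

        Returns (query_row, contig_idx, offset) arrays; a query with h
        hits (capped at *cap*) contributes h aligned entries.
        """
        lo = np.searchsorted(self.keys, query_keys, side="left")
        hi = np.searchsorted(self.keys, query_keys, side="right")
        n_hits = np.minimum(hi - lo, cap)
        rows = np.repeat(np.arange(query_keys.size), n_hits)
        if rows.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        cum = np.cumsum(n_hits)
        within = np.arange(rows.size) - np.repeat(cum - n_hits, n_hits)
        flat = np.repeat(lo, n_hits) + within
        return rows, self.contig_idx[flat], self.offset[flat]


def map_reads(reads, contigs: list[Contig], params: MapParams | None = None) -> dict[str, tuple[str, float]]:
    """Best-hit read placements: mate id -> (contig_id, identity).

    A read maps when it shares an exact seed of ``seed_length`` bases with
    a contig (either strand when ``allow_rc``) and its best banded gapped
    alignment reaches ``min_identity``, where identity = 1 - edit
    distance / read length.  One best contig is kept per read.
    """
    params = params or MapParams()
    if not contigs:
        raise EmptyInputError("map_reads requires at least one contig")
    mates = _mate_records(reads)
    if not mates:
        return {}
    max_rlen = max(len(seq) for _rid, seq in mates)
    s = params.seed_length if params.seed_length is not None else min(31, max_rlen)
    if s > min(len(c.sequence) for c in contigs):
        s = min(len(c.sequence) for c in contigs)
    index = _ContigIndex(contigs, s, max_rlen)

    # seed words for every mate, both strands, via one encoded pass
    codes = ke.concat_encoded(seq for _rid, seq in mates)
    fwd, rev, valid = ke.window_keys(codes, s)
    starts = np.cumsum([0] + [len(seq) + 1 for _rid, seq in mates])

    queries = []  # (mate_idx, strand, qpos_in_oriented_read, key)
    for m, (_rid, seq) in enumerate(mates):
        L = len(seq)
        if L < s:
            continue
        offs = sorted({0, (L - s) // 2, L - s})
        for off in offs:
            w = starts[m] + off
            if not valid[w]:
                continue
            queries.append((m, "+", off, fwd[w]))
            if params.allow_rc:
                # rev[w] is the seed of the reverse-complemented mate,
                # which sits at offset L-s-off within that orientation
                queries.append((m, "-", L - s - off, rev[w]))
    if not queries:
        return {}
    qkeys = np.array([q[3] for q in queries], dtype=ke.KEY_DTYPE)
    rows, hit_ci, hit_off = index.lookup(qkeys)

    cands: dict[int, set[tuple[int, str, int]]] = {}
    for r, ci, off in zip(rows.tolist(), hit_ci.tolist(), hit_off.tolist()):
        m, strand, qpos, _key = queries[r]
        cands.setdefault(m, set()).add((ci, strand, off - qpos))

    mapping: dict[str, tuple[str, float]] = {}
    pad_base = 4
    for m, cset in cands.items():
        rid, seq = mates[m]
        L = len(seq)
        max_ed = int((1 - params.min_identity) * L)
        pad = pad_base + max_ed
        best: tuple[float, str] | None = None
        rc_seq = None
        for ci, strand, diag in sorted(cset):
            q = seq
            if strand == "-":
                if rc_seq is None:
                    rc_seq = revcomp(seq)
                q = rc_seq
            v = index.vseqs[ci]
            lo = max(0, diag - pad)
            window = v[lo : diag + L + pad]
            if len(window) < s:
                continue
            res = edlib.align(q, window, mode="HW", task="distance", k=max_ed)
            ed = res["editDistance"]
            if ed < 0:
                continue
            ident = 1.0 - ed / L
            cid = index.contigs[ci].contig_id
            if best is None or ident > best[0] or (ident == best[0] and cid < best[1]):
                best = (ident, cid)
            if best is not None and best[0] >= 1.0:
                break
        if best is not None and best[0] >= params.min_identity:
            mapping[rid] = (best[1], best[0])
    return mapping


def subtract_pairs(reads: ReadSet, mapping: dict[str, tuple[str, float]]) -> ReadSet:
    """Drop every pair with at least one mapped mate, keeping input order."""
    kept = []
    for p in reads:
        if (
            f"{p.read_id}/1" in mapping
            or f"{p.read_id}/2" in mapping
            or p.read_id in mapping
        ):
            continue
        kept.append(p)
    return ReadSet(kept)


def assemble_at(reads, k: int, simplify_params: SimplifyParams | None = None) -> list[Contig]:
    """build -> simplify -> extract at a single kmer value."""
    from .debruijn import _simplify_view

    sp = simplify_params or SimplifyParams()
    graph = build_graph(reads, k, min_count=sp.min_edge_coverage)
    view = _simplify_view(graph, sp)
    simplified = DeBruijnGraph(k=k, edges=view.edges)
    return extract_contigs(simplified, _view=view)


def _support_counts(mapping: dict[str, tuple[str, float]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for cid, _ident in mapping.values():
        counts[cid] = counts.get(cid, 0) + 1
    return counts


def run_optitdba(
    reads: ReadSet,
    config=None,
    simplify_params: SimplifyParams | None = None,
    map_params: MapParams | None = None,
    score_log: list | None = None,
) -> AssemblyResult:
    """Run the full iterative assembly loop.

    ``score_log``, when given, collects (iteration, KmerScore) rows for
    the per-iteration kmer scan table.
    """
    from .kmers import AssemblyConfig, NoUsableAssemblyError, choose_kmer, score_assembly, trial_assemble

    config = config or AssemblyConfig()
    sp = simplify_params or SimplifyParams()
    mp = map_params or MapParams()
    if len(reads) == 0:
        raise EmptyInputError("empty read set")

    rng = np.random.default_rng(config.seed)
    current = reads
    contigs_out: list[Contig] = []
    records: list[IterationRecord] = []
    iteration = 0
    last_k: int | None = None

    while len(current) > 0:
        iteration += 1
        trial = current.subsample(config.trial_subsample, rng)
        min_len = trial.min_read_length()
        scores = []
        for k in config.kmer_range:
            if k > min_len:
                continue
            tc, _support = trial_assemble(trial, k, sp, replace(mp, seed_length=k))
            sc = score_assembly(tc, config, k=k)
            scores.append(sc)
            if score_log is not None:
                score_log.append((iteration, sc))
        if not scores:
            iteration -= 1
            break
        try:
            k = choose_kmer(scores)
        except NoUsableAssemblyError:
            iteration -= 1
            break
        last_k = k
        logger.info("iteration %d: k=%d chosen from %d trials", iteration, k, len(scores))

        contigs = assemble_at(current, k, sp)
        if not any(len(c) >= config.min_contig_len for c in contigs):
            iteration -= 1
            break  # zero contigs at the retention length: loop ends
        candidates = [
            c
            for c in contigs
            if len(c) >= config.min_contig_len
            or (c.is_circular and len(c) >= config.circular_min_len)
        ]
        mapping = map_reads(current, candidates, replace(mp, seed_length=k))
        support = _support_counts(mapping)
        for c in candidates:
            c.read_support = support.get(c.contig_id, 0)
            c.iteration = iteration

        circular_kept = [
            c for c in candidates if c.is_circular and len(c) >= config.circular_min_len
        ]
        pool = sorted(
            (c for c in candidates if c not in circular_kept and len(c) >= config.min_contig_len),
            key=lambda c: (-c.read_support, c.contig_id),
        )
        retained = circular_kept + pool[: config.top_n]
        retained_ids = {c.contig_id for c in retained}

        kept_mapping = {
            rid: hit for rid, hit in mapping.items() if hit[0] in retained_ids
        }
        new_reads = subtract_pairs(current, kept_mapping)
        reads_mapped = current.n_reads - new_reads.n_reads
        for i, c in enumerate(retained):
            c.contig_id = f"it{iteration:02d}_{c.contig_id}"
        contigs_out.extend(retained)
        records.append(
            IterationRecord(
                iteration=iteration,
                k_chosen=k,
                n_contigs_retained=len(retained),
                n_circular=len(circular_kept),
                reads_mapped=reads_mapped,
                reads_remaining=new_reads.n_reads,
            )
        )
        stop = reads_mapped == 0
        current = new_reads
        if stop:
            break

    # final sweep: assemble whatever is left at the last useful kmer so the
    # leftover structure is reported even though it never won retention
    if len(current) > 0 and last_k is not None and not (records and records[-1].reads_mapped == 0):
        iteration += 1
        contigs = assemble_at(current, last_k, sp)
        keep = [
            c
            for c in contigs
            if len(c) >= config.min_contig_len
            or (c.is_circular and len(c) >= config.circular_min_len)
        ]
        if keep:
            mapping = map_reads(current, keep, replace(mp, seed_length=last_k))
            support = _support_counts(mapping)
            for c in keep:
                c.read_support = support.get(c.contig_id, 0)
                c.iteration = iteration
                c.contig_id = f"it{iteration:02d}_{c.contig_id}"
            new_reads = subtract_pairs(current, mapping)
            records.append(
                IterationRecord(
                    iteration=iteration,
                    k_chosen=last_k,
                    n_contigs_retained=len(keep),
                    n_circular=sum(
                        1 for c in keep if c.is_circular and len(c) >= config.circular_min_len
                    ),
                    reads_mapped=current.n_reads - new_reads.n_reads,
                    reads_remaining=new_reads.n_reads,
                )
            )
            contigs_out.extend(keep)
            current = new_reads

    return AssemblyResult(
        contigs=contigs_out, iterations=records, unassembled_reads=current
    )


def recruit_profile(reads, contigs: list[Contig], map_params: MapParams | None = None) -> dict[str, int]:
    """Mapped-read counts per contig size class.

    Each mapped read is counted once, in the size class of its best
    contig; unmapped reads are excluded.  Classes are half-open bp
    intervals: [0,1000), [1000,3000), [3000,10000), [10000,inf).
    """
    if not contigs:
        raise EmptyInputError("recruit_profile requires contigs")
    mapping = map_reads(reads, contigs, map_params)
    lengths = {c.contig_id: len(c) for c in contigs}
    profile = {name: 0 for name, _lo, _hi in SIZE_CLASSES}
    for cid, _ident in mapping.values():
        L = lengths[cid]
        for name, lo, hi in SIZE_CLASSES:
            if L >= lo and (hi is None or L < hi):
                profile[name] += 1
                break
    return profile
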