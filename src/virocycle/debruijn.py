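"""Build, simplify and traverse de Bruijn graphs of sequencing reads.

The graph is stored strand-canonically: each edge is the lexicographic
minimum of a kmer and its reverse complement, with a coverage count of
how many read windows observed it (on either strand).  Traversal works
on the double-stranded string view: an "oriented node" is simply a
(k-1)-mer string, and following an edge appends one base.  Every
structure therefore appears once per strand and results are
deduplicated through canonical sequences, which makes the graph
invariant to reverse-complementing the input reads.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from . import _kmerenc as ke


class ParameterError(ValueError):
    """An argument violates a precondition (bad k, reads shorter than k...)."""


class EmptyInputError(ValueError):
    """An operation that needs data received none."""


_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical(seq: str) -> str:
    r = revcomp(seq)
    return seq if seq <= r else r


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically least rotation of s, O(n)."""
    if not s:
        return s
    ss = s + s
    f = [-1] * len(ss)
    kk = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - kk - 1]
        while i != -1 and sj != ss[kk + i + 1]:
            if sj < ss[kk + i + 1]:
                kk = j - i - 1
            i = f[i]
        if sj != ss[kk + i + 1]:
            if sj < ss[kk]:
                kk = j
            f[j - kk] = -1
        else:
            f[j - kk] = i + 1
    return ss[kk : kk + len(s)]


def canonical_rotation(seq: str) -> str:
    """Deterministic representative of a circular sequence: the least
    rotation over both strands."""
    return min(_least_rotation(seq), _least_rotation(revcomp(seq)))


@dataclass
class SimplifyParams:
    """Graph clean-up knobs: coverage floor, tip and bubble length limits.

    ``max_tip_length`` and ``bubble_max_len`` are measured in edges and
    default to 2k when left unset.
    """

    min_edge_coverage: int = 2
    max_tip_length: int | None = None
    bubble_max_len: int | None = None

    def __post_init__(self) -> None:
        if self.min_edge_coverage < 1:
            raise ParameterError("min_edge_coverage must be positive")
        for name in ("max_tip_length", "bubble_max_len"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ParameterError(f"{name} must be positive")

    def tip_limit(self, k: int) -> int:
        return self.max_tip_length if self.max_tip_length is not None else 2 * k

    def bubble_limit(self, k: int) -> int:
        return self.bubble_max_len if self.bubble_max_len is not None else 2 * k


@dataclass
class Contig:
    """An assembled consensus sequence from a maximal non-branching path."""

    contig_id: str
    sequence: str
    is_circular: bool = False
    kmer_used: int = 0
    read_support: int = 0
    iteration: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DeBruijnGraph:
    """Canonical-kmer de Bruijn graph: edges map kmer -> coverage count."""

    k: int
    edges: dict[str, int] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_coverage(self) -> int:
        return sum(self.edges.values())

    def nodes(self) -> set[str]:
        """Canonical (k-1)-mer node set."""
        out: set[str] = set()
        for km in self.edges:
            out.add(canonical(km[:-1]))
            out.add(canonical(km[1:]))
        return out


def _as_sequences(reads) -> list[str]:
    if hasattr(reads, "sequences"):
        return list(reads.sequences())
    if isinstance(reads, str):
        raise ParameterError("pass an iterable of sequences, not a single string")
    return [s.upper() for s in reads]


def build_graph(reads, k: int, *, min_count: int = 1) -> DeBruijnGraph:
    """Count every canonical kmer of every read into a graph.

    Each length-k window (identified with its reverse complement)
    contributes one to exactly one canonical edge; windows containing N
    are skipped.  ``min_count`` is a counting-stage shortcut equivalent
    to the coverage filter of :func:`simplify`.
    """
    seqs = _as_sequences(reads)
    if not seqs:
        raise EmptyInputError("empty read set")
    if k % 2 == 0 or k < 5:
        raise ParameterError(f"k must be odd and >= 5, got {k}")
    if k > ke.MAX_K:
        raise ParameterError(f"k must be <= {ke.MAX_K}, got {k}")
    if k > min(len(s) for s in seqs):
        raise ParameterError(f"k={k} exceeds the shortest read length")
    keys, counts = ke.count_canonical(seqs, k, min_count=min_count)
    edges = dict(zip(ke.decode(keys, k), counts.tolist()))
    return DeBruijnGraph(k=k, edges=edges)


# ---------------------------------------------------------------------------
# double-stranded string-view traversal


class _View:
    """Mutable traversal view of an edge dict.

    Keeps every edge in both orientations for O(1) membership probes,
    together with per-node in/out degree counters that are maintained
    through removals, so degree queries are single dict lookups.
    """

    def __init__(self, edges: dict[str, int]):
        from collections import Counter

        self.edges = edges
        rcs = [revcomp(km) for km in edges]
        self.both = set(edges)
        self.both.update(rcs)
        prefixes = [km[:-1] for km in edges]
        prefixes.extend(s[:-1] for s in rcs)
        suffixes = [km[1:] for km in edges]
        suffixes.extend(s[1:] for s in rcs)
        self.outd: dict[str, int] = Counter(prefixes)
        self.ind: dict[str, int] = Counter(suffixes)

    # queries ------------------------------------------------------------
    def out_edges(self, node: str) -> list[str]:
        return [node + b for b in "ACGT" if node + b in self.both]

    def in_edges(self, node: str) -> list[str]:
        return [b + node for b in "ACGT" if b + node in self.both]

    def outdeg(self, node: str) -> int:
        return self.outd.get(node, 0)

    def indeg(self, node: str) -> int:
        return self.ind.get(node, 0)

    def has_edge(self, oriented_kmer: str) -> bool:
        return oriented_kmer in self.both

    def coverage(self, oriented_kmer: str) -> int:
        return self.edges[canonical(oriented_kmer)]

    # mutation -----------------------------------------------------------
    def remove(self, oriented_kmer: str) -> None:
        c = canonical(oriented_kmer)
        if c not in self.edges:
            return
        del self.edges[c]
        for s in (c, revcomp(c)):
            self.both.discard(s)
            p, q = s[:-1], s[1:]
            self.outd[p] -= 1
            self.ind[q] -= 1

    def bump(self, oriented_kmer: str, extra: int) -> None:
        self.edges[canonical(oriented_kmer)] += extra

    # candidate shortlists (derived from the live counters) ---------------
    def dead_starts(self) -> list[str]:
        return sorted(
            n for n, d in self.outd.items() if d > 0 and self.ind.get(n, 0) == 0
        )

    def branch_starts(self) -> list[str]:
        return sorted(n for n, d in self.outd.items() if d >= 2)

    def junctions(self) -> list[str]:
        out = set()
        for n, d in self.outd.items():
            if d > 0 and (d != 1 or self.ind.get(n, 0) != 1):
                out.add(n)
        for n, d in self.ind.items():
            if d > 0 and (d != 1 or self.outd.get(n, 0) != 1):
                out.add(n)
        return sorted(out)


def _walk_linear(view: _View, first_edge: str, limit: int):
    """Follow a non-branching path starting with *first_edge*.

    Stops at the first node whose in/out degree is not 1/1, or when
    *limit* edges have been used, or when a node repeats (cycle guard).
    Returns (path_edges, internal_nodes, end_node, hit_junction) where
    hit_junction is True when the walk stopped at a branching/terminal
    node rather than by the limit or the cycle guard.
    """
    start = first_edge[:-1]
    path = [first_edge]
    internal: list[str] = []
    seen = {start}
    cur = first_edge[1:]
    ind = view.ind
    outd = view.outd
    both = view.both
    while ind.get(cur, 0) == 1 and outd.get(cur, 0) == 1:
        if cur in seen or len(path) >= limit:
            return path, internal, cur, False
        seen.add(cur)
        internal.append(cur)
        for b in "ACGT":
            nxt = cur + b
            if nxt in both:
                break
        path.append(nxt)
        cur = nxt[1:]
    return path, internal, cur, True


def _find_bubbles(view: _View, limit: int):
    """Yield simple bubbles (s, t, branch_a, branch_b): two internally
    disjoint non-branching paths from s to t, each branch given as
    (path_edges, internal_nodes)."""
    for s in view.branch_starts():
        outs = view.out_edges(s)
        if len(outs) < 2:
            continue
        walks = []
        for e in sorted(outs):
            path, internal, end, ok = _walk_linear(view, e, limit)
            if ok:
                walks.append((end, path, internal))
        by_end: dict[str, list] = {}
        for end, path, internal in walks:
            by_end.setdefault(end, []).append((path, internal))
        for t, branches in sorted(by_end.items()):
            if len(branches) != 2 or t == s:
                continue
            (p1, i1), (p2, i2) = branches
            if set(i1) & set(i2):
                continue
            if s in i1 or s in i2 or t in i1 or t in i2:
                continue
            yield s, t, (p1, i1), (p2, i2)


def count_bubbles(graph: DeBruijnGraph) -> int:
    """Number of node pairs joined by exactly two internally disjoint
    non-branching paths (polymorphism bubbles)."""
    view = _View(dict(graph.edges))
    limit = max(4 * graph.k, 64)
    seen: set[tuple[str, str]] = set()
    for s, t, _a, _b in _find_bubbles(view, limit):
        seen.add(min((s, t), (revcomp(t), revcomp(s))))
    return len(seen)


def connected_components(graph: DeBruijnGraph) -> int:
    """Weakly connected components of the canonical-node graph."""
    g = nx.Graph()
    for km in graph.edges:
        g.add_edge(canonical(km[:-1]), canonical(km[1:]))
    return nx.number_connected_components(g)


def _clip_tips(view: _View, limit: int) -> bool:
    """Remove dead-end spurs of at most *limit* edges that re-join the graph
    at a node with another way in.  Isolated linear paths are kept."""
    changed = False
    for node in view.dead_starts():
        if view.indeg(node) != 0:
            continue
        for e in sorted(view.out_edges(node)):
            if not view.has_edge(e):
                continue
            path, _internal, end, ok = _walk_linear(view, e, limit)
            if not ok or len(path) > limit:
                continue
            if view.indeg(end) >= 2:
                for pe in path:
                    view.remove(pe)
                changed = True
    return changed


def _pop_bubbles(view: _View, limit: int) -> bool:
    """Collapse simple two-path bubbles onto the higher-coverage branch,
    folding the losing branch's coverage into the kept path."""
    changed = False
    for s, t, (p1, i1), (p2, i2) in list(_find_bubbles(view, limit)):
        if any(not view.has_edge(e) for e in p1 + p2):
            continue  # stale: a previous pop already altered this region
        cov1 = sum(view.coverage(e) for e in p1) / len(p1)
        cov2 = sum(view.coverage(e) for e in p2) / len(p2)
        seq1 = "".join(e[-1] for e in p1)
        seq2 = "".join(e[-1] for e in p2)
        if (cov1, seq2) > (cov2, seq1):  # coverage first, ties to smaller seq
            keep, drop = p1, p2
        else:
            keep, drop = p2, p1
        dropped_cov = [view.coverage(e) for e in drop]
        for e in drop:
            view.remove(e)
        if len(keep) == len(drop):
            for e, extra in zip(keep, dropped_cov):
                view.bump(e, extra)
        else:
            extra = int(round(sum(dropped_cov) / len(dropped_cov)))
            for e in keep:
                view.bump(e, extra)
        changed = True
    return changed


def simplify(graph: DeBruijnGraph, params: SimplifyParams | None = None) -> DeBruijnGraph:
    """Coverage-filter, tip-clip and bubble-pop until nothing changes.

    Idempotent: simplifying an already simplified graph is a no-op.
    """
    return DeBruijnGraph(k=graph.k, edges=_simplify_view(graph, params).edges)


def _simplify_view(graph: DeBruijnGraph, params: SimplifyParams | None = None) -> _View:
    """Simplification workhorse; returns the traversal view so callers that
    immediately extract contigs can skip rebuilding it."""
    params = params or SimplifyParams()
    k = graph.k
    edges = {km: c for km, c in graph.edges.items() if c >= params.min_edge_coverage}
    view = _View(edges)  # degree counters stay exact through removals
    for _round in range(1000):
        changed = _clip_tips(view, params.tip_limit(k))
        changed |= _pop_bubbles(view, params.bubble_limit(k))
        if not changed:
            break
    return view


def extract_contigs(graph: DeBruijnGraph, *, _view: _View | None = None) -> list[Contig]:
    """Maximal non-branching paths as contigs; isolated simple cycles
    become circular contigs, reported without repeating the closing
    (k-1)-mer and rotation-normalised for deterministic output."""
    view = _view if _view is not None else _View(dict(graph.edges))
    k = graph.k
    used: set[str] = set()
    sequences: list[tuple[str, bool]] = []
    seen_seqs: set[str] = set()

    for s in view.junctions():
        for e in sorted(view.out_edges(s)):
            if canonical(e) in used:
                continue
            path, _internal, _end, _ok = _walk_linear(view, e, limit=len(view.edges) + 1)
            for pe in path:
                used.add(canonical(pe))
            seq = s + "".join(pe[-1] for pe in path)
            rep = min(seq, revcomp(seq))
            if rep not in seen_seqs:
                seen_seqs.add(rep)
                sequences.append((rep, False))

    # what remains are components in which every node is 1-in/1-out:
    # simple cycles, i.e. circular contigs
    for km in sorted(view.edges):
        if km in used:
            continue
        start = km[:-1]
        path = [km]
        used.add(km)
        cur = km[1:]
        while cur != start:
            nxt = view.out_edges(cur)
            if len(nxt) != 1:  # pragma: no cover - cycle invariant violated
                break
            e = nxt[0]
            path.append(e)
            used.add(canonical(e))
            cur = e[1:]
        seq = "".join(pe[-1] for pe in path)
        rep = canonical_rotation(seq)
        if rep not in seen_seqs:
            seen_seqs.add(rep)
            sequences.append((rep, True))

    sequences.sort(key=lambda t: (-len(t[0]), t[0]))
    width = max(5, len(str(len(sequences))))
    return [
        Contig(
            contig_id=f"contig_{i + 1:0{width}d}",
            sequence=seq,
            is_circular=circ,
            kmer_used=k,
        )
        for i, (seq, circ) in enumerate(sequences)
    ]


def write_contigs_fasta(path, contigs: list[Contig]) -> None:
    """FASTA export with circularity/kmer/support/iteration header tokens."""
    from .io import write_fasta

    write_fasta(
        path,
        (
            (
                f"{c.contig_id} circular={'true' if c.is_circular else 'false'} "
                f"kmer={c.kmer_used} reads={c.read_support} iter={c.iteration}",
                c.sequence,
            )
            for c in contigs
        ),
    )


def to_graphml(graph: DeBruijnGraph, path) -> None:
    """Debugging dump of the canonical graph with coverage edge attributes."""
    g = nx.DiGraph()
    for km, cov in sorted(graph.edges.items()):
        g.add_edge(canonical(km[:-1]), canonical(km[1:]), coverage=int(cov), kmer=km)
    nx.write_graphml(g, path)
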