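"""Cassette discovery: protein families that travel together on contigs.

Families are agglomerated into cassettes whenever the smaller of two
units is found on a shared contig at least 80% of the time
(|intersection| / min size), recalculating overlaps after every merge; a
merged unit's contig set is the intersection of its parts, the
conservative reading of "found on the same group of contigs".  Cassette
coherence is then quantified by the co-orientation score: for each
family pair, the proportion of shared contigs showing the modal of the
four possible relative strand orientations, averaged over pairs — 1.0
for a perfectly conserved cassette, 0.25 expected by chance.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

from .debruijn import ParameterError
from .families import ProteinFamily
from .orfs import Orf


class ConsistencyError(RuntimeError):
    """A cassette's internal bookkeeping is contradictory."""


def relative_orientation_states() -> list[tuple[str, str]]:
    """The possible relative orientations of a gene pair: each gene lies on
    one of two strands, giving 2 x 2 ordered states."""
    return list(itertools.product("+-", repeat=2))


@dataclass
class CassetteConfig:
    overlap_threshold: float = 0.80
    merge_rule: str = "intersection"  # or "union"

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold <= 1:
            raise ParameterError("overlap_threshold must be in (0, 1]")
        if self.merge_rule not in ("intersection", "union"):
            raise ParameterError("merge_rule must be 'intersection' or 'union'")


@dataclass
class Cassette:
    """A group of >= 2 families recurrently co-occurring on contigs."""

    cassette_id: str
    families: frozenset[str]
    contig_set: frozenset[str]
    co_orientation: float | None = None
    span: dict[str, tuple[int, float]] = field(default_factory=dict)


def overlap_fraction(set_a, set_b) -> float:
    """|a intersect b| / min(|a|, |b|); symmetric, in [0, 1]."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ParameterError("overlap_fraction of an empty contig set")
    return len(a & b) / min(len(a), len(b))


def discover_cassettes(families: list[ProteinFamily],
                       config: CassetteConfig | None = None) -> list[Cassette]:
    """Iterative best-first agglomeration of families into cassettes.

    The pair of units (family or already-merged cassette) with the
    highest overlap at or above the threshold merges first; ties break
    toward the larger smaller contig set, then lexicographic family ids.
    Stops when no pair reaches the threshold.  Output is independent of
    the input order of the families.
    """
    config = config or CassetteConfig()
    units: list[tuple[frozenset[str], frozenset[str]]] = sorted(
        ((frozenset([f.family_id]), frozenset(f.contig_set)) for f in families),
        key=lambda u: sorted(u[0]),
    )
    while len(units) > 1:
        best = None
        for i, j in itertools.combinations(range(len(units)), 2):
            fi, ci = units[i]
            fj, cj = units[j]
            if not ci or not cj:
                continue
            ov = overlap_fraction(ci, cj)
            if ov < config.overlap_threshold:
                continue
            key = (ov, min(len(ci), len(cj)), tuple(sorted(fi | fj)))
            # higher overlap first; then larger smaller-set; then earlier ids
            if best is None or (key[0], key[1]) > (best[0][0], best[0][1]) or (
                (key[0], key[1]) == (best[0][0], best[0][1]) and key[2] < best[0][2]
            ):
                best = (key, i, j)
        if best is None:
            break
        _key, i, j = best
        fi, ci = units[i]
        fj, cj = units[j]
        merged_contigs = (ci & cj) if config.merge_rule == "intersection" else (ci | cj)
        merged = (fi | fj, frozenset(merged_contigs))
        units = [u for idx, u in enumerate(units) if idx not in (i, j)] + [merged]
        units.sort(key=lambda u: sorted(u[0]))
    cassettes = [
        (fams, contigs) for fams, contigs in units if len(fams) >= 2 and contigs
    ]
    cassettes.sort(key=lambda t: sorted(t[0]))
    width = max(3, len(str(len(cassettes))))
    return [
        Cassette(
            cassette_id=f"cassette_{i + 1:0{width}d}",
            families=fams,
            contig_set=contigs,
        )
        for i, (fams, contigs) in enumerate(cassettes)
    ]


def _representatives(cassette: Cassette, families: list[ProteinFamily],
                     orfs: list[Orf]) -> dict[str, dict[str, Orf]]:
    """family_id -> contig_id -> representative (longest) member ORF,
    restricted to the cassette's contig set."""
    by_id = {o.orf_id: o for o in orfs}
    fam_by_id = {f.family_id: f for f in families}
    reps: dict[str, dict[str, Orf]] = {}
    for fid in sorted(cassette.families):
        fam = fam_by_id.get(fid)
        if fam is None:
            raise ConsistencyError(f"unknown family {fid} in {cassette.cassette_id}")
        per_contig: dict[str, Orf] = {}
        for oid in fam.member_orfs:
            o = by_id.get(oid)
            if o is None or o.contig_id not in cassette.contig_set:
                continue
            cur = per_contig.get(o.contig_id)
            if cur is None or (o.length_nt, o.orf_id) > (cur.length_nt, cur.orf_id):
                per_contig[o.contig_id] = o
        reps[fid] = per_contig
    return reps


def co_orientation_score(cassette: Cassette, families: list[ProteinFamily],
                         orfs: list[Orf]) -> float:
    """Mean, over family pairs, of the modal relative-orientation share.

    For each unordered family pair (ordered by family id) every shared
    contig contributes one of the four (strand, strand) states read on
    the contig's forward axis; the pair's score is the modal state's
    proportion and the cassette score averages the pairs.
    """
    reps = _representatives(cassette, families, orfs)
    pair_scores = []
    for fa, fb in itertools.combinations(sorted(cassette.families), 2):
        shared = sorted(set(reps[fa]) & set(reps[fb]))
        if not shared:
            raise ConsistencyError(
                f"families {fa},{fb} share no contig inside {cassette.cassette_id}"
            )
        counts: dict[tuple[str, str], int] = {}
        for cid in shared:
            state = (reps[fa][cid].strand, reps[fb][cid].strand)
            counts[state] = counts.get(state, 0) + 1
        pair_scores.append(max(counts.values()) / len(shared))
    if not pair_scores:
        raise ConsistencyError(f"{cassette.cassette_id} has fewer than 2 families")
    return sum(pair_scores) / len(pair_scores)


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


@dataclass
class SpanStats:
    per_contig: dict[str, tuple[int, float]]
    mean_covered_bp: float
    mean_covered_fraction: float


def cassette_span_stats(cassette: Cassette, families: list[ProteinFamily],
                        orfs: list[Orf], contigs) -> SpanStats:
    """Per-contig covered bp (union of member-ORF intervals) and fraction.

    ``contigs`` may be Contig objects or a contig_id -> length mapping.
    Wrap-around ORF intervals on circular contigs are folded modulo the
    contig length before the union.
    """
    if isinstance(contigs, dict):
        lengths = dict(contigs)
    else:
        lengths = {c.contig_id: len(c) for c in contigs}
    fam_by_id = {f.family_id: f for f in families}
    member_ids = set()
    for fid in cassette.families:
        member_ids.update(fam_by_id[fid].member_orfs)
    per_contig_ints: dict[str, list[tuple[int, int]]] = {
        cid: [] for cid in cassette.contig_set
    }
    for o in orfs:
        if o.orf_id not in member_ids or o.contig_id not in per_contig_ints:
            continue
        L = lengths[o.contig_id]
        if o.end <= L:
            per_contig_ints[o.contig_id].append((o.start, o.end))
        else:  # wraps the origin
            per_contig_ints[o.contig_id].append((o.start, L))
            per_contig_ints[o.contig_id].append((0, o.end - L))
    per_contig = {}
    for cid in sorted(per_contig_ints):
        bp = _interval_union(per_contig_ints[cid])
        per_contig[cid] = (bp, bp / lengths[cid])
    n = len(per_contig) or 1
    return SpanStats(
        per_contig=per_contig,
        mean_covered_bp=sum(v[0] for v in per_contig.values()) / n,
        mean_covered_fraction=sum(v[1] for v in per_contig.values()) / n,
    )


def chance_co_orientation(n_contigs: int, rng, n_families: int = 2) -> float:
    """Monte-Carlo chance level of the co-orientation score.

    Builds a synthetic cassette of ``n_families`` families shared by
    ``n_contigs`` contigs with independent uniform strands and scores it
    with :func:`co_orientation_score`; approaches 0.25 for large n.
    """
    families = []
    orfs = []
    contig_ids = [f"c{i}" for i in range(n_contigs)]
    for f in range(n_families):
        members = []
        for i, cid in enumerate(contig_ids):
            strand = "+" if rng.random() < 0.5 else "-"
            oid = f"{cid}_f{f}"
            orfs.append(
                Orf(oid, cid, start=300 * f, end=300 * f + 300, strand=strand,
                    aa_seq="M" * 99)
            )
            members.append(oid)
        families.append(
            ProteinFamily(
                family_id=f"family_{f:04d}",
                member_orfs=members,
                contig_set=frozenset(contig_ids),
            )
        )
    cassette = Cassette(
        cassette_id="cassette_mc",
        families=frozenset(f.family_id for f in families),
        contig_set=frozenset(contig_ids),
    )
    return co_orientation_score(cassette, families, orfs)


def write_cassettes_tsv(path, cassettes: list[Cassette],
                        families: list[ProteinFamily], orfs: list[Orf]) -> None:
    """Per-membership table: cassette, family, contig, representative
    orientation and ORF span on that contig."""
    from .io import write_tsv

    rows = []
    for cas in cassettes:
        reps = _representatives(cas, families, orfs)
        for fid in sorted(cas.families):
            for cid in sorted(reps[fid]):
                o = reps[fid][cid]
                rows.append((cas.cassette_id, fid, cid, o.strand, f"{o.start}-{o.end}"))
    write_tsv(path, ("cassette_id", "family_id", "contig_id", "orientation", "span"), rows)


def write_cassette_summary_tsv(path, cassettes: list[Cassette],
                               families: list[ProteinFamily], orfs: list[Orf],
                               contigs) -> None:
    """One row per cassette: size, contig count, co-orientation, mean span."""
    from .io import write_tsv

    rows = []
    for cas in cassettes:
        score = (
            cas.co_orientation
            if cas.co_orientation is not None
            else co_orientation_score(cas, families, orfs)
        )
        stats = cassette_span_stats(cas, families, orfs, contigs)
        rows.append(
            (
                cas.cassette_id,
                len(cas.families),
                len(cas.contig_set),
                f"{score:.4f}",
                f"{stats.mean_covered_bp:.1f}",
                f"{stats.mean_covered_fraction:.4f}",
            )
        )
    write_tsv(
        path,
        ("cassette_id", "n_families", "n_contigs", "co_orientation",
         "mean_covered_bp", "mean_covered_fraction"),
        rows,
    )


def export_cassette_diagram(path, cassette: Cassette, families: list[ProteinFamily],
                            orfs: list[Orf], contigs) -> None:
    """JSON with per-contig ORF intervals and family colours for plotting."""
    if isinstance(contigs, dict):
        lengths = dict(contigs)
    else:
        lengths = {c.contig_id: len(c) for c in contigs}
    fam_by_id = {f.family_id: f for f in families}
    fam_of = {}
    for fid in sorted(cassette.families):
        for oid in fam_by_id[fid].member_orfs:
            fam_of[oid] = fid
    data = {
        "cassette_id": cassette.cassette_id,
        "families": sorted(cassette.families),
        "co_orientation": cassette.co_orientation,
        "contigs": [
            {
                "contig_id": cid,
                "length": lengths[cid],
                "orfs": [
                    {
                        "orf_id": o.orf_id,
                        "family": fam_of[o.orf_id],
                        "start": o.start,
                        "end": o.end,
                        "strand": o.strand,
                    }
                    for o in sorted(orfs, key=lambda o: o.start)
                    if o.contig_id == cid and o.orf_id in fam_of
                ],
            }
            for cid in sorted(cassette.contig_set)
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
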