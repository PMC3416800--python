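"""Protein-coding families by greedy centroid identity clustering.

ORF translations are processed longest-first; each joins the first
centroid it matches at or above the identity threshold, otherwise it
founds a new centroid.  Clusters whose members sit on at least two
distinct contigs become families — a family is by definition a protein
repeated across contigs — and everything else is discarded as a
singleton.  Identity is matches over global-alignment columns, gaps
counting as columns.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .orfs import Orf


class AlignmentError(ValueError):
    """Alignment of an empty sequence was requested."""


_CIG = re.compile(r"(\d+)([=XIDM])")


def align_identity(aa_a: str, aa_b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Computed on an edit-distance-optimal alignment; symmetric, in [0, 1].
    """
    if not aa_a or not aa_b:
        raise AlignmentError("cannot align an empty sequence")
    # canonical argument order: among edit-optimal alignments the column
    # count can depend on direction, so fix it for exact symmetry
    if (len(aa_a), aa_a) > (len(aa_b), aa_b):
        aa_a, aa_b = aa_b, aa_a
    res = edlib.align(aa_a, aa_b, mode="NW", task="path")
    matches = 0
    columns = 0
    for num, op in _CIG.findall(res["cigar"]):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return matches / columns


@dataclass
class ProteinFamily:
    """A cluster of ORFs whose translations align at >= the threshold."""

    family_id: str
    member_orfs: list[str]
    contig_set: frozenset[str]
    centroid_orf: str = ""


def cluster_families(orfs: list[Orf], identity_threshold: float = 0.30) -> list[ProteinFamily]:
    """Greedy centroid clustering of ORF translations into families.

    Deterministic: ORFs are processed by (aa length desc, orf_id); a
    cluster is reported as a family only when its members span >= 2
    distinct contigs.  Families partition a subset of the ORFs.
    """
    if not orfs:
        raise AlignmentError("cluster_families needs at least one ORF")
    ordered = sorted(orfs, key=lambda o: (-len(o.aa_seq), o.orf_id))
    centroids: list[Orf] = []
    members: list[list[Orf]] = []
    for orf in ordered:
        for ci, cen in enumerate(centroids):
            if align_identity(orf.aa_seq, cen.aa_seq) >= identity_threshold:
                members[ci].append(orf)
                break
        else:
            centroids.append(orf)
            members.append([orf])
    families = []
    for cen, mem in zip(centroids, members):
        contigs = frozenset(o.contig_id for o in mem)
        if len(mem) >= 2 and len(contigs) >= 2:
            families.append((cen, mem, contigs))
    families.sort(key=lambda t: (-len(t[1]), t[0].orf_id))
    width = max(4, len(str(len(families))))
    return [
        ProteinFamily(
            family_id=f"family_{i + 1:0{width}d}",
            member_orfs=[o.orf_id for o in mem],
            contig_set=contigs,
            centroid_orf=cen.orf_id,
        )
        for i, (cen, mem, contigs) in enumerate(families)
    ]


def write_families_tsv(path, families: list[ProteinFamily], orfs: list[Orf]) -> None:
    from .io import write_tsv

    contig_of = {o.orf_id: o.contig_id for o in orfs}
    rows = []
    for fam in families:
        for oid in fam.member_orfs:
            rows.append(
                (fam.family_id, oid, contig_of[oid], int(oid == fam.centroid_orf))
            )
    write_tsv(path, ("family_id", "orf_id", "contig_id", "is_centroid"), rows)
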