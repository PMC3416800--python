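"""Six-frame ORF prediction and translation.

A deterministic longest-ORF caller: every maximal ATG-to-stop span of at
least ``min_orf_len`` nucleotides (stop included) in any of the six
frames is reported, with coordinates on the forward strand of the
contig.  On circular contigs frames are read across the origin; an ORF
crossing the origin keeps start < length and an end beyond the contig
length, so end - start is always the ORF span.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .debruijn import Contig, ParameterError, revcomp

_STOPS = frozenset({"TAA", "TAG", "TGA"})


def translate(nt_seq: str) -> str:
    """Standard-code translation; a terminal stop is dropped."""
    if len(nt_seq) % 3:
        raise ParameterError(f"sequence length {len(nt_seq)} not divisible by 3")
    aa = str(Seq(nt_seq).translate(table=1))
    return aa[:-1] if aa.endswith("*") else aa


@dataclass
class Orf:
    """An open reading frame on a contig, forward-axis half-open coords."""

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    aa_seq: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _scan_strand(seq: str, min_orf_len: int):
    """Maximal ATG->stop spans on one strand; yields (start, length)."""
    n = len(seq)
    for frame in range(3):
        atg: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if atg is not None:
                    span = pos + 3 - atg
                    if span >= min_orf_len:
                        yield atg, span
                    atg = None
            elif atg is None and codon == "ATG":
                atg = pos
    return


def call_orfs(contig: Contig, min_orf_len: int = 102) -> list[Orf]:
    """All maximal ATG->stop ORFs of at least min_orf_len nt, six frames.

    Minus-strand ORFs are reported on the forward axis with start < end.
    For circular contigs the scan runs over the doubled sequence and
    wrap-around ORFs are deduplicated modulo the contig length.
    """
    if min_orf_len % 3:
        raise ParameterError("min_orf_len must be a multiple of 3")
    seq = contig.sequence.upper()
    L = len(seq)
    if L < min_orf_len:
        return []
    scan = seq + seq if contig.is_circular else seq
    found: dict[tuple[int, int, str], Orf] = {}
    for strand in "+-":
        s = scan if strand == "+" else revcomp(scan)
        for pos, span in _scan_strand(s, min_orf_len):
            if span > L:
                continue  # an ORF cannot lap the whole circle
            if strand == "+":
                start, end = pos, pos + span
            else:
                start, end = len(scan) - (pos + span), len(scan) - pos
            if contig.is_circular:
                start0 = start % L
                end0 = start0 + span
            else:
                start0, end0 = start, end
            if start0 >= L:
                continue
            key = (start0, span, strand)
            if key not in found:
                nt = (
                    (seq + seq)[start0:end0]
                    if contig.is_circular
                    else seq[start0:end0]
                )
                if strand == "-":
                    nt = revcomp(nt)
                found[key] = Orf(
                    orf_id="",
                    contig_id=contig.contig_id,
                    start=start0,
                    end=end0,
                    strand=strand,
                    aa_seq=translate(nt),
                )
    orfs = sorted(found.values(), key=lambda o: (o.start, o.end, o.strand))
    for i, o in enumerate(orfs):
        o.orf_id = f"{contig.contig_id}_orf{i + 1:03d}"
    return orfs


def write_orfs_fasta(path, orfs: list[Orf]) -> None:
    from .io import write_fasta

    write_fasta(
        path,
        (
            (f"{o.orf_id} {o.contig_id}:{o.start}-{o.end}({o.strand})", o.aa_seq)
            for o in orfs
        ),
    )


def write_orfs_bed(path, orfs: list[Orf]) -> None:
    """BED6: contig, start, end (0-based half-open), orf id, score, strand."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(
                f"{o.contig_id}\t{o.start}\t{o.end}\t{o.orf_id}\t0\t{o.strand}\n"
            )
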