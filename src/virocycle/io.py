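"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython; thin wrappers add the
strict validation the assembler relies on (single uppercase ACGTN
alphabet, unique read identifiers, paired files of equal length) and
raise errors that name the offending line instead of silently dropping
records.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class PairingError(ValueError):
    """Two FASTQ files (or an interleaved stream) cannot be paired."""


class HitTableError(ValueError):
    """A hit table line cannot be parsed."""


_VALID_NT = frozenset("ACGTN")
_MATE_SUFFIX = re.compile(r"(/[12]|[._][12])$")


def _clean_seq(seq: str, where: str) -> str:
    s = seq.upper()
    if not set(s) <= _VALID_NT:
        bad = sorted(set(s) - _VALID_NT)
        raise FormatError(f"{where}: invalid characters {bad!r} (expected ACGTN)")
    return s


@dataclass
class ReadPair:
    """A pair of mated reads sharing one identifier."""

    read_id: str
    seq1: str
    seq2: str
    qual1: str | None = None
    qual2: str | None = None

    def __post_init__(self) -> None:
        if self.qual1 is not None and len(self.qual1) != len(self.seq1):
            raise FormatError(f"{self.read_id}: qual1/seq1 length mismatch")
        if self.qual2 is not None and len(self.qual2) != len(self.seq2):
            raise FormatError(f"{self.read_id}: qual2/seq2 length mismatch")


class ReadSet:
    """An ordered collection of :class:`ReadPair` with unique identifiers."""

    def __init__(self, pairs: Iterable[ReadPair] = ()):
        self.pairs: list[ReadPair] = list(pairs)
        seen: set[str] = set()
        for p in self.pairs:
            if p.read_id in seen:
                raise FormatError(f"duplicate read id {p.read_id!r}")
            seen.add(p.read_id)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[ReadPair]:
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    @property
    def n_reads(self) -> int:
        return 2 * len(self.pairs)

    def sequences(self) -> Iterator[str]:
        for p in self.pairs:
            yield p.seq1
            yield p.seq2

    def min_read_length(self) -> int:
        return min(min(len(p.seq1), len(p.seq2)) for p in self.pairs)

    def max_read_length(self) -> int:
        return max(max(len(p.seq1), len(p.seq2)) for p in self.pairs)

    def subsample(self, n_reads: int, rng: np.random.Generator) -> "ReadSet":
        """Seeded uniform draw of whole pairs totalling <= n_reads reads."""
        n_pairs = n_reads // 2
        if n_pairs >= len(self.pairs):
            return self
        idx = np.sort(rng.choice(len(self.pairs), size=n_pairs, replace=False))
        return ReadSet([self.pairs[i] for i in idx])


@dataclass
class HitRecord:
    """One ORF-to-reference-protein hit from an external homology search."""

    orf_id: str
    protein_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise HitTableError(f"{self.orf_id}: negative e-value {self.evalue}")


def read_fasta(path, alphabet: str | None = None) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; sequences uppercased, lines joined.

    ``alphabet="nucleotide"`` additionally rejects characters outside
    ACGTN (protein FASTA passes through unvalidated by default).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.description:
            raise FormatError(f"{path}: record with empty header")
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            seq = _clean_seq(seq, f"{path}:{rec.id}")
        # keep the whole header so FASTA round-trips byte-for-byte
        records.append((rec.description, seq))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def strip_mate_suffix(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


def _fastq_records(path) -> list[tuple[str, str, str]]:
    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            rid = title.split()[0]
            out.append((rid, _clean_seq(seq, f"{path}:{rid}"), qual))
    return out


def read_fastq_pairs(path1, path2=None, *, interleaved: bool = False) -> ReadSet:
    """Load paired reads from two FASTQ files or one interleaved file.

    Records pair by order; /1 and /2 style mate suffixes are stripped from
    the identifiers.  A record-count mismatch raises :class:`PairingError`.
    """
    if interleaved:
        if path2 is not None:
            raise ValueError("interleaved input takes a single path")
        recs = _fastq_records(path1)
        if len(recs) % 2:
            raise PairingError(
                f"{path1}: odd record count {len(recs)} in interleaved FASTQ"
            )
        recs1 = recs[0::2]
        recs2 = recs[1::2]
    else:
        if path2 is None:
            raise ValueError("two-file input requires path2 (or interleaved=True)")
        recs1 = _fastq_records(path1)
        recs2 = _fastq_records(path2)
        if len(recs1) != len(recs2):
            raise PairingError(
                f"record count mismatch: {path1} has {len(recs1)}, "
                f"{path2} has {len(recs2)}"
            )
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(recs1, recs2):
        base1, base2 = strip_mate_suffix(id1), strip_mate_suffix(id2)
        if base1 != base2:
            raise PairingError(f"mate ids do not pair: {id1!r} vs {id2!r}")
        pairs.append(ReadPair(base1, s1, s2, q1, q2))
    return ReadSet(pairs)


def write_fastq_pairs(reads: ReadSet, path1, path2=None, *, interleaved: bool = False) -> None:
    """Write pairs to two FASTQ files, or interleaved when path2 is omitted."""

    def _rec(rid: str, mate: int, seq: str, qual: str | None) -> str:
        q = qual if qual is not None else "I" * len(seq)
        return f"@{rid}/{mate}\n{seq}\n+\n{q}\n"

    if interleaved or path2 is None:
        with open(path1, "w") as fh:
            for p in reads:
                fh.write(_rec(p.read_id, 1, p.seq1, p.qual1))
                fh.write(_rec(p.read_id, 2, p.seq2, p.qual2))
    else:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for p in reads:
                f1.write(_rec(p.read_id, 1, p.seq1, p.qual1))
                f2.write(_rec(p.read_id, 2, p.seq2, p.qual2))


def read_hits_table(path) -> list[HitRecord]:
    """Parse a 4+ column tab-separated hit table (orf, protein, e-value, bits).

    The format is the leading subset of blast tabular output; extra columns
    are ignored and lines starting with '#' are comments.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise HitTableError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            orf_id, protein_id = fields[0], fields[1]
            try:
                evalue = float(fields[2])
            except ValueError as exc:
                raise HitTableError(
                    f"{path}:{lineno}: non-numeric e-value {fields[2]!r}"
                ) from exc
            try:
                bitscore = float(fields[3])
            except ValueError as exc:
                raise HitTableError(
                    f"{path}:{lineno}: non-numeric bit score {fields[3]!r}"
                ) from exc
            if evalue < 0:
                raise HitTableError(f"{path}:{lineno}: negative e-value {evalue}")
            records.append(HitRecord(orf_id, protein_id, evalue, bitscore))
    return records


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a YAML mapping")
    return data


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
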