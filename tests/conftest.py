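"""Shared fixtures and sequence helpers for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from virocycle.debruijn import revcomp

COMP = {"A": "C", "C": "A", "G": "T", "T": "G"}  # deterministic base swap


def random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def tile_reads(genome: str, read_len: int = 100, step: int = 20,
               circular: bool = False) -> list[str]:
    """Deterministic error-free reads tiling a genome (across the origin
    when circular) at coverage read_len/step."""
    src = genome + genome[: read_len - 1] if circular else genome
    last = len(genome) if circular else len(genome) - read_len + 1
    return [src[i : i + read_len] for i in range(0, last, step)]


def swap_base(seq: str, pos: int) -> str:
    return seq[:pos] + COMP[seq[pos]] + seq[pos + 1 :]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20120810)


@pytest.fixture()
def small_genome(rng) -> str:
    return random_seq(2500, rng)
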