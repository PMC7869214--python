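"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results position-by-position,
independently of the library's regex-based scanners, so scanner tests are
genuine cross-checks rather than self-comparisons.
"""

from __future__ import annotations

import numpy as np
import pytest

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_proline_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal P-runs by per-position checks: (start 0-based, length)."""
    s = seq.upper()
    n = len(s)
    runs = []
    for i in range(n):
        if s[i] == "P" and (i == 0 or s[i - 1] != "P"):
            length = 0
            while i + length < n and s[i + length] == "P":
                length += 1
            if length >= min_len:
                runs.append((i, length))
    return runs


def brute_consensus_scan(
    seq: str, pattern: str, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All-offsets IUPAC matcher: (position 1-based, strand)."""
    seq = seq.upper()
    pattern = pattern.upper()
    m, n = len(pattern), len(seq)
    hits = []
    for i in range(n - m + 1):
        if all(seq[i + k] in IUPAC[pattern[k]] for k in range(m)):
            hits.append((i + 1, "+"))
        if both_strands:
            # the minus-strand read of seq[i:i+m] is complement, reversed
            if all(
                _COMP[seq[i + m - 1 - k]] in IUPAC[pattern[k]] for k in range(m)
            ):
                hits.append((i + 1, "-"))
    return sorted(hits)


def random_protein(rng: np.random.Generator, length: int, p_freq: float = 0.3) -> str:
    """Random sequence over amino acids + X, proline-enriched so runs occur."""
    letters = list("ACDEFGHIKLMNQRSTVWYX")
    probs = [(1 - p_freq) / len(letters)] * len(letters) + [p_freq]
    return "".join(rng.choice(letters + ["P"], size=length, p=probs))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250929)
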