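"""Detection and classification of consecutive-proline motifs in proteins.

The translation factor eIF5A relieves ribosome stalling at consecutive
proline codons, so proteins carrying runs of three or more prolines (3P /
"PPP" motifs) depend on it for efficient synthesis.  Proteins with several
separate 3P motifs, or a single longer run (PPPP and beyond), are expected
to be the most eIF5A-dependent.  This module scans protein sequences for
*maximal* proline runs — a stretch of six prolines is one ">=6P" run, not
four overlapping 3-mers — profiles each protein, and tabulates a
proteome-wide census of run patterns.

Coordinates are 0-based half-open internally; output tables report 1-based
inclusive start positions, the convention biologists expect.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ProlineRun",
    "MotifProfile",
    "PatternCensus",
    "read_protein_fasta",
    "find_proline_runs",
    "profile_protein",
    "census",
    "profiles_to_table",
    "census_to_table",
    "pattern_label",
]

# 20 standard amino acids plus X (unknown) and * (terminator).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class ProlineRun:
    """A maximal run of prolines: ``start`` is 0-based, ``length`` >= min_len."""

    start: int
    length: int

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


@dataclass
class SequenceRecord:
    """One protein sequence keyed by its systematic name.

    ``description`` is retained for reporting but never used for identity.
    ``had_terminator`` flags that a single trailing ``*`` was stripped on read.
    """

    id: str
    description: str
    residues: str
    had_terminator: bool = False

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MotifProfile:
    """Per-protein inventory of maximal proline runs and its dependence class.

    ``high_dependence`` is True iff the protein has at least ``min_multi_runs``
    separate runs or one run of at least ``min_long_run`` prolines — the
    ">= 2 x 3P or >= PPPP" rule for strong eIF5A dependence.
    """

    protein_id: str
    runs: list[ProlineRun]
    n_runs: int
    max_run_len: int
    pattern_label: str
    high_dependence: bool


@dataclass
class PatternCensus:
    """Proteome-wide tabulation of run patterns."""

    counts: dict[str, int] = field(default_factory=dict)
    n_proteins_scanned: int = 0
    n_with_any_run: int = 0
    n_high_dependence: int = 0


class FastaParseError(ValueError):
    pass


def read_protein_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA into :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated, residues uppercased, and a single
    trailing ``*`` stripped (and flagged).  Raises :class:`FastaParseError`
    on an empty sequence (naming the record index), an invalid residue, or a
    duplicate id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        residues = str(rec.seq).upper()
        had_terminator = residues.endswith("*")
        if had_terminator:
            residues = residues[:-1]
        if not rec.id:
            raise FastaParseError(f"record {i}: empty header")
        if not residues:
            raise FastaParseError(f"record {i} ({rec.id!r}): empty sequence")
        bad = set(residues) - VALID_RESIDUES
        if bad:
            raise FastaParseError(
                f"record {i} ({rec.id!r}): invalid residues {sorted(bad)}"
            )
        if rec.id in seen:
            raise FastaParseError(f"record {i}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                residues=residues,
                had_terminator=had_terminator,
            )
        )
    return records


def find_proline_runs(residues: str, min_len: int = 3) -> list[ProlineRun]:
    """All maximal runs of ``P`` with length >= ``min_len``, sorted by start.

    Matching is case-insensitive; X, ``*`` and every non-P letter break runs.
    A run of length L counts once, never as overlapping windows.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    return [
        ProlineRun(start=m.start(), length=m.end() - m.start())
        for m in re.finditer(rf"P{{{min_len},}}", residues.upper())
    ]


def pattern_label(run_lengths: Iterable[int]) -> str:
    """Canonical pattern label: counts per distinct run length, ascending.

    e.g. run lengths [4, 3, 3] -> ``"2×3P+1×4P"``; no runs -> ``""``.
    """
    c = Counter(run_lengths)
    return "+".join(f"{c[ln]}×{ln}P" for ln in sorted(c))


def profile_protein(
    record: SequenceRecord,
    min_len: int = 3,
    min_multi_runs: int = 2,
    min_long_run: int = 4,
) -> MotifProfile:
    """Profile one protein: runs, canonical label, and dependence class."""
    runs = find_proline_runs(record.residues, min_len=min_len)
    max_run = max((r.length for r in runs), default=0)
    return MotifProfile(
        protein_id=record.id,
        runs=runs,
        n_runs=len(runs),
        max_run_len=max_run,
        pattern_label=pattern_label(r.length for r in runs),
        high_dependence=(len(runs) >= min_multi_runs) or (max_run >= min_long_run),
    )


def census(profiles: Sequence[MotifProfile]) -> PatternCensus:
    """Tabulate pattern labels over one proteome scan.

    The sum of per-pattern counts equals the number of proteins with at least
    one run; proteins with no run contribute only to ``n_proteins_scanned``.
    """
    counts: Counter[str] = Counter()
    n_any = 0
    n_high = 0
    for p in profiles:
        if p.n_runs > 0:
            counts[p.pattern_label] += 1
            n_any += 1
        if p.high_dependence:
            n_high += 1
    return PatternCensus(
        counts=dict(sorted(counts.items())),
        n_proteins_scanned=len(profiles),
        n_with_any_run=n_any,
        n_high_dependence=n_high,
    )


def profiles_to_table(profiles: Sequence[MotifProfile]) -> pd.DataFrame:
    """Tidy profile table; run starts reported 1-based inclusive."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "protein_id": p.protein_id,
                "n_runs": p.n_runs,
                "run_lengths": ",".join(str(r.length) for r in p.runs),
                "run_starts": ",".join(str(r.start + 1) for r in p.runs),
                "max_run_len": p.max_run_len,
                "pattern_label": p.pattern_label,
                "high_dependence": p.high_dependence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "n_runs",
            "run_lengths",
            "run_starts",
            "max_run_len",
            "pattern_label",
            "high_dependence",
        ],
    )


def census_to_table(c: PatternCensus) -> pd.DataFrame:
    df = pd.DataFrame(
        sorted(c.counts.items()), columns=["pattern_label", "n_proteins"]
    )
    return df
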