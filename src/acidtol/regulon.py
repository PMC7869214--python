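"""Transcription-factor target bookkeeping and direct-target calling.

A regulon table lists documented targets of a transcription factor (for
Ume6p: compiled from curated regulation databases).  A target is upgraded
to a *direct* target when the factor's binding consensus occurs in its
promoter — for Ume6p the upstream repressor site 1 (URS1), whose canonical
core TCGGCGGCT is the default pattern here.  Consensus matching honours
IUPAC degeneracy codes in the pattern; ``N`` in the *promoter* matches
nothing (an unsequenced base is never evidence of a site).  Both strands
are scanned by default because URS1 function is orientation-independent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .genesets import GeneSet

__all__ = [
    "ConsensusPattern",
    "PromoterRecord",
    "ConsensusMatch",
    "TargetEvidence",
    "RegulonTable",
    "OverlapReport",
    "scan_consensus",
    "classify_direct_targets",
    "overlap_with_tolerance",
    "read_regulon_tsv",
    "read_promoter_fasta",
    "reverse_complement",
    "IUPAC_CODES",
]

logger = logging.getLogger(__name__)

# IUPAC nucleotide degeneracy codes -> the set of concrete bases matched.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EVIDENCE_DOCUMENTED = "documented"
EVIDENCE_DIRECT = "direct_by_consensus"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusPattern:
    """A degenerate binding-site consensus over IUPAC nucleotide codes."""

    iupac: str
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        bad = [c for c in self.iupac.upper() if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad!r} in pattern {self.iupac!r}")

    def regex(self) -> re.Pattern[str]:
        """Overlap-tolerant regex (lookahead) with concrete base classes.

        Classes contain only A/C/G/T, so a promoter ``N`` can never match.
        """
        body = "".join(f"[{IUPAC_CODES[c]}]" for c in self.iupac.upper())
        return re.compile(f"(?=({body}))")


@dataclass
class PromoterRecord:
    """Promoter DNA, 5'->3' on the coding strand, up to ``window`` bp upstream."""

    gene: str
    sequence: str
    window: int = 1000

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter {self.gene}: invalid bases {sorted(bad)}")
        if len(self.sequence) > self.window:
            raise ValueError(
                f"promoter {self.gene}: length {len(self.sequence)} exceeds "
                f"window {self.window}"
            )


@dataclass(frozen=True)
class ConsensusMatch:
    """Match position is 1-based from the promoter 5' end (leftmost base)."""

    position: int
    strand: str  # "+" or "-"


@dataclass
class TargetEvidence:
    target: str
    evidence: str = EVIDENCE_DOCUMENTED
    match_positions: list[ConsensusMatch] = field(default_factory=list)


@dataclass
class RegulonTable:
    """One transcription factor's targets with their evidence levels."""

    tf: str
    targets: list[TargetEvidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.target for t in self.targets]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate targets in regulon of {self.tf}")
        for t in self.targets:
            if t.evidence == EVIDENCE_DIRECT and not t.match_positions:
                raise ValueError(
                    f"{t.target}: direct_by_consensus requires >=1 match position"
                )

    @property
    def target_ids(self) -> frozenset[str]:
        return frozenset(t.target for t in self.targets)

    @property
    def direct_ids(self) -> frozenset[str]:
        return frozenset(
            t.target for t in self.targets if t.evidence == EVIDENCE_DIRECT
        )

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "tf": self.tf,
                "target": t.target,
                "evidence": t.evidence,
                "match_positions": ";".join(
                    f"{m.position}{m.strand}" for m in t.match_positions
                ),
            }
            for t in self.targets
        ]
        return pd.DataFrame(rows, columns=["tf", "target", "evidence", "match_positions"])


def scan_consensus(
    promoter: PromoterRecord, pattern: ConsensusPattern
) -> list[ConsensusMatch]:
    """All (overlapping) consensus matches in one promoter.

    Forward-strand matches report the 1-based position of their leftmost
    base.  When ``scan_both_strands``, the reverse complement is searched
    too and matches are mapped back to promoter coordinates with strand "−".
    """
    seq = promoter.sequence
    m = len(pattern.iupac)
    if m == 0 or m > len(seq):
        return []
    rx = pattern.regex()
    matches = [ConsensusMatch(mt.start() + 1, "+") for mt in rx.finditer(seq)]
    if pattern.scan_both_strands:
        rc = reverse_complement(seq)
        n = len(seq)
        for mt in rx.finditer(rc):
            # offset i in the reverse complement covers promoter bases
            # [n - i - m, n - i) -> leftmost base at 1-based n - i - m + 1
            matches.append(ConsensusMatch(n - mt.start() - m + 1, "-"))
    return sorted(matches, key=lambda x: (x.position, x.strand))


def classify_direct_targets(
    table: RegulonTable,
    promoters: Sequence[PromoterRecord] | Mapping[str, PromoterRecord],
    pattern: ConsensusPattern,
) -> RegulonTable:
    """Upgrade targets with >=1 consensus match in their promoter to direct.

    Targets without an available promoter are logged and left non-direct.
    """
    if not isinstance(promoters, Mapping):
        promoters = {p.gene: p for p in promoters}
    out: list[TargetEvidence] = []
    missing = 0
    for t in table.targets:
        prom = promoters.get(t.target)
        if prom is None:
            missing += 1
            out.append(replace(t, match_positions=list(t.match_positions)))
            continue
        hits = scan_consensus(prom, pattern)
        if hits:
            out.append(TargetEvidence(t.target, EVIDENCE_DIRECT, hits))
        else:
            out.append(TargetEvidence(t.target, EVIDENCE_DOCUMENTED, []))
    if missing:
        logger.warning(
            "%d of %d targets have no promoter sequence; left non-direct",
            missing, len(table.targets),
        )
    result = RegulonTable(tf=table.tf, targets=out)
    logger.info(
        "%s: %d targets, %d direct by consensus",
        table.tf, len(result.targets), len(result.direct_ids),
    )
    return result


@dataclass
class OverlapReport:
    """Set arithmetic between a regulon and a tolerance gene set."""

    n_targets: int
    n_direct: int
    n_targets_in_tolerance: int
    n_direct_in_tolerance: int
    targets_in_tolerance: frozenset[str]
    direct_in_tolerance: frozenset[str]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("targets", self.n_targets, ""),
                ("direct_targets", self.n_direct, ""),
                (
                    "targets_in_tolerance",
                    self.n_targets_in_tolerance,
                    ";".join(sorted(self.targets_in_tolerance)),
                ),
                (
                    "direct_in_tolerance",
                    self.n_direct_in_tolerance,
                    ";".join(sorted(self.direct_in_tolerance)),
                ),
            ],
            columns=["quantity", "count", "members"],
        )


def overlap_with_tolerance(table: RegulonTable, tolerance: GeneSet) -> OverlapReport:
    """Counts of targets / direct targets that are also tolerance genes."""
    targets = table.target_ids
    direct = table.direct_ids
    t_in = targets & tolerance.ids
    d_in = direct & tolerance.ids
    return OverlapReport(
        n_targets=len(targets),
        n_direct=len(direct),
        n_targets_in_tolerance=len(t_in),
        n_direct_in_tolerance=len(d_in),
        targets_in_tolerance=frozenset(t_in),
        direct_in_tolerance=frozenset(d_in),
    )


def read_regulon_tsv(path: str | Path) -> RegulonTable:
    """Read tf<TAB>target[<TAB>evidence] rows (one TF per file)."""
    tf: str | None = None
    targets: list[TargetEvidence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected tf<TAB>target")
            if tf is None:
                tf = parts[0]
            elif parts[0] != tf:
                raise ValueError(
                    f"{path}:{lineno}: multiple TFs in one table "
                    f"({tf!r} and {parts[0]!r})"
                )
            evidence = parts[2] if len(parts) > 2 and parts[2] else EVIDENCE_DOCUMENTED
            if evidence == EVIDENCE_DIRECT:
                # positions unknown on load; downgrade until promoters rescanned
                evidence = EVIDENCE_DOCUMENTED
            targets.append(TargetEvidence(parts[1], evidence))
    if tf is None:
        raise ValueError(f"{path}: empty regulon table")
    return RegulonTable(tf=tf, targets=targets)


def read_promoter_fasta(path: str | Path, window: int = 1000) -> list[PromoterRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            PromoterRecord(gene=rec.id, sequence=str(rec.seq), window=window)
        )
    return records
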