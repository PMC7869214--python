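"""Alias-aware gene-set arithmetic and functional categorization.

Deletion-collection screens and genome databases mix standard gene names
(e.g. HYP2) and systematic ORF names (e.g. YEL034W).  Everything here works
in the systematic namespace: identifiers are canonicalized through an
:class:`AliasMap` on load, after which union / intersection are exact set
operations.  The deduplicating union is the "consistency analysis" used to
merge independent acid-sensitivity screens; intersection with the
polyproline gene set and the high-dependence filter implement the
candidate-gene funnel (screens -> union -> common -> strongly
eIF5A-dependent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motifscan import MotifProfile

__all__ = [
    "GeneSet",
    "AliasMap",
    "AnnotationMap",
    "UnionResult",
    "load_gene_list",
    "consistency_union",
    "intersect",
    "filter_high_dependence",
    "categorize",
]

logger = logging.getLogger(__name__)

UNKNOWN_CATEGORY = "unknown function"


@dataclass(frozen=True)
class GeneSet:
    """A named collection of canonical gene identifiers with provenance."""

    name: str
    ids: frozenset[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, ident: str) -> bool:
        return ident in self.ids


class AliasMap:
    """Many-to-one mapping alias -> canonical (systematic) name.

    Canonical names always resolve to themselves.  Unknown identifiers are
    returned verbatim — dropping them silently would corrupt funnel counts —
    and recorded in :attr:`unknown_seen`.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        self.unknown_seen: set[str] = set()
        if mapping:
            for alias, canonical in mapping.items():
                self._map[alias] = canonical
                self._map.setdefault(canonical, canonical)

    def __contains__(self, ident: str) -> bool:
        return ident in self._map

    def __len__(self) -> int:
        return len(self._map)

    def resolve(self, ident: str) -> str:
        if ident in self._map:
            return self._map[ident]
        self.unknown_seen.add(ident)
        return ident

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasMap":
        """Load a two-column TSV: alias<TAB>canonical. '#' lines skipped."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected alias<TAB>canonical")
                mapping[parts[0]] = parts[1]
        return cls(mapping)


class AnnotationMap:
    """Mapping canonical gene id -> set of functional category labels."""

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None) -> None:
        self._map: dict[str, set[str]] = {}
        if mapping:
            for gene, cats in mapping.items():
                cats = {c for c in cats if c}
                if any(not c for c in cats):
                    raise ValueError(f"empty category label for {gene}")
                self._map[gene] = set(cats)

    def categories(self, gene: str) -> set[str]:
        return self._map.get(gene, set())

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        """Load gene<TAB>category rows (repeated rows for multi-category)."""
        mapping: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[1]:
                    raise ValueError(f"{path}:{lineno}: expected gene<TAB>category")
                mapping.setdefault(parts[0], set()).add(parts[1])
        return cls(mapping)


def load_gene_list(
    path: str | Path,
    alias_map: AliasMap | None = None,
    name: str | None = None,
) -> GeneSet:
    """Read one identifier per line (or first TSV column) into a GeneSet.

    Identifiers are canonicalized through ``alias_map``; unknown aliases are
    kept verbatim and logged.  An empty file yields an empty set with a
    warning rather than an error.
    """
    path = Path(path)
    alias_map = alias_map or AliasMap()
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ident = line.split("\t")[0].strip()
            if ident:
                ids.add(alias_map.resolve(ident))
    if not ids:
        logger.warning("gene list %s is empty", path)
    if alias_map.unknown_seen:
        logger.info(
            "%d identifiers in %s not in alias map, kept verbatim",
            len(alias_map.unknown_seen), path,
        )
    return GeneSet(name=name or path.stem, ids=frozenset(ids), provenance=str(path))


@dataclass
class UnionResult:
    """Deduplicating union of screens plus the bookkeeping that validates it."""

    union: GeneSet
    per_source: dict[str, int] = field(default_factory=dict)
    pairwise_overlaps: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return len(self.union)


def consistency_union(sets: Sequence[GeneSet], name: str = "union") -> UnionResult:
    """Exact deduplicating union across screens ("exclude the repeats").

    Reports per-source counts and all pairwise overlap sizes so the
    inclusion–exclusion identity |A∪B| = |A| + |B| − |A∩B| can be audited on
    every pair.
    """
    ids: set[str] = set()
    for s in sets:
        ids |= s.ids
    per_source = {s.name: len(s) for s in sets}
    overlaps = {
        (a.name, b.name): len(a.ids & b.ids) for a, b in combinations(sets, 2)
    }
    union = GeneSet(
        name=name,
        ids=frozenset(ids),
        provenance="union of: " + ", ".join(s.name for s in sets),
    )
    return UnionResult(union=union, per_source=per_source, pairwise_overlaps=overlaps)


def intersect(a: GeneSet, b: GeneSet, name: str | None = None) -> GeneSet:
    """Exact intersection, with provenance naming both parents."""
    return GeneSet(
        name=name or f"{a.name}∩{b.name}",
        ids=frozenset(a.ids & b.ids),
        provenance=f"intersection of {a.name} and {b.name}",
    )


def filter_high_dependence(
    genes: GeneSet, profiles: Sequence[MotifProfile], name: str | None = None
) -> GeneSet:
    """Subset of ``genes`` whose motif profile marks strong eIF5A dependence.

    Genes without a profile are logged and excluded (a gene that was never
    scanned cannot be called dependent).
    """
    by_id = {p.protein_id: p for p in profiles}
    missing = {g for g in genes.ids if g not in by_id}
    if missing:
        logger.warning(
            "%d genes have no motif profile and are excluded: %s",
            len(missing), ", ".join(sorted(missing)[:10]),
        )
    kept = frozenset(
        g for g in genes.ids if g in by_id and by_id[g].high_dependence
    )
    return GeneSet(
        name=name or f"{genes.name}|high-dependence",
        ids=kept,
        provenance=f"high-eIF5A-dependence subset of {genes.name}",
    )


def categorize(genes: GeneSet, ann: AnnotationMap) -> pd.DataFrame:
    """Per-category membership table (columns: category, count, members).

    A gene with k categories contributes one count to each of the k rows, so
    the column sum can exceed |genes|; unannotated genes are reported under
    the ``"unknown function"`` row.  Member lists are emitted so single-count
    views can be derived downstream.
    """
    members: dict[str, set[str]] = {}
    for g in sorted(genes.ids):
        cats = ann.categories(g) or {UNKNOWN_CATEGORY}
        for c in cats:
            members.setdefault(c, set()).add(g)
    rows = [
        {"category": c, "count": len(m), "members": ";".join(sorted(m))}
        for c, m in members.items()
    ]
    df = pd.DataFrame(rows, columns=["category", "count", "members"])
    if len(df):
        df = df.sort_values(
            ["count", "category"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
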