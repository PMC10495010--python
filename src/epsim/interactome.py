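"""Interaction-partner sets and their overlap structure.

An interaction table maps each redoxin to the set of UniProtKB accessions
reported as its interaction partners (from IntAct/BioGRID-style exports or
a planted synthetic table).  Operations: per-protein partner counts, the
matrix of common interactions, Venn region counts for 2-5 proteins, and the
number of partners exclusive to a single redoxin.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

__all__ = [
    "CountMatrix",
    "InteractionTable",
    "read_interaction_table",
    "write_interaction_table",
    "partner_counts",
    "overlap_matrix",
    "venn_counts",
    "exclusive_partner_count",
]

_ISOFORM_SUFFIX = re.compile(r"-\d+$")


@dataclass
class CountMatrix:
    """A labelled symmetric matrix of integer counts (diagonal = set sizes)."""

    labels: list[str]
    M: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.M):
                fh.write(lab + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


@dataclass
class InteractionTable:
    """Per-redoxin sets of partner accessions."""

    partners: dict[str, set[str]] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return list(self.partners)

    def __getitem__(self, label: str) -> set[str]:
        return self.partners[label]


def _canonical(accession: str, trim_isoforms: bool) -> str:
    acc = accession.strip()
    if trim_isoforms:
        acc = _ISOFORM_SUFFIX.sub("", acc)
    return acc


def read_interaction_table(path, trim_isoforms: bool = True) -> InteractionTable:
    """Read a TSV with columns ``redoxin`` and ``partner``.

    Partner sets are deduplicated; isoform suffixes ("-1", "-2", ...) are
    trimmed from accessions by default so isoform and canonical entries
    collapse (disable with ``trim_isoforms=False``).  Rows with an empty
    partner field are skipped with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"{path.name}: empty interaction table")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    try:
        i_red = header.index("redoxin")
        i_par = header.index("partner")
    except ValueError as exc:
        raise ValueError(f"{path.name}: need 'redoxin' and 'partner' columns, got {header}") from exc
    table = InteractionTable()
    for ln in lines[1:]:
        cells = ln.split("\t")
        redoxin = cells[i_red].strip() if len(cells) > i_red else ""
        partner = cells[i_par].strip() if len(cells) > i_par else ""
        if not redoxin:
            continue
        table.partners.setdefault(redoxin, set())
        if not partner:
            warnings.warn(f"{path.name}: empty partner field for {redoxin}; row skipped")
            continue
        table.partners[redoxin].add(_canonical(partner, trim_isoforms))
    return table


def write_interaction_table(table: InteractionTable, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("redoxin\tpartner\n")
        for label, parts in table.partners.items():
            for p in sorted(parts):
                fh.write(f"{label}\t{p}\n")
    return path


def partner_counts(table: InteractionTable) -> dict[str, int]:
    """Size of each redoxin's partner set."""
    return {label: len(parts) for label, parts in table.partners.items()}


def overlap_matrix(table: InteractionTable) -> CountMatrix:
    """Matrix of common interactions: entry (i, j) = |partners_i ∩ partners_j|.

    The diagonal holds each protein's own partner-set size, so this is a
    count matrix, not a metric.
    """
    labels = table.labels()
    if len(labels) < 2:
        raise ValueError("need at least 2 labels for an overlap matrix")
    n = len(labels)
    M = np.zeros((n, n), dtype=int)
    for i, li in enumerate(labels):
        M[i, i] = len(table[li])
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = len(table[li] & table[labels[j]])
    return CountMatrix(labels=labels, M=M)


def venn_counts(table: InteractionTable, labels: list[str]) -> dict[frozenset, int]:
    """Counts of every Venn region over 2-5 selected partner sets.

    Keys are frozensets naming the labels a region belongs to (exclusively);
    the 2^k − 1 region counts sum to the size of the union.
    """
    if not 2 <= len(labels) <= 5:
        raise ValueError("venn_counts needs between 2 and 5 labels")
    for lab in labels:
        if lab not in table.partners:
            raise KeyError(f"unknown label {lab!r}")
    regions: dict[frozenset, int] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(table[l] for l in combo))
            outside = set().union(*(table[l] for l in labels if l not in combo)) if k < len(labels) else set()
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def exclusive_partner_count(table: InteractionTable) -> int:
    """Number of partner accessions reported for exactly one redoxin."""
    seen: dict[str, int] = {}
    for parts in table.partners.values():
        for p in parts:
            seen[p] = seen.get(p, 0) + 1
    return sum(1 for c in seen.values() if c == 1)
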