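"""Gene-to-category assignment tables and abundance profiles.

The input is a three-column TSV (``genome_id``, ``gene_id``, ``category_id``)
in the style of an IMG COG export: one row per gene-category hit.  Category
ids are opaque strings, so Pfam/KO tables work the same way.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Literal

__all__ = [
    "ParseError",
    "GeneAssignment",
    "AbundanceProfile",
    "RankEntry",
    "RankFrequencySeries",
    "read_assignments",
    "build_profile",
    "rank_frequencies",
]

HEADER = ("genome_id", "gene_id", "category_id")

MultiPolicy = Literal["per_pair", "first_only"]


class ParseError(ValueError):
    """Malformed assignment table."""


@dataclass(frozen=True)
class GeneAssignment:
    genome_id: str
    gene_id: str
    category_id: str


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-genome counts of items per functional category.

    ``N`` counts items (gene-category memberships or genes, depending on the
    policy used to build the profile); ``S`` counts distinct categories.
    """

    genome_id: str
    counts: dict[str, int] = field(repr=False)

    def __post_init__(self):
        if not self.counts:
            raise ValueError(f"empty profile for genome {self.genome_id!r}")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all category counts must be >= 1")

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    @property
    def S(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class RankEntry:
    rank: int
    category_id: str
    count: int
    frequency: float


@dataclass(frozen=True)
class RankFrequencySeries:
    genome_id: str
    entries: tuple[RankEntry, ...]

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["rank", "category_id", "count", "frequency"])
            for e in self.entries:
                w.writerow([e.rank, e.category_id, e.count, repr(e.frequency)])


def read_assignments(source) -> list[GeneAssignment]:
    """Parse an assignment TSV into :class:`GeneAssignment` rows.

    ``source`` may be a path or an open text handle.  Lines starting with
    ``#`` are ignored; exact duplicate triples collapse to one occurrence
    (first position kept); malformed rows raise :class:`ParseError` naming
    the 1-based line number.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, newline="") as fh:
            return read_assignments(fh)

    expected_header = "\t".join(HEADER)
    out: list[GeneAssignment] = []
    seen: set[tuple[str, str, str]] = set()
    header_seen = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != HEADER:
                raise ParseError(
                    f"line {lineno}: expected header {expected_header!r}, got {line!r}"
                )
            header_seen = True
            continue
        if len(fields) != 3:
            raise ParseError(f"line {lineno}: expected 3 tab-separated columns, got {len(fields)}")
        if any(f == "" for f in fields):
            raise ParseError(f"line {lineno}: empty field in {line!r}")
        triple = (fields[0], fields[1], fields[2])
        if triple in seen:
            continue
        seen.add(triple)
        out.append(GeneAssignment(*triple))
    if not header_seen:
        raise ParseError("line 1: missing header row")
    return out


def build_profile(
    assignments: Iterable[GeneAssignment],
    genome_id: str,
    multi_policy: MultiPolicy = "per_pair",
) -> AbundanceProfile:
    """Aggregate assignments for one genome into an abundance profile.

    ``per_pair`` (default): each distinct (gene, category) pair contributes
    one item, so a gene assigned to k categories adds k items and N counts
    gene-category memberships.  ``first_only``: only the first listed
    category of each gene counts, so N equals the number of genes.
    """
    if multi_policy not in ("per_pair", "first_only"):
        raise ValueError(f"unknown multi_policy {multi_policy!r}")
    counts: dict[str, int] = {}
    first_cat: dict[str, str] = {}
    n_rows = 0
    for a in assignments:
        if a.genome_id != genome_id:
            continue
        n_rows += 1
        if multi_policy == "per_pair":
            counts[a.category_id] = counts.get(a.category_id, 0) + 1
        else:
            if a.gene_id not in first_cat:
                first_cat[a.gene_id] = a.category_id
    if multi_policy == "first_only":
        for cat in first_cat.values():
            counts[cat] = counts.get(cat, 0) + 1
    if n_rows == 0:
        raise ValueError(f"no assignments for genome {genome_id!r}")
    return AbundanceProfile(genome_id=genome_id, counts=counts)


def rank_frequencies(profile: AbundanceProfile, top: int | None = None) -> RankFrequencySeries:
    """Frequency-sorted series: count descending, ties by category id ascending.

    ``frequency = count / N``; the series is truncated to the ``top`` most
    frequent categories when requested.
    """
    if top is not None and top < 1:
        raise ValueError(f"top must be >= 1, got {top}")
    n = profile.N
    ordered = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top is not None:
        ordered = ordered[:top]
    entries = tuple(
        RankEntry(rank=i, category_id=cat, count=c, frequency=c / n)
        for i, (cat, c) in enumerate(ordered, start=1)
    )
    return RankFrequencySeries(genome_id=profile.genome_id, entries=entries)
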