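"""Genome summary statistics: size, GC, coding fraction.

Plumbing over FASTA (+ optional GFF3) producing the usual genome-table rows:
total size, contig count, G+C content and the coding fraction from the union
of CDS intervals (overlaps counted once).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

__all__ = ["GenomeSummary", "genome_summary"]

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


@dataclass(frozen=True)
class GenomeSummary:
    size_bp: int
    contig_count: int
    gc_bp: int
    gc_percent: float  # of unambiguous (ACGT) bases
    coding_bp: int
    coding_fraction: float
    gene_count: int

    def to_dict(self) -> dict:
        return {
            "size_bp": self.size_bp,
            "contig_count": self.contig_count,
            "gc_bp": self.gc_bp,
            "gc_percent": round(self.gc_percent, 2),
            "coding_bp": self.coding_bp,
            "coding_fraction": round(self.coding_fraction, 4),
            "gene_count": self.gene_count,
        }


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    max_end = -1
    for start, end in sorted(intervals):
        if end > max_end:
            total += end - max(start, max_end)
            max_end = end
    return total


def _read_cds(gff3_path, contig_lengths: dict[str, int]) -> tuple[dict[str, list], int]:
    df = pd.read_csv(
        gff3_path,
        sep="\t",
        comment="#",
        header=None,
        names=GFF3_COLUMNS,
        dtype={"seqid": str, "type": str},
    )
    cds = df[df["type"] == "CDS"]
    per_contig: dict[str, list] = {}
    for row in cds.itertuples(index=False):
        if row.seqid not in contig_lengths:
            raise ValueError(
                f"GFF3 feature {row.type} {row.start}..{row.end} references "
                f"unknown contig {row.seqid!r}"
            )
        # GFF3 is 1-based inclusive
        per_contig.setdefault(row.seqid, []).append((int(row.start) - 1, int(row.end)))
    return per_contig, len(cds)


def _read_coords_tsv(path, contig_lengths: dict[str, int]) -> tuple[dict[str, list], int]:
    """Fallback dialect: 2 columns (start, end; 1-based inclusive) on the sole
    contig, or 3 columns (contig, start, end)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    per_contig: dict[str, list] = {}
    n = 0
    for row in df.itertuples(index=False):
        if len(row) == 2:
            if len(contig_lengths) != 1:
                raise ValueError("2-column coordinates require a single-contig FASTA")
            contig = next(iter(contig_lengths))
            start, end = int(row[0]), int(row[1])
        else:
            contig, start, end = str(row[0]), int(row[1]), int(row[2])
            if contig not in contig_lengths:
                raise ValueError(f"coordinate row references unknown contig {contig!r}")
        per_contig.setdefault(contig, []).append((start - 1, end))
        n += 1
    return per_contig, n


def genome_summary(fasta, gff3=None, coords_tsv=None) -> GenomeSummary:
    """Summary statistics for one genome FASTA, optionally with CDS features.

    GC is the percentage of G+C among unambiguous A/C/G/T bases.  Coding bp
    is the per-contig union of CDS intervals (1-based inclusive input
    coordinates), so overlapping CDS are counted once.
    """
    records = list(SeqIO.parse(fasta, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta!r}")
    contig_lengths = {r.id: len(r.seq) for r in records}
    size = sum(contig_lengths.values())
    gc = at = 0
    for r in records:
        s = str(r.seq).upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    unambiguous = gc + at

    per_contig: dict[str, list] = {}
    gene_count = 0
    if gff3 is not None:
        per_contig, gene_count = _read_cds(gff3, contig_lengths)
    elif coords_tsv is not None:
        per_contig, gene_count = _read_coords_tsv(coords_tsv, contig_lengths)
    coding = 0
    for contig, intervals in per_contig.items():
        clipped = [(max(0, s), min(e, contig_lengths[contig])) for s, e in intervals]
        coding += _union_length([iv for iv in clipped if iv[1] > iv[0]])

    return GenomeSummary(
        size_bp=size,
        contig_count=len(records),
        gc_bp=gc,
        gc_percent=100.0 * gc / unambiguous if unambiguous else 0.0,
        coding_bp=coding,
        coding_fraction=coding / size,
        gene_count=gene_count,
    )
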