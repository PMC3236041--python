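"""Genome-to-genome distance formulas over high-scoring segment pairs.

Given two nucleotide sequences, :func:`find_hsps` produces ungapped HSPs by
exact k-mer seeding and X-drop extension (+1 match / -1 mismatch), and
:func:`ggdc_formulas` turns any HSP set into the three classic
genome-to-genome ratios:

* ``f1`` — summed HSP length / total length (genome coverage),
* ``f2`` — identities / HSP length (identity within matching segments),
* ``f3`` — identities / total length (identity over the whole genome),

where *total length* is the arithmetic mean of the two genome lengths and
overlapping HSP intervals are merged (union) per genome before summing, so
``f3 = f1 * f2`` holds exactly.  These are coverage/identity similarities in
[0, 1]; they are reported as printed, without any distance transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "Hsp",
    "GgdcResult",
    "find_hsps",
    "ggdc_formulas",
    "genome_pair_distance",
    "write_hsps_tsv",
]

CONTIG_SPACER = 100  # Ns between concatenated contigs; excluded from length accounting


@dataclass(frozen=True)
class Hsp:
    """Ungapped high-scoring segment pair; 0-based half-open intervals."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identities: int

    def __post_init__(self):
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise ValueError("ungapped HSP intervals must have equal length")
        if self.identities > self.length:
            raise ValueError("identities cannot exceed HSP length")

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    @property
    def diagonal(self) -> int:
        return self.b_start - self.a_start


@dataclass(frozen=True)
class GgdcResult:
    f1: float  # HSP length / total length
    f2: float  # identities / HSP length
    f3: float  # identities / total length
    total_length: float
    hsp_length: float
    identities: float
    n_hsps: int
    empty: bool

    def to_dict(self) -> dict:
        return {
            "f1_hsp_length_over_total_length": self.f1,
            "f2_identities_over_hsp_length": self.f2,
            "f3_identities_over_total_length": self.f3,
            "f1_pct": round(100.0 * self.f1, 2),
            "f2_pct": round(100.0 * self.f2, 2),
            "f3_pct": round(100.0 * self.f3, 2),
            "total_length": self.total_length,
            "hsp_length": self.hsp_length,
            "identities": self.identities,
            "n_hsps": self.n_hsps,
            "empty": self.empty,
        }


def _extend(sa: str, sb: str, i: int, j: int, w: int, xdrop: int) -> tuple[int, int]:
    """X-drop ungapped extension of an exact seed at (i, j) of width w.

    Returns the (left_offset, right_offset) of the maximal-score extent
    relative to the seed: the HSP spans a[i-left : i+w+right].  Scoring is
    +1 match / -1 mismatch; extension stops once the running score falls
    more than ``xdrop`` below the running maximum, and the extent is trimmed
    back to the position of the maximum.
    """
    # right of the seed
    score = best = 0
    right = 0
    k = 0
    la, lb = len(sa), len(sb)
    while i + w + k < la and j + w + k < lb:
        ca, cb = sa[i + w + k], sb[j + w + k]
        score += 1 if (ca == cb and ca != "N") else -1
        k += 1
        if score > best:
            best, right = score, k
        elif best - score > xdrop:
            break
    # left of the seed
    score = best = 0
    left = 0
    k = 0
    while i - k > 0 and j - k > 0:
        ca, cb = sa[i - 1 - k], sb[j - 1 - k]
        score += 1 if (ca == cb and ca != "N") else -1
        k += 1
        if score > best:
            best, left = score, k
        elif best - score > xdrop:
            break
    return left, right


def find_hsps(
    seq_a: str,
    seq_b: str,
    word_size: int = 11,
    xdrop: int = 20,
    min_length: int = 50,
) -> list[Hsp]:
    """Seed-and-extend ungapped HSPs between two nucleotide sequences.

    Every exact shared ``word_size``-mer (A/C/G/T only; words containing N
    never seed) is extended in both directions with +1/-1 scoring under an
    X-drop of ``xdrop``; the resulting segments are deduplicated, segments
    contained in a longer segment on the same diagonal are dropped, and
    segments shorter than ``min_length`` are discarded.
    """
    if word_size < 8:
        raise ValueError(f"word_size must be >= 8 (got {word_size}): seed explosion guard")
    sa, sb = str(seq_a).upper(), str(seq_b).upper()
    w = word_size
    index: dict[str, list[int]] = {}
    for j in range(len(sb) - w + 1):
        word = sb[j : j + w]
        if "N" not in word:
            index.setdefault(word, []).append(j)

    raw: set[tuple[int, int, int]] = set()  # (a_start, b_start, length)
    for i in range(len(sa) - w + 1):
        word = sa[i : i + w]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            left, right = _extend(sa, sb, i, j, w, xdrop)
            a_start, a_end = i - left, i + w + right
            raw.add((a_start, j - left, a_end - a_start))

    # collapse containment per diagonal, then filter by length
    by_diag: dict[int, list[tuple[int, int, int]]] = {}
    for a_start, b_start, length in raw:
        by_diag.setdefault(b_start - a_start, []).append((a_start, b_start, length))
    hsps: list[Hsp] = []
    for diag, items in by_diag.items():
        items.sort(key=lambda t: (t[0], -t[2]))
        kept: list[tuple[int, int, int]] = []
        max_end = -1
        for a_start, b_start, length in items:
            if a_start + length <= max_end:
                continue  # contained in a previously kept segment
            kept.append((a_start, b_start, length))
            max_end = a_start + length
        for a_start, b_start, length in kept:
            if length < min_length:
                continue
            ident = sum(
                1
                for k in range(length)
                if sa[a_start + k] == sb[b_start + k] and sa[a_start + k] != "N"
            )
            hsps.append(
                Hsp(
                    a_start=a_start,
                    a_end=a_start + length,
                    b_start=b_start,
                    b_end=b_start + length,
                    identities=ident,
                )
            )
    hsps.sort(key=lambda h: (h.a_start, h.b_start))
    return hsps


def _merged_coverage(intervals: list[tuple[int, int, int]]) -> tuple[int, float]:
    """Union length and identity mass of (start, end, identities) intervals.

    Where intervals overlap, the later interval contributes identities only
    for its novel columns, scaled by its own identity fraction (overlap
    columns are already accounted for by the earlier interval).
    """
    covered = 0
    ident = 0.0
    max_end = -1
    for start, end, identities in sorted(intervals):
        length = end - start
        novel_start = max(start, max_end)
        novel = max(0, end - novel_start)
        if novel > 0:
            covered += novel
            ident += identities * (novel / length)
            max_end = end
    return covered, ident


def ggdc_formulas(hsps, len_a: int, len_b: int) -> GgdcResult:
    """The three coverage/identity ratios for an HSP set.

    Overlapping HSP intervals are merged per genome; the summed HSP length
    (and identity mass) is the average of the two genomes' union lengths.
    An empty HSP set yields f1 = f2 = f3 = 0 with the ``empty`` flag set.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("genome lengths must be positive")
    hsps = list(hsps)
    total_length = (len_a + len_b) / 2.0
    if not hsps:
        return GgdcResult(0.0, 0.0, 0.0, total_length, 0.0, 0.0, 0, True)
    cov_a, id_a = _merged_coverage([(h.a_start, h.a_end, h.identities) for h in hsps])
    cov_b, id_b = _merged_coverage([(h.b_start, h.b_end, h.identities) for h in hsps])
    hsp_length = (cov_a + cov_b) / 2.0
    identities = (id_a + id_b) / 2.0
    f1 = hsp_length / total_length
    f2 = identities / hsp_length
    f3 = identities / total_length
    return GgdcResult(f1, f2, f3, total_length, hsp_length, identities, len(hsps), False)


def _read_concatenated(source) -> tuple[str, int]:
    """Concatenate a (multi-)FASTA's contigs with N spacers.

    Returns the search sequence and the genome length *excluding* spacers.
    The spacer (100 Ns) can never seed or sit inside an HSP, so coverage is
    unaffected by concatenation.
    """
    if hasattr(source, "seq"):  # a single SeqRecord
        s = str(source.seq).upper()
        return s, len(s)
    if isinstance(source, str) and "\n" not in source and set(source.upper()) <= set("ACGTN"):
        return source.upper(), len(source)  # a raw sequence string
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {source!r}")
    seqs = [str(r.seq).upper() for r in records]
    joined = ("N" * CONTIG_SPACER).join(seqs)
    return joined, sum(len(s) for s in seqs)


def genome_pair_distance(
    fasta_a,
    fasta_b,
    word_size: int = 11,
    xdrop: int = 20,
    min_length: int = 50,
    both_strands: bool = False,
) -> tuple[GgdcResult, list[Hsp]]:
    """End-to-end: read two genomes, find HSPs, apply the three formulas.

    With ``both_strands`` the reverse complement of B is also searched and
    the HSP sets are pooled (reverse-strand HSP coordinates reported on the
    reverse-complemented B).
    """
    sa, len_a = _read_concatenated(fasta_a)
    sb, len_b = _read_concatenated(fasta_b)
    hsps = find_hsps(sa, sb, word_size=word_size, xdrop=xdrop, min_length=min_length)
    if both_strands:
        hsps += find_hsps(
            sa, reverse_complement(sb), word_size=word_size, xdrop=xdrop, min_length=min_length
        )
    return ggdc_formulas(hsps, len_a, len_b), hsps


def write_hsps_tsv(hsps, path) -> None:
    with open(path, "w") as fh:
        fh.write("a_start\ta_end\tb_start\tb_end\tlength\tidentities\n")
        for h in hsps:
            fh.write(f"{h.a_start}\t{h.a_end}\t{h.b_start}\t{h.b_end}\t{h.length}\t{h.identities}\n")
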