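"""Pairwise protein homology and three-way shared-gene (Venn) partitioning.

A desk-scale stand-in for an all-vs-all BLASTP screen: exact Smith-Waterman
local alignment (Biopython's ``PairwiseAligner`` with BLOSUM62 and affine
gaps) scored into BLAST-like E-values via the Karlin-Altschul formula
``E = K * m * n * exp(-lambda * S_raw)`` with fixed published gapped-BLOSUM62
constants.  A gene in genome X counts as having a homolog in genome Y when
at least one of its local alignments against Y passes *both* thresholds:
E-value at most ``max_evalue`` and percent identity at least
``min_identity_pct`` (identity over all alignment columns, gap columns
included, as BLAST reports it).

The Venn partitioning is gene-level and directional: each gene of each
genome is classified by which of the other genomes contain a homolog of it.
Homology is not transitive, so region counts are reported per genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "VALID_RESIDUES",
    "HomologyParams",
    "HomologyHit",
    "VennPartition",
    "read_proteome",
    "local_align",
    "search_hits",
    "homologs",
    "venn3",
    "write_hits_tsv",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class HomologyParams:
    """Thresholds and scoring for homolog detection.

    ``karlin_lambda``/``karlin_k`` are the published gapped BLOSUM62
    (open 11 / extend 1) constants.  ``search_space_policy``:
    ``pairwise_product`` uses m*n = query length * subject length per pair;
    ``effective`` uses m * (summed length of the subject proteome), the
    database-style search space.
    """

    max_evalue: float = 1e-5
    min_identity_pct: float = 30.0
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    search_space_policy: str = "pairwise_product"

    def __post_init__(self):
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if not 0 < self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in (0, 100]")
        if self.search_space_policy not in ("pairwise_product", "effective"):
            raise ValueError(f"unknown search_space_policy {self.search_space_policy!r}")

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        # affine: a gap of length g costs gap_open + gap_extend * g
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    length: int  # alignment columns, gap columns included
    identities: int
    identity_pct: float
    mismatches: int
    gap_opens: int
    q_start: int  # 1-based inclusive, BLAST outfmt-6 style
    q_end: int
    s_start: int
    s_end: int
    raw_score: float
    bit_score: float
    evalue: float

    def passes(self, params: HomologyParams) -> bool:
        return self.evalue <= params.max_evalue and self.identity_pct >= params.min_identity_pct


@dataclass(frozen=True)
class VennPartition:
    """Per-genome counts over the regions of a three-set Venn diagram.

    ``regions[g]`` maps a sorted '&'-joined genome-set label (e.g. ``"A"``,
    ``"A&B"``, ``"A&B&C"``) to the number of genes of ``g`` whose homolog
    support is exactly that set of genomes.
    """

    genome_names: tuple[str, ...]
    totals: dict[str, int]
    regions: dict[str, dict[str, int]]

    def shared_by_all(self, genome: str) -> int:
        label = "&".join(sorted(self.genome_names))
        return self.regions[genome].get(label, 0)

    def to_dict(self) -> dict:
        return {
            "genome_names": list(self.genome_names),
            "totals": dict(self.totals),
            "regions": {g: dict(r) for g, r in self.regions.items()},
        }


def read_proteome(source) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping."""
    records = SeqIO.parse(source, "fasta")
    out = {}
    for rec in records:
        out[rec.id] = str(rec.seq).upper()
    return out


def _as_dict(proteome) -> dict[str, str]:
    if isinstance(proteome, dict):
        return {k: str(v).upper() for k, v in proteome.items()}
    if isinstance(proteome, (str, bytes)) or hasattr(proteome, "__fspath__"):
        return read_proteome(proteome)
    # list of SeqRecords
    return {rec.id: str(rec.seq).upper() for rec in proteome}


def _validate(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise ValueError(f"{label}: invalid residue {ch!r} at position {pos}")


def local_align(
    seq_a: str,
    seq_b: str,
    params: HomologyParams | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_space: int | None = None,
    aligner: PairwiseAligner | None = None,
) -> HomologyHit | None:
    """Best Smith-Waterman local alignment between two protein sequences.

    Returns ``None`` when no alignment scores above zero (the empty local
    alignment wins).  ``subject_space`` overrides the n of the Karlin-
    Altschul search space m*n (used for database-style E-values).
    """
    params = params or HomologyParams()
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    _validate(seq_a, f"sequence {query_id!r}")
    _validate(seq_b, f"sequence {subject_id!r}")
    if aligner is None:
        aligner = params.make_aligner()
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(seq_a, seq_b)))
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    identities = counts.identities
    blocks_q = aln.aligned[0]
    blocks_s = aln.aligned[1]
    # each junction between aligned blocks is one gap opening
    gap_opens = len(blocks_q) - 1
    n = subject_space if subject_space is not None else len(seq_b)
    evalue = params.karlin_k * len(seq_a) * n * math.exp(-params.karlin_lambda * score)
    bits = (params.karlin_lambda * score - math.log(params.karlin_k)) / math.log(2)
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        length=int(length),
        identities=int(identities),
        identity_pct=100.0 * identities / length,
        mismatches=int(counts.mismatches),
        gap_opens=int(gap_opens),
        q_start=int(blocks_q[0][0]) + 1,
        q_end=int(blocks_q[-1][1]),
        s_start=int(blocks_s[0][0]) + 1,
        s_end=int(blocks_s[-1][1]),
        raw_score=float(score),
        bit_score=bits,
        evalue=evalue,
    )


def search_hits(proteome_a, proteome_b, params: HomologyParams | None = None) -> list[HomologyHit]:
    """All-vs-all local alignments of A queries against B subjects.

    Returns every hit that passes both thresholds, ordered by query then
    ascending E-value.
    """
    params = params or HomologyParams()
    pa, pb = _as_dict(proteome_a), _as_dict(proteome_b)
    if not pa or not pb:
        raise ValueError("empty proteome")
    aligner = params.make_aligner()
    space = sum(len(s) for s in pb.values()) if params.search_space_policy == "effective" else None
    hits: list[HomologyHit] = []
    for qid, qseq in pa.items():
        per_q = []
        for sid, sseq in pb.items():
            hit = local_align(
                qseq,
                sseq,
                params,
                query_id=qid,
                subject_id=sid,
                subject_space=space,
                aligner=aligner,
            )
            if hit is not None and hit.passes(params):
                per_q.append(hit)
        per_q.sort(key=lambda h: (h.evalue, h.subject_id))
        hits.extend(per_q)
    return hits


def homologs(proteome_a, proteome_b, params: HomologyParams | None = None) -> set[str]:
    """Gene ids of A with at least one hit in B passing both thresholds."""
    return {hit.query_id for hit in search_hits(proteome_a, proteome_b, params)}


def venn3(proteome_a, proteome_b, proteome_c, params: HomologyParams | None = None,
          genome_names: tuple[str, str, str] = ("A", "B", "C")) -> VennPartition:
    """Three-genome gene-level Venn partition.

    For each genome, every gene is classified by which of the other two
    genomes contain a homolog of it; the four per-genome region counts
    (unique; shared with one other; shared with the other; shared with both)
    always sum to the genome's gene count.
    """
    params = params or HomologyParams()
    proteomes = dict(zip(genome_names, map(_as_dict, (proteome_a, proteome_b, proteome_c))))
    support: dict[str, dict[str, set[str]]] = {g: {} for g in genome_names}
    for g, h in combinations(genome_names, 2):
        for query, subject in ((g, h), (h, g)):
            found = homologs(proteomes[query], proteomes[subject], params)
            for gid in found:
                support[query].setdefault(gid, set()).add(subject)
    regions: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for g in genome_names:
        totals[g] = len(proteomes[g])
        counts: dict[str, int] = {}
        for gid in proteomes[g]:
            label = "&".join(sorted({g} | support[g].get(gid, set())))
            counts[label] = counts.get(label, 0) + 1
        regions[g] = counts
    return VennPartition(genome_names=tuple(genome_names), totals=totals, regions=regions)


def write_hits_tsv(hits, path) -> None:
    """BLAST outfmt-6-like 12-column table."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        str(h.length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.2e}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
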