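"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* :func:`simulate_cog_table` — gene-to-category assignment tables whose
  category-count distribution follows a chosen model (uniform, broken-stick,
  geometric, Dirichlet-multinomial, or a Dirichlet baseline plus a designated
  heavy "mobile element"-style burst family absorbing a stated mass fraction).
* :func:`simulate_proteomes` — two or three proteomes with planted homolog
  families (core, pairwise, unique) at a controlled within-family identity.
* :func:`simulate_genome_pair` — two nucleotide sequences with planted shared
  segments of controlled length and identity on independent random
  backgrounds at a stated GC content.

Each generator returns its outputs together with a :class:`SimTruth` manifest
(true counts, family memberships, planted 0-based half-open coordinates)
sufficient to score any downstream inference exactly.  Same seed, same
config: byte-identical output.

Substitutions always replace a position with a uniformly chosen *different*
symbol, so a substitution rate r gives identity 1 - r exactly in expectation.
No indels, no strand flips, no codon structure.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ConfigError",
    "CogSimConfig",
    "ProteomeSimConfig",
    "GenomePairSimConfig",
    "SimTruth",
    "simulate_cog_table",
    "simulate_proteomes",
    "simulate_genome_pair",
    "write_assignments_tsv",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"
DEFAULT_SEED = 42

COG_MODELS = ("uniform", "brokenstick", "geometric", "dirichlet", "transposon_burst")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CogSimConfig:
    """Category-count table simulation.

    ``model_params`` by model: geometric -> ``ratio`` in (0,1);
    dirichlet -> ``alpha`` > 0; transposon_burst -> ``n_burst`` (int >= 1),
    ``burst_mass`` in (0,1) and optional ``alpha`` for the baseline.
    """

    n_genes: int
    n_categories: int
    model: str = "brokenstick"
    model_params: dict = field(default_factory=dict)
    genome_id: str = "SIM"
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n_genes < 1 or self.n_categories < 1:
            raise ConfigError("n_genes and n_categories must be positive")
        if self.n_categories > self.n_genes:
            raise ConfigError(
                f"n_categories ({self.n_categories}) cannot exceed n_genes ({self.n_genes})"
            )
        if self.model not in COG_MODELS:
            raise ConfigError(f"unknown model {self.model!r}; choose from {COG_MODELS}")
        p = self.model_params
        if self.model == "geometric":
            k = p.get("ratio", 0.95)
            if not 0 < k < 1:
                raise ConfigError("geometric ratio must be in (0, 1)")
        if self.model == "dirichlet" and p.get("alpha", 1.0) <= 0:
            raise ConfigError("dirichlet alpha must be > 0")
        if self.model == "transposon_burst":
            if not 0 < p.get("burst_mass", 0.3) < 1:
                raise ConfigError("burst_mass must be in (0, 1)")
            if p.get("n_burst", 1) < 1:
                raise ConfigError("n_burst must be >= 1")


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Proteome-triple (or pair) simulation with planted homolog families.

    ``within_family_identity`` is the expected *pairwise* identity between any
    two members of a family.  ``n_pairwise_families`` maps a genome pair (a
    ``"A-B"`` string or 2-tuple) to a family count; ``n_unique`` maps a genome
    to its count of unrelated singleton genes.
    """

    n_genomes: int = 3
    n_core_families: int = 5
    n_pairwise_families: dict = field(default_factory=dict)
    n_unique: dict = field(default_factory=dict)
    protein_length: int = 120
    within_family_identity: float = 0.9
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n_genomes not in (2, 3):
            raise ConfigError("n_genomes must be 2 or 3")
        if not 0 < self.within_family_identity <= 1:
            raise ConfigError("within_family_identity must be in (0, 1]")
        if self.within_family_identity < 0.1:
            raise ConfigError("within_family_identity below 0.1 is not resolvable")
        if self.protein_length < 30:
            raise ConfigError("protein_length must be >= 30")
        names = self.genome_names
        for pair in self.n_pairwise_families:
            if not set(_pair_key(pair)) <= set(names):
                raise ConfigError(f"unknown genome pair {pair!r}")
        for g in self.n_unique:
            if g not in names:
                raise ConfigError(f"unknown genome {g!r} in n_unique")

    @property
    def genome_names(self) -> tuple[str, ...]:
        return ("A", "B", "C")[: self.n_genomes]


@dataclass(frozen=True)
class GenomePairSimConfig:
    """Two random genomes with shared segments planted from A into B."""

    len_a: int
    len_b: int
    planted_segments: tuple = ()
    gc: float = 0.5
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.len_a < 1 or self.len_b < 1:
            raise ConfigError("genome lengths must be positive")
        if not 0 < self.gc < 1:
            raise ConfigError("gc must be in (0, 1)")
        total = 0
        for length, identity in self.planted_segments:
            if length < 1:
                raise ConfigError("planted segment length must be positive")
            if not 0 < identity <= 1:
                raise ConfigError("planted identity must be in (0, 1]")
            total += length
        if total > min(self.len_a, self.len_b):
            raise ConfigError(
                "sum of planted segment lengths exceeds the shorter genome"
            )


@dataclass
class SimTruth:
    """Ground-truth manifest for one simulation run."""

    kind: str
    config: dict
    category_counts: dict | None = None
    families: dict | None = None  # family_id -> [[genome, gene_id], ...]
    segments: list | None = None  # [{a_start, a_end, b_start, b_end, identity}, ...]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# category-count tables

def _model_proportions(cfg: CogSimConfig, rng: np.random.Generator):
    """Per-category probabilities (burst categories are the first n_burst)."""
    S = cfg.n_categories
    p = cfg.model_params
    if cfg.model == "brokenstick":
        from .redundancy import broken_stick

        return np.array(broken_stick(S).proportions), []
    if cfg.model == "geometric":
        k = p.get("ratio", 0.95)
        w = k ** np.arange(S)
        return w / w.sum(), []
    if cfg.model == "dirichlet":
        alpha = p.get("alpha", 1.0)
        return rng.dirichlet(np.full(S, alpha)), []
    if cfg.model == "transposon_burst":
        n_burst = int(p.get("n_burst", 1))
        mass = float(p.get("burst_mass", 0.3))
        alpha = p.get("alpha", 1.0)
        if n_burst >= S:
            raise ConfigError("n_burst must be smaller than n_categories")
        base = rng.dirichlet(np.full(S - n_burst, alpha)) * (1.0 - mass)
        burst = np.full(n_burst, mass / n_burst)
        return np.concatenate([burst, base]), list(range(n_burst))
    raise AssertionError(cfg.model)


def simulate_cog_table(cfg: CogSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw an assignment table whose category counts follow ``cfg.model``.

    Returns the table as a DataFrame with columns
    (genome_id, gene_id, category_id) — one row per gene — and the truth
    manifest holding the drawn per-category counts (zeros included).
    """
    rng = np.random.default_rng(cfg.seed)
    S, G = cfg.n_categories, cfg.n_genes
    width = len(str(S - 1))
    cats = [f"CAT{i:0{width}d}" for i in range(S)]

    if cfg.model == "uniform":
        # one gene per category, repeated round-robin
        counts = np.array([(G - i - 1) // S + 1 for i in range(S)], dtype=int)
        burst_ids = []
    else:
        props, burst_idx = _model_proportions(cfg, rng)
        counts = rng.multinomial(G, props)
        burst_ids = [cats[i] for i in burst_idx]

    gene_cat = np.repeat(np.arange(S), counts)
    gwidth = len(str(G - 1))
    rows = {
        "genome_id": cfg.genome_id,
        "gene_id": [f"{cfg.genome_id}_g{i:0{gwidth}d}" for i in range(G)],
        "category_id": [cats[c] for c in gene_cat],
    }
    table = pd.DataFrame(rows)
    truth = SimTruth(
        kind="cog_table",
        config=dataclasses.asdict(cfg),
        category_counts={c: int(n) for c, n in zip(cats, counts)},
    )
    if burst_ids:
        truth.config["burst_category_ids"] = burst_ids
    return table, truth


# ---------------------------------------------------------------------------
# proteomes with planted families

def _pair_key(pair) -> tuple[str, str]:
    if isinstance(pair, str):
        parts = tuple(pair.split("-"))
    else:
        parts = tuple(pair)
    if len(parts) != 2 or parts[0] == parts[1]:
        raise ConfigError(f"invalid genome pair {pair!r}")
    return tuple(sorted(parts))


def _substitution_rate(pairwise_identity: float, n_symbols: int) -> float:
    """Per-member rate r so that two members' expected identity hits the target.

    Both members mutate independently from the ancestor; positions match if
    neither mutated, or both mutated to the same of the n-1 alternatives:
    (1-r)^2 + r^2/(n-1) = identity.
    """
    if pairwise_identity >= 1.0:
        return 0.0
    m = n_symbols - 1
    a = 1.0 + 1.0 / m
    # a*r^2 - 2r + (1 - identity) = 0, smaller root
    disc = 4.0 - 4.0 * a * (1.0 - pairwise_identity)
    if disc < 0:
        raise ConfigError("within_family_identity too low for the alphabet")
    return (2.0 - math.sqrt(disc)) / (2.0 * a)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator, n_symbols: int) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    # add 1..n-1 mod n: always a different symbol
    out[hit] = (out[hit] + rng.integers(1, n_symbols, size=int(hit.sum()))) % n_symbols
    return out


def simulate_proteomes(cfg: ProteomeSimConfig) -> tuple[dict[str, list[SeqRecord]], SimTruth]:
    """Generate proteomes with planted core / pairwise / unique families.

    Each family descends from one random ancestral sequence; every member is
    an independently mutated copy, tuned so that the expected pairwise
    identity between members equals ``cfg.within_family_identity``.  Unique
    genes are fresh random sequences with no family label in the truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n_sym = len(AMINO_ACIDS)
    rate = _substitution_rate(cfg.within_family_identity, n_sym)
    names = cfg.genome_names

    proteomes: dict[str, list[SeqRecord]] = {g: [] for g in names}
    families: dict[str, list[list[str]]] = {}
    counters = {g: 0 for g in names}

    def new_seq() -> np.ndarray:
        return rng.integers(0, n_sym, size=cfg.protein_length)

    def add_gene(genome: str, seq: np.ndarray, family: str | None) -> str:
        gid = f"{genome}_p{counters[genome]:04d}"
        counters[genome] += 1
        aa = "".join(AMINO_ACIDS[i] for i in seq)
        desc = f"family={family}" if family else "unique"
        proteomes[genome].append(SeqRecord(Seq(aa), id=gid, description=desc))
        if family is not None:
            families.setdefault(family, []).append([genome, gid])
        return gid

    def plant_family(fid: str, members: tuple[str, ...]) -> None:
        ancestor = new_seq()
        for genome in members:
            add_gene(genome, _mutate(ancestor, rate, rng, n_sym), fid)

    for i in range(cfg.n_core_families):
        plant_family(f"core{i:03d}", names)
    for pair, count in sorted(cfg.n_pairwise_families.items(), key=lambda kv: _pair_key(kv[0])):
        g1, g2 = _pair_key(pair)
        for i in range(count):
            plant_family(f"pair_{g1}{g2}_{i:03d}", (g1, g2))
    for genome in names:
        for _ in range(cfg.n_unique.get(genome, 0)):
            add_gene(genome, new_seq(), None)

    truth = SimTruth(kind="proteomes", config=dataclasses.asdict(cfg), families=families)
    return proteomes, truth


# ---------------------------------------------------------------------------
# genome pairs with planted shared segments

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    # symbol order A, C, G, T
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _place_intervals(rng: np.random.Generator, seq_len: int, lengths: list[int]) -> list[int]:
    """Random non-overlapping starts for the given interval lengths."""
    for _ in range(1000):
        # rejection sampling over joint placements
        cand = [int(rng.integers(0, seq_len - L + 1)) for L in lengths]
        ivs = sorted(zip(cand, lengths))
        if all(ivs[i][0] + ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1)):
            return cand
    raise ConfigError("could not place planted segments without overlap")


def simulate_genome_pair(cfg: GenomePairSimConfig) -> tuple[tuple[SeqRecord, SeqRecord], SimTruth]:
    """Two random backgrounds with shared segments copied from A into B.

    Each planted segment is taken from a random non-overlapping window of A,
    substituted down to the stated identity, and written into a random
    non-overlapping window of B (forward strand).  Truth records both
    0-based half-open intervals and the target identity.
    """
    rng = np.random.default_rng(cfg.seed)
    a = _random_dna(rng, cfg.len_a, cfg.gc)
    b = _random_dna(rng, cfg.len_b, cfg.gc)

    lengths = [int(L) for L, _ in cfg.planted_segments]
    segments: list[dict] = []
    if lengths:
        starts_a = _place_intervals(rng, cfg.len_a, lengths)
        starts_b = _place_intervals(rng, cfg.len_b, lengths)
        for (length, identity), sa, sb in zip(cfg.planted_segments, starts_a, starts_b):
            copy = _mutate(a[sa : sa + length], 1.0 - identity, rng, 4)
            b[sb : sb + length] = copy
            segments.append(
                {
                    "a_start": int(sa),
                    "a_end": int(sa + length),
                    "b_start": int(sb),
                    "b_end": int(sb + length),
                    "identity": float(identity),
                }
            )

    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["planted_segments"] = [list(s) for s in cfg.planted_segments]
    truth = SimTruth(kind="genome_pair", config=cfg_dict, segments=segments)
    rec_a = SeqRecord(Seq("".join(NUCLEOTIDES[i] for i in a)), id="genomeA", description="")
    rec_b = SeqRecord(Seq("".join(NUCLEOTIDES[i] for i in b)), id="genomeB", description="")
    return (rec_a, rec_b), truth


# ---------------------------------------------------------------------------
# writers

def write_assignments_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_fasta(records, path) -> None:
    """FASTA wrapped at 60 columns (Biopython's default line width)."""
    from Bio import SeqIO

    SeqIO.write(list(records), path, "fasta")
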