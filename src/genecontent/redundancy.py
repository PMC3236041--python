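"""Entropy and broken-stick statistics for gene-content redundancy.

A genome's gene-to-functional-category assignment (e.g. genes to COGs) is an
abundance distribution: ``N`` items over ``S`` categories.  Its Shannon entropy
``H`` measures evenness; comparing ``H`` against two reference entropies gives
two redundancy indices:

* ``H_max = ln N`` — entropy of the maximally even case in which every
  category holds exactly one gene.  ``1 - H/H_max`` is redundancy against the
  maximum.
* ``H_exp`` — entropy of the broken-stick expectation for ``S`` categories,
  the null in which a unit interval is broken at ``S - 1`` uniform random
  points.  ``1 - H/H_exp`` is redundancy against chance and goes negative when
  the observed distribution is *more* even than a random broken stick.

A category is called over-represented when its observed relative frequency,
at its rank in the frequency-sorted list, strictly exceeds the broken-stick
expectation for that rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .profiles import AbundanceProfile, rank_frequencies

__all__ = [
    "BrokenStickExpectation",
    "OverrepresentedCall",
    "RedundancyReport",
    "shannon_entropy",
    "h_max",
    "broken_stick",
    "h_exp",
    "redundancy_indices",
    "over_represented",
    "redundancy_report",
    "overlay_table",
]


@dataclass(frozen=True)
class BrokenStickExpectation:
    """Expected rank-ordered relative abundances for ``S`` categories.

    ``proportions[i-1] = (1/S) * sum_{k=i..S} 1/k`` — strictly decreasing and
    summing to one.
    """

    S: int
    proportions: np.ndarray = field(repr=False)

    def entropy(self) -> float:
        """Shannon entropy (nats) of the expected distribution."""
        return float(_scipy_entropy(self.proportions))


@dataclass(frozen=True)
class OverrepresentedCall:
    rank: int
    category_id: str
    observed: float
    expected: float


@dataclass(frozen=True)
class RedundancyReport:
    genome_id: str
    N: int
    S: int
    H: float
    H_max: float
    H_exp: float
    evenness: float
    redundancy_max: float
    redundancy_exp: float
    overrepresented: tuple[OverrepresentedCall, ...]

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "N": self.N,
            "S": self.S,
            "H": self.H,
            "H_max": self.H_max,
            "H_exp": self.H_exp,
            "evenness": self.evenness,
            "redundancy_max": self.redundancy_max,
            "redundancy_exp": self.redundancy_exp,
            "redundancy_max_pct": round(100.0 * self.redundancy_max, 2),
            "redundancy_exp_pct": round(100.0 * self.redundancy_exp, 2),
            "n_overrepresented": len(self.overrepresented),
            "overrepresented": [
                {
                    "rank": c.rank,
                    "category_id": c.category_id,
                    "observed": c.observed,
                    "expected": c.expected,
                }
                for c in self.overrepresented
            ],
        }


def shannon_entropy(counts) -> float:
    """Shannon entropy ``-sum (c/N) ln (c/N)`` in nats.

    Parameters
    ----------
    counts : sequence of positive numbers
        Category counts; order is irrelevant.
    """
    arr = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts, dtype=float)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(arr < 1):
        raise ValueError("all counts must be >= 1")
    return float(_scipy_entropy(arr))


def h_max(n_items: int) -> float:
    """``ln N`` — entropy if every one of the N items founded its own category."""
    if n_items < 1:
        raise ValueError(f"N must be >= 1, got {n_items}")
    return math.log(n_items)


def broken_stick(S: int) -> BrokenStickExpectation:
    """Broken-stick expected proportions for ``S`` categories."""
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    inv = 1.0 / np.arange(1, S + 1)
    # p_i = (1/S) * sum_{k=i..S} 1/k  -> reversed cumulative sum of 1/k
    tail = np.cumsum(inv[::-1])[::-1]
    props = tail / S
    props.setflags(write=False)
    return BrokenStickExpectation(S=S, proportions=props)


def h_exp(S: int) -> float:
    """Entropy (nats) of the exact broken-stick expectation for ``S`` categories.

    Computed from the summed proportions, not the large-``S`` asymptotic
    ``ln S - (1 - gamma)`` (the two agree to ~1/S).
    """
    return broken_stick(S).entropy()


def redundancy_indices(H: float, N: int, S: int) -> dict:
    """Evenness and both redundancy indices from an observed entropy.

    Returns a dict with ``H_max``, ``H_exp``, ``evenness`` (= H/H_max),
    ``redundancy_max`` (= 1 - H/H_max) and ``redundancy_exp`` (= 1 - H/H_exp),
    all as fractions.
    """
    if S > N:
        raise ValueError(f"S ({S}) cannot exceed N ({N})")
    hm = h_max(N)
    he = h_exp(S)
    evenness = H / hm if hm > 0 else 1.0
    return {
        "H": H,
        "H_max": hm,
        "H_exp": he,
        "evenness": evenness,
        "redundancy_max": 1.0 - evenness,
        "redundancy_exp": 1.0 - H / he if he > 0 else 0.0,
    }


def over_represented(profile: AbundanceProfile) -> list[OverrepresentedCall]:
    """Categories whose observed frequency strictly exceeds the broken-stick
    expectation at their own rank.

    Ranks come from the full frequency-sorted list (count descending, ties by
    category id ascending); the comparison is rank-positional, mirroring the
    observed-vs-expected curve overlay of a rank-abundance plot.  Ties with
    the expectation are not flagged.
    """
    series = rank_frequencies(profile)
    expected = broken_stick(profile.S).proportions
    calls = []
    for entry, exp_freq in zip(series.entries, expected):
        if entry.frequency > exp_freq:
            calls.append(
                OverrepresentedCall(
                    rank=entry.rank,
                    category_id=entry.category_id,
                    observed=entry.frequency,
                    expected=float(exp_freq),
                )
            )
    return calls


def redundancy_report(profile: AbundanceProfile) -> RedundancyReport:
    """Full redundancy report for one genome's category-abundance profile."""
    counts = np.fromiter(profile.counts.values(), dtype=float, count=profile.S)
    H = shannon_entropy(counts)
    idx = redundancy_indices(H, profile.N, profile.S)
    return RedundancyReport(
        genome_id=profile.genome_id,
        N=profile.N,
        S=profile.S,
        H=H,
        H_max=idx["H_max"],
        H_exp=idx["H_exp"],
        evenness=idx["evenness"],
        redundancy_max=idx["redundancy_max"],
        redundancy_exp=idx["redundancy_exp"],
        overrepresented=tuple(over_represented(profile)),
    )


def overlay_table(profile: AbundanceProfile, top: int | None = None):
    """Rank / category / observed / expected / flagged table.

    Plot-ready data for a rank-abundance curve with the broken-stick overlay
    (observed frequencies as one line, expectations as the other, flags where
    observed strictly exceeds expected).  Returns a pandas DataFrame.
    """
    import pandas as pd

    series = rank_frequencies(profile)
    expected = broken_stick(profile.S).proportions
    rows = [
        {
            "rank": e.rank,
            "category_id": e.category_id,
            "count": e.count,
            "observed": e.frequency,
            "expected": float(x),
            "overrepresented": e.frequency > x,
        }
        for e, x in zip(series.entries, expected)
    ]
    df = pd.DataFrame(rows)
    if top is not None:
        if top < 1:
            raise ValueError("top must be >= 1")
        df = df.head(top)
    return df
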