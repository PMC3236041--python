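import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genecontent import (
    CogSimConfig,
    broken_stick,
    build_profile,
    h_exp,
    h_max,
    over_represented,
    overlay_table,
    redundancy_indices,
    redundancy_report,
    shannon_entropy,
    simulate_cog_table,
)
from genecontent.profiles import AbundanceProfile, GeneAssignment

from oracles import brute_broken_stick, brute_entropy, brute_overrepresented

EULER_GAMMA = 0.5772156649015329


def profile_from_counts(counts: dict[str, int]) -> AbundanceProfile:
    return AbundanceProfile(genome_id="G", counts=dict(counts))


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1, 1, 1], math.log(4)),
            ([4], 0.0),
            ([10, 3, 2, 1], brute_entropy([10, 3, 2, 1])),
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon_entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_rejects_empty_and_fractional(self):
        with pytest.raises(ValueError):
            shannon_entropy([])
        with pytest.raises(ValueError):
            shannon_entropy([0.5, 2])

    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1, max_size=50))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_brute_force(self, counts):
        assert shannon_entropy(counts) == pytest.approx(brute_entropy(counts), abs=1e-10)

    @given(st.lists(st.integers(min_value=1, max_value=100), min_size=2, max_size=20))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_merging_categories_never_increases_entropy(self, counts):
        merged = [counts[0] + counts[1]] + counts[2:]
        assert shannon_entropy(merged) <= shannon_entropy(counts) + 1e-12


class TestHMax:
    def test_boundaries(self):
        assert h_max(1) == 0.0
        assert h_max(2022) == pytest.approx(math.log(2022))
        with pytest.raises(ValueError):
            h_max(0)

    def test_consistency_with_printed_redundancies(self):
        # ln N as the evenness denominator is what reproduces the published
        # redundancy percentages from the published entropies
        assert 100 * (1 - 6.912 / h_max(2022)) == pytest.approx(9.20, abs=0.05)
        assert 100 * (1 - 6.455 / h_max(6654)) == pytest.approx(26.67, abs=0.05)


class TestBrokenStick:
    @pytest.mark.parametrize(
        "S,expected",
        [
            (1, [1.0]),
            (2, [0.75, 0.25]),
            (4, [25 / 48, 13 / 48, 7 / 48, 3 / 48]),
        ],
    )
    def test_small_cases(self, S, expected):
        assert broken_stick(S).proportions == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("S", [3, 10, 57])
    def test_matches_definition(self, S):
        assert broken_stick(S).proportions == pytest.approx(
            brute_broken_stick(S), abs=1e-12
        )

    @pytest.mark.parametrize("S", [2, 100, 10_000, 100_000])
    def test_sums_to_one_strictly_decreasing(self, S):
        p = broken_stick(S).proportions
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(np.diff(p) < 0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            broken_stick(0)


class TestHExp:
    def test_degenerate(self):
        assert h_exp(1) == 0.0

    @pytest.mark.parametrize("S,expected", [(1300, 6.748), (1383, 6.810), (1731, 7.034)])
    def test_published_expected_entropies(self, S, expected):
        assert h_exp(S) == pytest.approx(expected, abs=0.005)

    def test_below_ln_s_and_tracks_asymptotic(self):
        # the exact broken-stick entropy exceeds the asymptote ln S - (1 - gamma)
        # by ~1.2/S (0.0118 at S=100, 1.0e-3 at S=1000), vanishing with S
        prev = None
        for S in (100, 1000, 10_000):
            he = h_exp(S)
            assert he < math.log(S)
            gap = abs(he - (math.log(S) - (1 - EULER_GAMMA)))
            assert gap < 1.5 / S
            if prev is not None:
                assert gap < prev
            prev = gap


class TestRedundancyIndices:
    def test_one_gene_per_category_is_nonredundant(self):
        prof = profile_from_counts({f"C{i}": 1 for i in range(100)})
        rep = redundancy_report(prof)
        assert rep.H == pytest.approx(math.log(100))
        assert rep.redundancy_max == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "H,N,S,r_max,r_exp",
        [
            (6.912, 2022, 1300, 9.20, -2.42),
            (6.837, 2619, 1383, 13.14, -0.39),
            (6.455, 6654, 1731, 26.67, 8.24),
        ],
    )
    def test_published_triples(self, H, N, S, r_max, r_exp):
        idx = redundancy_indices(H, N, S)
        assert 100 * idx["redundancy_max"] == pytest.approx(r_max, abs=0.05)
        assert 100 * idx["redundancy_exp"] == pytest.approx(r_exp, abs=0.05)

    def test_s_cannot_exceed_n(self):
        with pytest.raises(ValueError):
            redundancy_indices(1.0, 10, 11)

    @given(st.lists(st.integers(min_value=1, max_value=9), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_zero_redundancy_iff_all_singletons(self, counts):
        prof = profile_from_counts({f"C{i:02d}": c for i, c in enumerate(counts)})
        rep = redundancy_report(prof)
        if all(c == 1 for c in counts):
            assert rep.redundancy_max == pytest.approx(0.0, abs=1e-12)
        else:
            assert rep.redundancy_max > 1e-12


def _exhaustive_profiles(max_s=6, max_n=12):
    """Every count multiset with S <= max_s categories and N <= max_n items."""
    def partitions(n, k, minimum=1):
        if k == 1:
            if n >= minimum:
                yield (n,)
            return
        for first in range(minimum, n - k + 2):
            for rest in partitions(n - first, k - 1, first):
                yield (first,) + rest

    for n in range(1, max_n + 1):
        for s in range(1, min(max_s, n) + 1):
            for part in partitions(n, s):
                yield {f"C{i}": c for i, c in enumerate(sorted(part, reverse=True))}


class TestOverRepresented:
    def test_hand_example_strict_inequality(self):
        # at S=4 the expectations are (25, 13, 7, 3)/48; 1/16 == 3/48 exactly,
        # so the rank-4 category ties and must NOT be flagged
        prof = profile_from_counts({"X": 10, "Y": 3, "Z": 2, "W": 1})
        calls = over_represented(prof)
        assert [(c.rank, c.category_id) for c in calls] == [(1, "X")]
        assert calls[0].observed == pytest.approx(0.625)
        assert calls[0].expected == pytest.approx(25 / 48)

    def test_uniform_profile_matches_direct_comparison(self):
        prof = profile_from_counts({f"C{i}": 1 for i in range(5)})
        flagged = {c.category_id for c in over_represented(prof)}
        assert flagged == set(brute_overrepresented(prof.counts))

    def test_exhaustive_small_profiles_match_oracle(self):
        for counts in _exhaustive_profiles():
            prof = profile_from_counts(counts)
            got = [c.category_id for c in over_represented(prof)]
            assert got == brute_overrepresented(counts), counts

    def test_burst_family_flagged_at_rank_one(self):
        table, truth = simulate_cog_table(
            CogSimConfig(
                n_genes=10_000,
                n_categories=100,
                model="transposon_burst",
                model_params={"n_burst": 1, "burst_mass": 0.3},
                seed=1,
            )
        )
        rows = [GeneAssignment(*r) for r in table.itertuples(index=False)]
        prof = build_profile(rows, "SIM")
        calls = over_represented(prof)
        assert calls[0].rank == 1
        assert calls[0].category_id == truth.config["burst_category_ids"][0]

    def test_overlay_table_consistency(self):
        prof = profile_from_counts({"X": 10, "Y": 3, "Z": 2, "W": 1})
        table = overlay_table(prof)
        assert list(table["rank"]) == [1, 2, 3, 4]
        assert table["overrepresented"].sum() == 1
        assert overlay_table(prof, top=2).shape[0] == 2
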