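"""Contact matrices: construction, normalization, binning, summaries."""

import itertools
import math

import numpy as np
import pytest

from t2c.contacts import (
    BinnedMatrix,
    ContactMatrix,
    bin_matrix,
    build_contact_matrix,
    capture_efficiency,
    compare_binned_maps,
    fragment_marginals,
    interaction_read_quantiles,
    mean_reads_per_interaction,
    normalize_capture,
    summarize,
)
from t2c.digestion import Fragment, FragmentMap, get_enzyme


@pytest.fixture(scope="module")
def fragmap6():
    frags = [Fragment(i, "chrA", i * 100, (i + 1) * 100, True) for i in range(5)]
    frags.append(Fragment(5, "chrB", 0, 100, False))
    return FragmentMap(frags, get_enzyme("HindIII"), [("chrA", 0, 500)])


class TestBuildMatrix:
    def test_counts_aggregate(self, fragmap6):
        m = build_contact_matrix([(0, 2), (0, 2), (1, 3)], fragmap6)
        assert m.entries == {(0, 2): 2, (1, 3): 1}
        assert m.n_interactions == 2

    def test_empty_input(self, fragmap6):
        assert build_contact_matrix([], fragmap6).entries == {}

    def test_symmetry_of_lookup(self, fragmap6):
        m = build_contact_matrix([(3, 1)], fragmap6)
        assert m.get(1, 3) == m.get(3, 1) == 1

    def test_self_pair_rejected(self, fragmap6):
        with pytest.raises(ValueError):
            build_contact_matrix([(2, 2)], fragmap6)

    def test_unknown_fragment_rejected(self, fragmap6):
        with pytest.raises(ValueError):
            build_contact_matrix([(0, 99)], fragmap6)

    def test_scope_filters(self, fragmap6):
        pairs = [(0, 2), (0, 5), (1, 5)]
        assert set(build_contact_matrix(pairs, fragmap6, "IN_REGION").entries) == {(0, 2)}
        assert len(build_contact_matrix(pairs, fragmap6, "REGION_VS_GENOME").entries) == 3
        assert len(build_contact_matrix(pairs, fragmap6, "GENOME").entries) == 3


class TestMarginalsAndNormalization:
    def test_marginals(self, fragmap6):
        m = build_contact_matrix([(0, 1)] * 2 + [(0, 2)] * 3, fragmap6)
        s = fragment_marginals(m)
        assert s == {0: 5, 1: 2, 2: 3}

    def test_marginals_with_self_uncut(self, fragmap6):
        m = build_contact_matrix([(0, 1)] * 2 + [(0, 2)] * 3, fragmap6)
        s = fragment_marginals(m, {0: 4})
        assert s[0] == 9

    def test_double_counting_identity(self, fragmap6):
        pairs = [(0, 1), (0, 2), (1, 3), (2, 4), (2, 4)]
        m = build_contact_matrix(pairs, fragmap6)
        assert sum(fragment_marginals(m).values()) == 2 * len(pairs)

    def test_normalization_formula(self, fragmap6):
        m = build_contact_matrix([(0, 1)] * 4 + [(0, 2)] * 6 + [(1, 2)] * 24, fragmap6)
        norm = normalize_capture(m)
        # n=4, S_0=10, S_1=28 -> 4/38
        assert norm.get(0, 1) == pytest.approx(4 / 38)

    def test_single_entry_scores_half(self, fragmap6):
        for k in (1, 7, 100):
            m = build_contact_matrix([(1, 4)] * k, fragmap6)
            assert normalize_capture(m).get(1, 4) == 0.5

    def test_bound_half_over_small_matrices(self, fragmap6):
        """Enumerate all 3-entry matrices on 4 fragments: scores <= 0.5."""
        for combo in itertools.combinations(itertools.combinations(range(4), 2), 3):
            for counts in itertools.product([1, 3], repeat=3):
                pairs = [p for p, c in zip(combo, counts) for _ in range(c)]
                norm = normalize_capture(build_contact_matrix(pairs, fragmap6))
                assert all(0 < v <= 0.5 for v in norm.entries.values())


class TestCaptureEfficiency:
    def test_fraction(self, fragmap6):
        pairs = [(0, 2)] * 8 + [(3, 4)] * 2
        assert capture_efficiency(pairs, {0}, fragmap6) == pytest.approx(0.8)

    def test_all_on_probe_fragments(self, fragmap6):
        assert capture_efficiency([(0, 1)] * 5, {0, 1}, fragmap6) == 1.0

    def test_zero_pairs_errors(self, fragmap6):
        with pytest.raises(ValueError):
            capture_efficiency([], {0}, fragmap6)


class TestBinning:
    def test_boundary(self):
        b = bin_matrix([(("c", 39_999), ("c", 40_000))], 40_000)
        assert b.entries == {(("c", 0), ("c", 1)): 1}

    def test_single_bin_pair_totals(self):
        pairs = [(("c", 5), ("c", 100))] * 7
        b = bin_matrix(pairs, 40_000)
        assert b.entries == {(("c", 0), ("c", 0)): 7}
        assert b.total == 7

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        pairs = [(("c", int(a)), ("c", int(b))) for a, b in rng.integers(0, 500_000, (200, 2))]
        assert bin_matrix(pairs, 40_000).total == 200

    def test_fragment_midpoint_rebinning_agrees(self, fragmap6):
        """Binning reads directly vs. re-binning fragment midpoints agrees
        when no fragment straddles a bin boundary."""
        bin_size = 500  # all chrA fragments fall in bin 0
        pairs_frag = [(0, 2), (1, 3), (0, 4)]
        direct = bin_matrix(
            [(("chrA", fragmap6[i].start), ("chrA", fragmap6[j].start)) for i, j in pairs_frag],
            bin_size,
        )
        via_mid = bin_matrix(
            [(("chrA", int(fragmap6[i].midpoint)), ("chrA", int(fragmap6[j].midpoint)))
             for i, j in pairs_frag],
            bin_size,
        )
        assert direct.entries == via_mid.entries


def _rank(values):
    """Midrank helper for the brute-force oracle."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestCompareBinnedMaps:
    def _mat(self, entries):
        return BinnedMatrix(entries, 40_000)

    def test_self_correlation_exactly_one(self):
        rng = np.random.default_rng(1)
        entries = {
            (("c", int(i)), ("c", int(j))): int(n)
            for (i, j), n in zip(rng.integers(0, 50, (30, 2)), rng.integers(1, 99, 30))
        }
        a = self._mat(entries)
        rho, p = compare_binned_maps(a, a)
        assert rho == 1.0

    def test_rank_reversal_gives_minus_one(self):
        keys = [(("c", 0), ("c", k)) for k in range(1, 7)]
        a = self._mat({k: n for k, n in zip(keys, [1, 2, 3, 4, 5, 6])})
        b = self._mat({k: n for k, n in zip(keys, [6, 5, 4, 3, 2, 1])})
        rho, _ = compare_binned_maps(a, b)
        assert rho == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_pearson(self):
        """rho equals rank-then-Pearson with midranks on 5x5 matrices."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            keys = [(("c", i), ("c", j)) for i in range(5) for j in range(i, 5)]
            va = rng.integers(0, 6, len(keys))
            vb = rng.integers(0, 6, len(keys))
            a = self._mat({k: int(v) for k, v in zip(keys, va) if v > 0})
            b = self._mat({k: int(v) for k, v in zip(keys, vb) if v > 0})
            union = sorted(set(a.entries) | set(b.entries))
            if len(union) < 3:
                continue
            xa = [a.entries.get(k, 0) for k in union]
            xb = [b.entries.get(k, 0) for k in union]
            ra, rb = _rank(xa), _rank(xb)
            expected = np.corrcoef(ra, rb)[0, 1]
            rho, _ = compare_binned_maps(a, b)
            assert rho == pytest.approx(expected, abs=1e-12)

    def test_too_few_bins_errors(self):
        a = self._mat({(("c", 0), ("c", 1)): 1})
        with pytest.raises(ValueError):
            compare_binned_maps(a, a)


class TestSummaries:
    @pytest.mark.parametrize(
        "pairs,interactions,expected",
        [
            (557_763, 4_057, 137),
            (271_177, 2_369, 114),
            (1_929_245, 8_989, 215),  # requires round-half-up
            (10, 10, 1),
        ],
    )
    def test_mean_reads_per_interaction(self, pairs, interactions, expected):
        assert mean_reads_per_interaction(pairs, interactions) == expected

    def test_zero_interactions_errors(self):
        with pytest.raises(ValueError):
            mean_reads_per_interaction(10, 0)

    def test_summarize_cascade_and_fields(self, fragmap6):
        m = build_contact_matrix([(0, 1)] * 3 + [(2, 3)], fragmap6, "IN_REGION")
        s = summarize({}, m, fragmap6, raw_pairs=100, mapped_pairs=50,
                      region_vs_genome_pairs=20, unique_filtered_pairs=10,
                      unique_filtered_region_vs_genome=8)
        assert s.in_region_pairs == 4
        assert s.interactions_in_region == 2
        assert s.mean_reads_per_interaction == 2
        assert s.median_resolution_kbp == 0.1

    def test_summarize_rejects_nonmonotone_cascade(self, fragmap6):
        m = build_contact_matrix([(0, 1)], fragmap6, "IN_REGION")
        with pytest.raises(ValueError):
            summarize({}, m, fragmap6, raw_pairs=10, mapped_pairs=50,
                      region_vs_genome_pairs=20, unique_filtered_pairs=10,
                      unique_filtered_region_vs_genome=8)


class TestQuantiles:
    def _matrix(self, counts, fragmap):
        pairs = []
        for k, c in enumerate(counts):
            pairs += [(0, k + 1)] * c
        return build_contact_matrix(pairs, fragmap)

    def test_top_band(self, fragmap6):
        m = self._matrix([10, 8, 5, 1, 1], fragmap6)
        assert interaction_read_quantiles(m, 0.4) == (10, 8)

    def test_full_band(self, fragmap6):
        m = self._matrix([10, 8, 5, 1, 1], fragmap6)
        assert interaction_read_quantiles(m, 1.0) == (10, 1)

    def test_constant_counts(self, fragmap6):
        m = self._matrix([4, 4, 4], fragmap6)
        assert interaction_read_quantiles(m, 0.5) == (4, 4)

    def test_bad_fraction(self, fragmap6):
        m = self._matrix([1], fragmap6)
        with pytest.raises(ValueError):
            interaction_read_quantiles(m, 0.0)
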