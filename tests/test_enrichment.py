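"""2x2 enrichment statistics, test selection and FDR adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import bh_stepup, fisher_two_sided_enumeration
from tfdosage import (
    ContingencyTable,
    bh_adjust,
    expected_count,
    fisher_exact,
    pearson_chi2,
    run_enrichment,
    small_family_groups,
    enrich_group_vs_set,
)


class TestExpectedCount:
    @pytest.mark.parametrize(
        "n_group, n_set, n_universe, expected",
        [
            (1639, 853, 22810, 61.29),
            (46, 853, 22810, 1.72),
            (0, 853, 22810, 0.0),
            (747, 5579, 22810, 182.71),
        ],
    )
    def test_values(self, n_group, n_set, n_universe, expected):
        assert expected_count(n_group, n_set, n_universe) == pytest.approx(
            expected, abs=0.005
        )

    def test_three_significant_figures(self):
        assert float(f"{expected_count(747, 5579, 22810):.3g}") == 183

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError):
            expected_count(10, 10, 0)

    def test_partition_sums_to_set_size(self):
        """If groups partition the universe, expected counts sum to the
        target-set size exactly."""
        sizes = [500, 1200, 300, 8000, 10000, 2810]
        total = sum(sizes)
        n_set = 853
        assert sum(expected_count(s, n_set, total) for s in sizes) == pytest.approx(
            n_set, rel=1e-12
        )


class TestPearsonChi2:
    def test_independent_table(self):
        statistic, p = pearson_chi2(ContingencyTable(10, 10, 10, 10))
        assert statistic == 0.0
        assert p == 1.0

    def test_matches_closed_form(self):
        a, b, c, d = 20, 5, 5, 20
        n = a + b + c + d
        longhand = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        statistic, p = pearson_chi2(ContingencyTable(a, b, c, d))
        assert statistic == pytest.approx(longhand, rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(longhand, 1)), rel=1e-12)

    def test_doubling_cells_doubles_statistic(self):
        s1, _ = pearson_chi2(ContingencyTable(12, 5, 7, 30))
        s2, _ = pearson_chi2(ContingencyTable(24, 10, 14, 60))
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_zero_expected_cell_directs_to_fisher(self):
        with pytest.raises(ValueError, match="fisher_exact"):
            pearson_chi2(ContingencyTable(0, 0, 5, 5))

    def test_yates_shrinks_statistic(self):
        plain, _ = pearson_chi2(ContingencyTable(12, 5, 7, 30))
        corrected, _ = pearson_chi2(ContingencyTable(12, 5, 7, 30), yates=True)
        assert 0 < corrected < plain


class TestFisherExact:
    def test_degenerate_single_table(self):
        assert fisher_exact(ContingencyTable(0, 0, 4, 6)) == 1.0

    def test_symmetric_table(self):
        assert fisher_exact(ContingencyTable(3, 3, 3, 3)) == 1.0

    def test_small_table_vs_enumeration(self):
        table = ContingencyTable(3, 1, 1, 3)
        assert fisher_exact(table) == pytest.approx(
            fisher_two_sided_enumeration(3, 1, 1, 3), rel=1e-12
        )

    def test_chi2_consistency_for_large_expecteds(self):
        """Where every expected cell is >= 20 the asymptotic and exact tests
        agree within a factor of 1.5."""
        for table in (
            ContingencyTable(30, 40, 40, 30),
            ContingencyTable(60, 45, 40, 70),
            ContingencyTable(25, 25, 30, 40),
        ):
            assert table.expected_cells().min() >= 20
            _, p_chi = pearson_chi2(table)
            p_f = fisher_exact(table)
            assert p_chi / p_f < 1.5 and p_f / p_chi < 1.5


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_worked_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_empty_input(self):
        assert bh_adjust([]) == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_stepup_oracle(self, pvalues):
        adjusted = bh_adjust(pvalues)
        assert adjusted == pytest.approx(bh_stepup(pvalues), rel=1e-12)
        assert all(a >= p - 1e-15 for a, p in zip(adjusted, pvalues))
        order = np.argsort(pvalues)
        sorted_adj = np.asarray(adjusted)[order]
        assert (np.diff(sorted_adj) >= -1e-15).all()


class TestRunEnrichment:
    def make_families(self):
        ids = [f"g{i}" for i in range(2000)]
        return ids, {
            "FamA": set(ids[:46]),
            "FamB": set(ids[46:146]),
            "FamC": set(ids[146:150]),
        }

    def test_test_selection_by_expected(self):
        """Expected <= 5 selects Fisher; larger expecteds select chi-square."""
        universe = {f"g{i}" for i in range(22810)}
        target = set(list(universe)[:853])
        small = set(list(universe)[:46])
        big = set(list(universe)[:1639])
        r_small = enrich_group_vs_set(small, target, len(universe), "small")
        r_big = enrich_group_vs_set(big, target, len(universe), "big")
        assert r_small.expected == pytest.approx(1.72, abs=0.005)
        assert r_small.test_used == "fisher_exact"
        assert r_big.expected == pytest.approx(61.29, abs=0.005)
        assert r_big.test_used == "chi_square"

    def test_group_equal_universe_direction_none(self):
        universe = {f"g{i}" for i in range(100)}
        target = {f"g{i}" for i in range(20)}
        result = enrich_group_vs_set(universe, target, 100, "all")
        assert result.observed == len(target)
        assert result.expected == pytest.approx(len(target))
        assert result.direction == "none"

    def test_bh_across_one_target_set(self):
        ids, families = self.make_families()
        target = set(ids[:100])
        results = run_enrichment(target, families, set(ids))
        raw = [r.p for r in results]
        assert [r.p_adj for r in results] == pytest.approx(bh_stepup(raw))

    def test_small_family_pooling(self):
        families = {
            "A": {"g1", "g2"},
            "B": {"g3", "g4", "g5", "g6", "g7", "g8"},
            "C": set(f"h{i}" for i in range(12)),
        }
        pooled = small_family_groups(families, cutoffs=(5, 7))
        assert pooled["<=5 members"] == families["A"]
        assert pooled["<=7 members"] == families["A"] | families["B"]

    def test_planted_family_detected_null_families_controlled(self):
        """A planted relative-risk-8 family of 50 genes (universe 20,000,
        target prevalence 0.04) is BH-significant in >= 95% of 100 seeded
        draws while null families stay below a 10% flag rate."""
        n_universe, prevalence, rr, fam_size = 20000, 0.04, 8.0, 50
        ids = np.array([f"g{i}" for i in range(n_universe)])
        sizes = [fam_size] + [30] * 20 + [10] * 20 + [5] * 24
        names = ["planted"] + [f"null{i}" for i in range(len(sizes) - 1)]
        families = {}
        pos = 0
        for name, size in zip(names, sizes):
            families[name] = set(ids[pos: pos + size])
            pos += size
        universe = set(ids)
        hits = 0
        null_flags, null_tests = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            p_in = np.full(n_universe, prevalence)
            p_in[:fam_size] = rr * prevalence
            target = set(ids[rng.random(n_universe) < p_in])
            results = run_enrichment(
                target, families, universe, small_family_cutoffs=(), all_tf_group=False
            )
            by_name = {r.group_name: r for r in results}
            if by_name["planted"].p_adj < 0.05:
                hits += 1
            for name in names[1:]:
                null_tests += 1
                if by_name[name].p_adj < 0.05:
                    null_flags += 1
        assert hits >= 95
        assert null_flags / null_tests <= 0.10
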