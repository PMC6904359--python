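"""Two-group feature characterization: motifs, proportions, comparisons."""

import numpy as np
import pytest
from scipy import stats

from oracles import mwu_two_sided_enumeration
from tfdosage import (
    Motif,
    classify,
    compare_feature,
    compare_motifs,
    default_config,
    generate,
    mann_whitney,
    motif_stats,
    proportion_compare,
    summarize_expression,
)
from tfdosage.classifier import MRDIS, MRDS, DosageLabel
from tfdosage.features import expression_counts


def uniform_motif(length):
    return Motif(tf_gene_id="M", matrix=np.full((length, 4), 0.25))


class TestMotifStats:
    def test_uniform(self):
        result = motif_stats(uniform_motif(4))
        assert result.length == 4
        assert result.base_fraction == {
            "A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25,
        }

    def test_two_pure_positions(self):
        motif = Motif(tf_gene_id="M", matrix=[[1, 0, 0, 0], [0, 1, 0, 0]])
        result = motif_stats(motif)
        assert result.base_fraction == {"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0}

    def test_fractions_sum_to_one_and_reversal_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            gamma = rng.gamma(1.0, 1.0, (int(rng.integers(1, 20)), 4))
            matrix = gamma / gamma.sum(axis=1, keepdims=True)
            stats_fwd = motif_stats(Motif(tf_gene_id="M", matrix=matrix))
            stats_rev = motif_stats(Motif(tf_gene_id="M", matrix=matrix[::-1]))
            assert sum(stats_fwd.base_fraction.values()) == pytest.approx(1.0)
            assert stats_fwd.base_fraction == pytest.approx(stats_rev.base_fraction)

    def test_length_additive_under_concatenation(self):
        rng = np.random.default_rng(2)
        g1 = rng.dirichlet([1, 1, 1, 1], 5)
        g2 = rng.dirichlet([1, 1, 1, 1], 7)
        joined = motif_stats(Motif(tf_gene_id="M", matrix=np.vstack([g1, g2])))
        assert joined.length == 5 + 7


class TestMannWhitney:
    def test_identical_singletons(self):
        u, p = mann_whitney([5], [5])
        assert p == 1.0

    def test_complete_separation_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_branch_matches_enumeration(self):
        """All tie-free shapes up to 4 per group agree with the full
        rank-arrangement enumeration."""
        rng = np.random.default_rng(4)
        for n_a in range(1, 5):
            for n_b in range(1, 5):
                for _ in range(3):
                    pooled = rng.permutation(
                        np.arange(1.0, n_a + n_b + 1)
                    )
                    a, b = pooled[:n_a], pooled[n_a:]
                    u_oracle, p_oracle = mwu_two_sided_enumeration(list(a), list(b))
                    u, p = mann_whitney(a, b)
                    assert u == pytest.approx(u_oracle)
                    assert p == pytest.approx(p_oracle, rel=1e-9)


class TestProportionCompare:
    @pytest.mark.parametrize(
        "k_a, n_a, k_b, n_b, pct_a, pct_b",
        [
            (21, 122, 3, 368, 17.2, 0.82),  # activation domains
            (8, 122, 214, 368, 6.56, 58.2),  # repressor domains (KRAB counted)
            (1226, 22810, 0, 1, 5.4, 0.0),  # HLOF-tolerant share of the genome
            (103, 1639, 0, 1, 6.3, 0.0),  # HLOF-tolerant share of TFs
        ],
    )
    def test_printed_percentages(self, k_a, n_a, k_b, n_b, pct_a, pct_b):
        pa, pb, _, _ = proportion_compare(k_a, n_a, k_b, n_b)
        digits_a = len(str(pct_a).split(".")[1])
        digits_b = len(str(pct_b).split(".")[1])
        assert round(pa, digits_a) == pct_a
        assert round(pb, digits_b) == pct_b

    def test_zero_in_both_groups(self):
        pa, pb, _, p = proportion_compare(0, 10, 0, 20)
        assert pa == pb == 0.0
        assert p == 1.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            proportion_compare(1, 0, 1, 5)
        with pytest.raises(ValueError):
            proportion_compare(6, 5, 1, 5)


class TestCompareFeature:
    def test_recovers_planted_cds_shift(self, default_data, default_labels):
        """Class CDS means planted at 2640 vs 1310 bp are recovered within
        3 standard errors on a default-size catalog."""
        result = compare_feature(
            default_data.frame, default_labels, "cds_length", restrict="all_genes"
        )
        se_a = result.sd_a / np.sqrt(result.n_a)
        se_b = result.sd_b / np.sqrt(result.n_b)
        assert abs(result.mean_a - 2640) < 3 * se_a
        assert abs(result.mean_b - 1310) < 3 * se_b
        assert result.p < 1e-6

    def test_dnds_excludes_zero_ds(self, default_data, default_labels):
        frame = default_data.frame
        result = compare_feature(frame, default_labels, "dnds", restrict="all_genes")
        label_map = {l.gene_id: l.label for l in default_labels}
        lab = frame["gene_id"].map(label_map)
        ds = frame["ds"].astype(float)
        n_valid_a = int(((lab == MRDS) & (ds > 0)).sum())
        n_valid_b = int(((lab == MRDIS) & (ds > 0)).sum())
        assert result.n_a == n_valid_a  # effective n excludes dS = 0 rows
        assert result.n_b == n_valid_b
        assert result.n_a < (lab == MRDS).sum()

    def test_unknown_feature_and_empty_group(self, default_data, default_labels):
        with pytest.raises(ValueError, match="unknown feature"):
            compare_feature(default_data.frame, default_labels, "bogus")
        labels = [
            DosageLabel(l.gene_id, "UNCLASSIFIED", l.n_evidence_sets)
            for l in default_labels
        ]
        with pytest.raises(ValueError, match="cds_length"):
            compare_feature(default_data.frame, labels, "cds_length")

    def test_null_pvalues_uniform_under_label_permutation(
        self, default_data, default_labels
    ):
        """Permuting MRDS/MRDIS labels across the pooled genes destroys the
        association, so the comparison p-values are uniform (KS at 0.01)."""
        frame = default_data.frame
        label_map = {l.gene_id: l.label for l in default_labels}
        lab = frame["gene_id"].map(label_map)
        pooled = frame[(lab == MRDS) | (lab == MRDIS)]
        pooled = pooled.sample(n=400, random_state=0).reset_index(drop=True)
        values = pooled["cds_length"].to_numpy(dtype=float)
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            perm = rng.permutation(len(values))
            _, p = mann_whitney(values[perm[:150]], values[perm[150:]])
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMotifComparison:
    def test_class_shift_direction(self, default_data, default_labels):
        """MRDIS binding sites are A-richer than MRDS sites, as planted."""
        results = {
            r.feature: r
            for r in compare_motifs(default_data.motifs, default_labels)
        }
        assert set(results) == {
            "motif_length", "motif_A_percent", "motif_C_percent",
            "motif_G_percent", "motif_T_percent",
        }
        assert results["motif_A_percent"].mean_b > results["motif_A_percent"].mean_a
        frac_sum = sum(
            results[f"motif_{b}_percent"].mean_a for b in "ACGT"
        )
        assert frac_sum == pytest.approx(100.0, abs=1e-6)


class TestExpression:
    def test_counts_partition_sample_panel(self):
        levels = (
            {f"S{i}": "high" for i in range(9)}
            | {f"S{i}": "medium" for i in range(9, 21)}
            | {f"S{i}": "low" for i in range(21, 29)}
            | {f"S{i}": "not_detected" for i in range(29, 31)}
        )
        samples = [f"S{i}" for i in range(31)]
        counts = expression_counts(levels, samples)
        assert counts == {"high": 9, "medium": 12, "low": 8, "not_detected": 2}
        assert sum(counts.values()) == 31

    def test_incomplete_profile_excluded(self):
        samples = ["S1", "S2"]
        assert expression_counts({"S1": "high"}, samples) is None

    def test_summary_and_comparisons(self, default_data, default_labels):
        summaries, comparisons = summarize_expression(
            default_data.frame, default_labels, default_data.expression_samples
        )
        for summary in summaries.values():
            assert sum(summary.mean_counts.values()) == pytest.approx(
                len(default_data.expression_samples)
            )
        by_name = {c.feature: c for c in comparisons}
        # planted: sensitive genes are detected in more samples
        assert by_name["expression_not_detected"].mean_a < by_name[
            "expression_not_detected"
        ].mean_b
        assert by_name["expression_high"].p < 0.05

    def test_degenerate_all_not_detected(self):
        config = default_config(seed=9)
        config.n_genes, config.n_tf = 400, 40
        config.family_sizes = [["C2H2-ZF", 30], ["Unknown", 10]]
        config.n_kzfp = 10
        config.planted_families = []
        config.expression_probs = {
            "sensitive": [0.0, 0.0, 0.0, 1.0],
            "insensitive": [0.0, 0.0, 0.0, 1.0],
        }
        config.expression_complete_rate = 1.0
        config.expression_partial_rate = 0.0
        data = generate(config)
        labels = classify(data.frame, data.evidence)
        _, comparisons = summarize_expression(
            data.frame, labels, data.expression_samples
        )
        for comparison in comparisons:
            if comparison.feature != "expression_not_detected":
                assert comparison.p == 1.0

    def test_empty_sample_list_rejected(self, default_data, default_labels):
        with pytest.raises(ValueError):
            summarize_expression(default_data.frame, default_labels, [])
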