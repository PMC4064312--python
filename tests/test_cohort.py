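"""Cohort statistics: enrichment, exact tests, clustering, design power."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelvar.cohort import (
    AlterationMatrix,
    CohortModel,
    PowerSpec,
    bh_fdr,
    build_alteration_matrix,
    chi_squared_power,
    chi_squared_test,
    fisher_exact,
    gene_enrichment,
    hierarchical_cluster,
    logistic_group_test,
    wilcoxon_rank_sum,
)

from oracles import (
    bh_stepup_oracle,
    conditional_chi2_p,
    fisher_exact_oracle,
    wilcoxon_enumeration_oracle,
)


def two_group_matrix(cells_a, cells_b, genes):
    data, groups = {}, {}
    for i, cells in enumerate(cells_a):
        data[f"A{i}"] = dict(zip(genes, cells))
        groups[f"A{i}"] = "A"
    for i, cells in enumerate(cells_b):
        data[f"B{i}"] = dict(zip(genes, cells))
        groups[f"B{i}"] = "B"
    return AlterationMatrix(pd.DataFrame(data).T[list(genes)],
                            pd.Series(groups))


class TestAlterationMatrix:
    def sheet(self):
        return pd.DataFrame({"sample": ["s1", "s2", "s3"],
                             "group": ["A", "A", "B"]})

    def test_no_calls_gives_all_none(self):
        m = build_alteration_matrix({}, {}, self.sheet(), genes=["TP53"])
        assert (m.data == "none").all().all()

    def test_single_mutation_single_cell(self):
        m = build_alteration_matrix({"s2": [{"gene": "TP53"}]}, {},
                                    self.sheet(), genes=["TP53", "PTEN"])
        assert m.data.loc["s2", "TP53"] == "mutation"
        assert (m.data != "none").sum().sum() == 1

    def test_mutation_plus_cna_reduces_to_multiple(self):
        m = build_alteration_matrix(
            {"s1": [{"gene": "PIK3CA"}]},
            {"s1": [{"gene": "PIK3CA", "kind": "amplification"}]},
            self.sheet(), genes=["PIK3CA"])
        assert m.data.loc["s1", "PIK3CA"] == "multiple"

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError):
            build_alteration_matrix({"sX": [{"gene": "TP53"}]}, {},
                                    self.sheet())


class TestChiSquared:
    def test_balanced_table_is_null(self):
        stat, p = chi_squared_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_printed_cohort_table_statistic(self):
        """TP53 altered 16/16 in one stratum vs 1/18 in the other gives a
        Pearson statistic of ~30.22 (hand-computable from Sum (O-E)^2/E)."""
        stat, p = chi_squared_test([[16, 0], [1, 17]])
        assert stat == pytest.approx(30.2222, abs=1e-3)
        assert p < 1e-6

    def test_zero_margin_degenerate(self):
        stat, p = chi_squared_test([[0, 0], [5, 5]])
        assert (stat, p) == (0.0, 1.0)

    def test_matches_exact_conditional_tail(self, rng):
        """Asymptotic chi-squared p agrees with the exact conditional
        (fixed-margin, mid-p) tail probability on medium-size tables."""
        for _ in range(20):
            t = rng.integers(20, 80, size=(2, 2))
            stat, p = chi_squared_test(t)
            p_exact = conditional_chi2_p(t, mid=True)
            assert abs(p - p_exact) < 0.05


class TestFisher:
    def test_balanced_is_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        """Two-sided p equals hypergeometric-tail enumeration on 200 random
        tables."""
        for _ in range(200):
            t = rng.integers(0, 25, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                fisher_exact_oracle(t), abs=1e-10)

    def test_concordant_table_strongly_significant(self):
        p = fisher_exact([[8, 1], [0, 25]])
        assert p < 0.001
        assert p == pytest.approx(fisher_exact_oracle([[8, 1], [0, 25]]),
                                  abs=1e-12)


class TestWilcoxon:
    def test_identical_samples_near_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_exact_matches_enumeration(self, rng):
        """Small-sample p equals full enumeration over assignments,
        including tied data."""
        for _ in range(30):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            vals = rng.integers(0, 6, size=n + m).astype(float)  # many ties
            x, y = vals[:n], vals[n:]
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_complete_separation_attains_minimal_p(self):
        x, y = [1, 2, 3, 4, 5, 6], [10, 11, 12, 13, 14, 15]
        p = wilcoxon_rank_sum(x, y)
        # the two extreme assignments out of C(12,6)
        assert p == pytest.approx(2 / 924)

    def test_normal_approximation_regime_matches_scipy(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 25)
        p = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestLogistic:
    def test_flat_covariate_null(self):
        coef, p = logistic_group_test([5.0, 5.1, 4.9, 5.0, 5.05, 4.95],
                                      ["A", "A", "A", "B", "B", "B"])
        assert abs(coef) < 0.5 and p > 0.5

    def test_shifted_covariate_detected_with_correct_sign(self, rng):
        a = rng.normal(50, 5, 20)
        b = rng.normal(62, 5, 20)
        coef, p = logistic_group_test(np.concatenate([a, b]),
                                      ["A"] * 20 + ["B"] * 20)
        assert coef > 0 and p < 0.01

    def test_perfect_separation_flagged(self):
        coef, p = logistic_group_test([1, 2, 3, 10, 11, 12],
                                      ["A", "A", "A", "B", "B", "B"])
        assert np.isinf(coef) and np.isnan(p)

    def test_slope_recovery_within_two_se(self, rng):
        """Simulated logistic data: estimate within 2 SE of truth in ~95%
        of replicates."""
        import statsmodels.api as sm

        beta = 0.8
        ok = 0
        for _ in range(100):
            x = rng.normal(0, 1, 120)
            pr = 1 / (1 + np.exp(-(0.2 + beta * x)))
            y = rng.random(120) < pr
            if y.sum() < 3 or (~y).sum() < 3:
                continue
            fit = sm.Logit(y.astype(float), sm.add_constant(x)).fit(disp=0)
            ok += abs(fit.params[1] - beta) <= 2 * fit.bse[1]
        assert ok >= 85


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_worked_stepup(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_matches_longhand_oracle_and_monotone(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        assert q == pytest.approx(bh_stepup_oracle(p), abs=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-15).all()


class TestEnrichment:
    def test_printed_tp53_contrast_is_significant_after_fdr(self):
        """A gene altered in 16/16 of one group and 1/18 of the other stays
        q < 0.01 even under worst-case correction across a 182-gene panel."""
        cells_a = [["mutation"]] * 16 + [["none"]] * 0
        cells_b = [["mutation"]] * 1 + [["none"]] * 17
        m = two_group_matrix(cells_a, cells_b, ["TP53"])
        res = gene_enrichment(m)[0]
        assert res.statistic == pytest.approx(30.2222, abs=1e-3)
        assert res.p_value * 182 < 0.01  # worst-case BH rank-1 bound

    def test_untouched_gene_excluded(self):
        m = two_group_matrix([["mutation", "none"]] * 4,
                             [["none", "none"]] * 4, ["G1", "G2"])
        assert [r.gene for r in gene_enrichment(m)] == ["G1"]

    def test_equal_prevalence_is_null(self):
        cells = [["mutation"]] * 5 + [["none"]] * 11
        m = two_group_matrix(cells, cells, ["G"])
        res = gene_enrichment(m)[0]
        assert res.p_value == 1.0 and res.q_value == 1.0

    def test_single_group_rejected(self):
        m = two_group_matrix([["mutation"]], [], ["G"])
        with pytest.raises(ValueError):
            gene_enrichment(m)

    def test_type_one_error_controlled_on_null_cohorts(self, rng):
        """Equal-prevalence cohorts: the fraction of genes reaching q < 0.05
        stays at or below the nominal level over 200 replicates."""
        n_sig = n_tests = 0
        for _ in range(200):
            prev = rng.uniform(0.1, 0.6, 12)
            flags_a = rng.random((20, 12)) < prev
            flags_b = rng.random((20, 12)) < prev
            cells_a = np.where(flags_a, "mutation", "none")
            cells_b = np.where(flags_b, "mutation", "none")
            m = two_group_matrix(cells_a.tolist(), cells_b.tolist(),
                                 [f"G{i}" for i in range(12)])
            for r in gene_enrichment(m):
                n_tests += 1
                n_sig += r.q_value < 0.05
        assert n_sig / n_tests <= 0.05


class TestClustering:
    def test_disjoint_alteration_sets_cluster_perfectly(self):
        """Two strata with non-overlapping alteration profiles separate with
        100% purity."""
        cells_a = [["mutation", "mutation", "none", "none"]] * 9
        cells_b = [["none", "none", "deletion", "amplification"]] * 8
        m = two_group_matrix(cells_a, cells_b, ["G1", "G2", "G3", "G4"])
        res = hierarchical_cluster(m)
        assert res.purity == 1.0
        assert sorted(np.unique(res.labels)) == [1, 2]

    def test_one_sample_per_group_trivial_split(self):
        m = two_group_matrix([["mutation"]], [["none"]], ["G"])
        assert hierarchical_cluster(m).purity == 1.0

    def test_identical_rows_flagged_degenerate(self):
        m = two_group_matrix([["mutation"]] * 3, [["mutation"]] * 3, ["G"])
        assert hierarchical_cluster(m).degenerate

    def test_newick_export_contains_all_samples(self):
        m = two_group_matrix([["mutation", "none"]] * 3,
                             [["none", "deletion"]] * 3, ["G1", "G2"])
        nwk = hierarchical_cluster(m).to_newick()
        for s in m.data.index:
            assert s in nwk

    def test_study_like_cohorts_reach_high_purity(self):
        """Cohorts drawn from the two-group prevalence template separate at
        >= 90% mean purity over 20 seeds."""
        from panelvar.simulate import CohortSpec, simulate_cohort

        purities = []
        for seed in range(20):
            spec = CohortSpec(seed=seed, depth_mean=60.0, snps_per_gene=1)
            _, truth = simulate_cohort(spec)
            genes = spec.panel.genes
            rows, groups = {}, {}
            for s in truth.samples:
                cell = {g: "none" for g in genes}
                for v in s.variants:
                    cell[v["gene"]] = "mutation"
                for g, c in s.gene_copies.items():
                    if c >= 6:
                        cell[g] = "amplification" if cell[g] == "none" else "multiple"
                    elif c == 0:
                        cell[g] = "deletion" if cell[g] == "none" else "multiple"
                rows[s.sample] = cell
                groups[s.sample] = s.group
            m = AlterationMatrix(pd.DataFrame(rows).T[genes], pd.Series(groups))
            purities.append(hierarchical_cluster(m).purity)
        assert np.mean(purities) >= 0.90


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert chi_squared_power(PowerSpec(0.0, 0.05, 40, 1)) == pytest.approx(0.05)

    def test_study_design_power_just_under_ninety_percent(self):
        """w=0.5, alpha=0.05, N=40, df=1 gives ~0.885."""
        power = chi_squared_power(PowerSpec(0.5, 0.05, 40, 1))
        assert power == pytest.approx(0.885, abs=0.002)
        assert power < 0.90

    def test_monotone_in_n_w_alpha(self):
        for n1, n2 in [(20, 40), (40, 80)]:
            assert (chi_squared_power(PowerSpec(0.5, 0.05, n2, 1))
                    > chi_squared_power(PowerSpec(0.5, 0.05, n1, 1)))
        assert (chi_squared_power(PowerSpec(0.7, 0.05, 40, 1))
                > chi_squared_power(PowerSpec(0.5, 0.05, 40, 1)))
        assert (chi_squared_power(PowerSpec(0.5, 0.10, 40, 1))
                > chi_squared_power(PowerSpec(0.5, 0.05, 40, 1)))


class TestCohortModel:
    def test_fit_returns_enrichment_clustering_and_clinical(self, rng):
        cells_a = [["mutation", "none"]] * 8
        cells_b = [["none", "deletion"]] * 8
        m = two_group_matrix(cells_a, cells_b, ["PIK3CA", "CDKN2A"])
        clinical = pd.DataFrame({
            "sample": list(m.data.index),
            "age": np.r_[rng.normal(56, 5, 8), rng.normal(59, 5, 8)],
            "alcohol": np.r_[rng.integers(0, 2, 8), rng.integers(1, 3, 8)],
        })
        res = CohortModel(m, clinical=clinical).fit()
        assert set(res.enrichment_table.gene) == {"PIK3CA", "CDKN2A"}
        assert res.clustering.purity == 1.0
        assert set(res.clinical_tests) == {"age", "alcohol"}
        assert res.clinical_tests["age"]["test"] == "logistic"
        assert res.clinical_tests["alcohol"]["test"] == "wilcoxon"
        assert "Cohort analysis" in res.summary()
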