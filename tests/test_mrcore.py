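"""MR estimators against hand-derived values, oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exmr import calibration, ivselect, mrcore


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        est, se, p = mrcore.wald_ratio(0.5, 0.05, 0.0, 0.1)
        assert est == 0.0 and p == pytest.approx(1.0)

    def test_identity_instrument(self):
        est, se, _ = mrcore.wald_ratio(1.0, 0.05, 0.3, 0.1)
        assert (est, se) == (0.3, 0.1)

    def test_delta_method_formula(self):
        est, se, _ = mrcore.wald_ratio(0.5, 0.05, 0.2, 0.1)
        assert est == pytest.approx(0.4)
        assert se == pytest.approx(0.2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mrcore.wald_ratio(0.0, 0.1, 0.1, 0.1)


class TestIvwFixed:
    def test_hand_computed_two_instrument_example(self):
        est, se, _ = mrcore.ivw_fixed([0.5, 0.25], [0.1, 0.1], [0.1, 0.1])
        assert est == pytest.approx(0.24)
        assert se == pytest.approx(0.178885, abs=1e-4)

    def test_single_instrument_reduces_to_wald(self, rng):
        for _ in range(20):
            bx, by = rng.normal(size=2)
            sy = rng.uniform(0.01, 0.5)
            if abs(bx) < 1e-3:
                continue
            w = mrcore.wald_ratio(bx, 0.1, by, sy)
            i = mrcore.ivw_fixed([bx], [by], [sy])
            assert np.allclose(w, i)

    def test_homogeneous_ratios_recovered_exactly(self):
        bx = np.array([0.2, 0.4, 0.6])
        est, _, _ = mrcore.ivw_fixed(bx, 0.3 * bx, [0.1, 0.1, 0.1])
        assert est == pytest.approx(0.3)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            mrcore.ivw_fixed([0.1], [0.1], [0.0])


class TestCochranQ:
    def test_homogeneous_is_zero_with_p_one(self):
        bx = np.array([0.2, 0.4, 0.6])
        q, df, p = mrcore.cochran_q(bx, 0.3 * bx, [0.1] * 3, 0.3)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        q, df, _ = mrcore.cochran_q([0.5, 0.25], [0.1, 0.1], [0.1, 0.1],
                                    0.24)
        assert q == pytest.approx(0.2)
        assert df == 1

    def test_rejection_rises_with_planted_heterogeneity(self, rng):
        """Extra per-SNP effect variance inflates Q monotonically."""
        rates = []
        for tau in (0.0, 0.3, 1.0):
            rej = 0
            for _ in range(300):
                bx = rng.uniform(0.2, 0.5, size=8)
                sy = np.full(8, 0.05)
                by = 0.3 * bx + rng.normal(0, sy) + \
                    tau * rng.normal(0, sy)
                est, _, _ = mrcore.ivw_fixed(bx, by, sy)
                _, _, p = mrcore.cochran_q(bx, by, sy, est)
                rej += p < 0.05
            rates.append(rej / 300)
        assert rates[0] < rates[1] < rates[2]


class TestEgger:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.05 + 0.4 * bx
        slope, _, _, intercept, _, _ = mrcore.egger(bx, 0.01 * bx, by,
                                                    np.full(5, 0.1))
        assert slope == pytest.approx(0.4, abs=1e-12)
        assert intercept == pytest.approx(0.05, abs=1e-12)

    def test_planted_pleiotropy_covered_by_intercept_ci(self):
        res = calibration.egger_pleiotropy_recovery(n_rep=50, seed=4,
                                                    alpha_planted=0.05)
        assert res["coverage"] >= 0.90

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            mrcore.egger([0.1, 0.2], [0.01, 0.01], [0.1, 0.1], [0.1, 0.1])


class TestWeightedMedian:
    def test_equal_weights_odd_k_gives_middle_order_statistic(self):
        bx = np.ones(5)
        by = np.array([0.5, 0.1, 0.3, 0.2, 0.4])
        est, _, _ = mrcore.weighted_median(bx, by, np.ones(5), n_boot=10)
        assert est == pytest.approx(0.3)

    def test_resists_single_invalid_instrument_better_than_ivw(self):
        bx = np.full(10, 0.4)
        sy = np.full(10, 0.02)
        by = 0.3 * bx
        by[0] = 0.3 * bx[0] + 0.5  # one wildly pleiotropic instrument
        med, _, _ = mrcore.weighted_median(bx, by, sy, n_boot=50, seed=1)
        ivw, _, _ = mrcore.ivw_fixed(bx, by, sy)
        assert abs(med - 0.3) < abs(ivw - 0.3)
        assert abs(med - 0.3) < 0.02

    def test_bootstrap_se_reproducible_given_seed(self):
        bx = np.array([0.2, 0.3, 0.4, 0.5])
        by = 0.3 * bx + np.array([0.01, -0.02, 0.0, 0.015])
        sy = np.full(4, 0.05)
        a = mrcore.weighted_median(bx, by, sy, seed=7)
        b = mrcore.weighted_median(bx, by, sy, seed=7)
        assert a == b


class TestModeEstimators:
    def test_identical_ratios_short_circuit(self):
        bx = np.array([0.2, 0.4, 0.8])
        out = mrcore.mode_estimators(bx, 0.25 * bx, np.full(3, 0.1),
                                     n_boot=10)
        assert out["simple_mode"][0] == pytest.approx(0.25)
        assert out["weighted_mode"][0] == pytest.approx(0.25)

    def test_bimodal_ratios_follow_majority_and_weights(self):
        """6 ratios at 0.1 vs 3 at 0.5: simple mode tracks the majority;
        with the weight mass on the 0.5 cluster the weighted mode moves."""
        bx = np.concatenate([np.full(6, 0.1), np.full(3, 1.0)])
        by = np.concatenate([np.full(6, 0.01), np.full(3, 0.5)])
        sy = np.full(9, 0.05)
        out = mrcore.mode_estimators(bx, by, sy, n_boot=10)
        assert abs(out["simple_mode"][0] - 0.1) < 0.1
        assert abs(out["weighted_mode"][0] - 0.5) < 0.1

    def test_kde_argmax_matches_dense_grid_oracle(self, rng):
        r = rng.normal(0.3, 0.1, size=9)
        w = np.full(9, 1 / 9)
        est = mrcore._kde_mode(r, w, phi=1.0)
        # independent dense evaluation of the same weighted KDE
        mean = (w * r).sum()
        sd = np.sqrt((w * (r - mean) ** 2).sum())
        iqr = (np.percentile(r, 75) - np.percentile(r, 25)) / 1.34
        h = 0.9 * min(sd, iqr if iqr > 0 else sd) * 9 ** (-0.2)
        dense = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 40001)
        dens = np.exp(-0.5 * ((dense[:, None] - r) / h) ** 2).sum(axis=1)
        assert est == pytest.approx(dense[dens.argmax()], abs=2e-3)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.booleans(), min_size=3, max_size=8))
def test_estimators_invariant_to_allele_recoding(flips):
    """Simultaneously flipping (bx, by) for any SNP subset (an allele
    recoding) leaves every estimator unchanged."""
    k = len(flips)
    rng = np.random.default_rng(99)
    bx = rng.uniform(0.1, 0.5, size=k)
    by = 0.3 * bx + rng.normal(0, 0.05, size=k)
    sy = rng.uniform(0.02, 0.1, size=k)
    s = np.where(flips, -1.0, 1.0)

    a = mrcore.ivw_fixed(bx, by, sy)
    b = mrcore.ivw_fixed(s * bx, s * by, sy)
    assert np.allclose(a, b)
    ea = mrcore.egger(bx, 0.1 * bx, by, sy)
    eb = mrcore.egger(s * bx, 0.1 * bx, s * by, sy)
    assert np.allclose(ea, eb)
    ma = mrcore.weighted_median(bx, by, sy, n_boot=20, seed=3)
    mb = mrcore.weighted_median(s * bx, s * by, sy, n_boot=20, seed=3)
    assert ma[0] == pytest.approx(mb[0])


def _hset(k: int, gene="g", outcome="o", theta=0.3, seed=0):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.1, 0.4, size=k)
    table = pd.DataFrame({
        "snp": [f"s{i}" for i in range(k)],
        "beta_exp": bx, "se_exp": 0.02,
        "beta_out": theta * bx + rng.normal(0, 0.02, size=k),
        "se_out": 0.02, "eaf_exp": 0.3, "eaf_out": 0.3,
        "n_exp": 588, "n_out": 20_000})
    return ivselect.HarmonizedSet(gene=gene, outcome=outcome, table=table)


class TestRunGene:
    def test_single_snp_uses_wald_ratio(self):
        results, _ = mrcore.run_gene(_hset(1), n_boot=10)
        assert results[0].method == "wald_ratio"
        assert results[0].nsnp == 1

    def test_average_iv_count_reports_all_six_methods(self):
        results, sens = mrcore.run_gene(_hset(14), n_boot=50)
        methods = {r.method for r in results}
        assert methods == {"ivw_fe", "egger", "weighted_median",
                           "simple_mode", "weighted_mode"}
        assert all(r.nsnp == 14 for r in results)
        assert np.isfinite(sens.q_ivw_p) and np.isfinite(sens.egger_intercept_p)

    def test_binary_outcome_reports_odds_ratio(self):
        results, _ = mrcore.run_gene(_hset(3), binary=True, n_boot=10)
        row = results[0].to_row()
        assert row["or"] == pytest.approx(np.exp(row["estimate"]))

    def test_ci_is_plus_minus_196_se(self):
        results, _ = mrcore.run_gene(_hset(5), n_boot=10)
        r = results[0]
        lo, hi = r.ci95
        assert lo == pytest.approx(r.estimate - 1.96 * r.se, abs=1e-4)
        assert hi == pytest.approx(r.estimate + 1.96 * r.se, abs=1e-4)

    def test_empty_set_rejected(self):
        empty = ivselect.HarmonizedSet(
            gene="g", outcome="o",
            table=_hset(1).table.iloc[0:0])
        with pytest.raises(ValueError):
            mrcore.run_gene(empty)


class TestSelectCausal:
    def test_bonferroni_thresholds_print_as_reported(self):
        assert round(mrcore.bonferroni_alpha(248) * 1e4, 2) == 2.02
        assert round(mrcore.bonferroni_alpha(250) * 1e4, 2) == 2.00

    def test_heterogeneous_gene_excluded_with_reason(self):
        results, sens = mrcore.run_gene(_hset(5, gene="g1"), n_boot=10)
        sens.q_ivw_p = 0.01  # planted heterogeneity verdict
        sens.steiger_passed = True
        results[0].p = 1e-6
        table = mrcore.select_causal([results], [sens], m_tested=10)
        assert len(table.selected) == 0
        assert table.exclusions["g1"] == ["heterogeneity_ivw"]

    def test_recovers_planted_causal_genes_with_zero_fdp(self):
        res = calibration.selection_recovery(n_genes=30, n_causal=6, seed=2)
        assert res["sensitivity"] >= 0.8
        assert res["fdp"] == 0.0


class TestCrossPhenotype:
    @staticmethod
    def _table(outcome, genes, signs=None):
        signs = signs if signs is not None else [1] * len(genes)
        selected = pd.DataFrame({
            "gene": genes, "estimate": signs, "se": 0.1, "p": 1e-6,
            "nsnp": 5, "sign": signs, "consistent_methods": True})
        return mrcore.CausalGeneTable(outcome=outcome, m_tested=100,
                                      alpha=5e-4, selected=selected)

    def test_disjoint_tables_share_nothing(self):
        tables = {"a": self._table("a", ["g1"]),
                  "b": self._table("b", ["g2"])}
        rep = mrcore.cross_phenotype(tables)
        assert rep["n_triple"] == 0
        assert rep["n_unique"] == 2

    def test_published_count_structure_gives_113_unique(self):
        """Outcome sizes (40, 68, 62) with 37 genes in exactly two and 10
        in all three must give 170 - 37 - 2*10 = 113 unique genes."""
        triple = [f"t{i}" for i in range(10)]
        ab = [f"ab{i}" for i in range(5)]
        ac = [f"ac{i}" for i in range(10)]
        bc = [f"bc{i}" for i in range(22)]
        sa = [f"sa{i}" for i in range(15)]
        sb = [f"sb{i}" for i in range(31)]
        sc = [f"sc{i}" for i in range(20)]
        tables = {
            "sarcopenia": self._table("sarcopenia", triple + ab + ac + sa),
            "ALM": self._table("ALM", triple + ab + bc + sb),
            "HGS": self._table("HGS", triple + ac + bc + sc),
        }
        sizes = {o: len(t.selected) for o, t in tables.items()}
        assert sizes == {"sarcopenia": 40, "ALM": 68, "HGS": 62}
        rep = mrcore.cross_phenotype(tables)
        assert rep["n_exactly_two"] == 37
        assert rep["n_exactly_three"] == 10
        assert rep["n_unique"] == 113
        assert rep["unique_by_inclusion_exclusion"] == 113

    def test_consistent_polarity_classification(self):
        genes = ["risk", "prot"]
        tables = {
            "disease": self._table("disease", genes, [1, -1]),
            "lean_mass": self._table("lean_mass", genes, [-1, 1]),
            "grip": self._table("grip", genes, [-1, 1]),
        }
        rep = mrcore.cross_phenotype(tables, binary_outcomes={"disease"})
        assert rep["triple_classification"] == {
            "risk": "consistent_risk", "prot": "consistent_protective"}

    def test_needs_at_least_two_tables(self):
        with pytest.raises(ValueError):
            mrcore.cross_phenotype({"a": self._table("a", ["g"])})
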