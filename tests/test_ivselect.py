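"""Instrument filters, LD clumping, harmonisation, Steiger directionality."""

import numpy as np
import pandas as pd
import pytest

from exmr import calibration, ivselect, synthio


def _stats(rows) -> pd.DataFrame:
    cols = ["snp", "chrom", "pos", "effect_allele", "other_allele", "eaf",
            "beta", "se", "p", "n"]
    return pd.DataFrame(rows, columns=cols)


def _snp(snp, pos=1000, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02,
         p=1e-10, n=588):
    return (snp, "chr1", pos, ea, oa, eaf, beta, se, p, n)


class TestPositionalFilters:
    def test_cis_window_boundaries(self):
        df = _stats([_snp("at_tss", pos=5_000_000),
                     _snp("edge_in", pos=6_000_000),
                     _snp("edge_out", pos=6_000_001)])
        kept = ivselect.cis_filter(df, tss=5_000_000)
        assert list(kept["snp"]) == ["at_tss", "edge_in"]

    def test_cis_matches_linear_scan(self, rng):
        pos = rng.integers(1, 10_000_000, size=300)
        df = _stats([_snp(f"s{i}", pos=int(p)) for i, p in enumerate(pos)])
        tss = 5_000_000
        kept = set(ivselect.cis_filter(df, tss)["snp"])
        expected = {f"s{i}" for i, p in enumerate(pos)
                    if abs(int(p) - tss) <= 1_000_000}
        assert kept == expected

    def test_significance_is_strict(self):
        df = _stats([_snp("at_threshold", p=5e-8), _snp("below", p=4.9e-8)])
        kept = ivselect.significance_filter(df)
        assert list(kept["snp"]) == ["below"]

    def test_significance_count_matches_truth(self, rng):
        ps = np.concatenate([rng.uniform(1e-12, 4e-8, 10),
                             rng.uniform(1e-7, 1, 90)])
        df = _stats([_snp(f"s{i}", p=float(p)) for i, p in enumerate(ps)])
        assert len(ivselect.significance_filter(df)) == 10


class TestWeakFilter:
    def test_f_arithmetic_and_boundary(self):
        assert ivselect.f_statistic(0.5, 0.1) == pytest.approx(25.0)
        df = _stats([_snp("strong", beta=0.5, se=0.1),
                     _snp("weak", beta=0.1, se=0.1),
                     _snp("boundary", beta=np.sqrt(10) * 0.1, se=0.1)])
        kept = ivselect.weak_filter(df)
        assert set(kept["snp"]) == {"strong", "boundary"}

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ivselect.f_statistic([0.1], [0.0])


class TestComputeLd:
    def test_self_and_duplicate_are_one(self, rng):
        g = rng.integers(0, 3, size=(100, 1))
        panel = pd.DataFrame(np.hstack([g, g]), columns=["a", "b"])
        ld = ivselect.compute_ld(panel)
        assert ld.at["a", "a"] == pytest.approx(1.0)
        assert ld.at["a", "b"] == pytest.approx(1.0)

    def test_matches_direct_correlation(self, rng):
        cfg = synthio.SimConfig(seed=9, n_blocks=2, snps_per_block=5,
                                block_rho=0.7)
        panel = synthio.simulate_panel(cfg)
        ld = ivselect.compute_ld(panel.dosages)
        expected = np.corrcoef(panel.dosages.to_numpy(float).T) ** 2
        assert np.allclose(ld.to_numpy(), expected, atol=1e-10)

    def test_monomorphic_zeroed_with_warning(self, rng):
        panel = pd.DataFrame({"mono": np.zeros(60, dtype=int),
                              "poly": rng.integers(0, 3, 60)})
        with pytest.warns(UserWarning):
            ld = ivselect.compute_ld(panel)
        assert ld.at["mono", "poly"] == 0.0
        assert ld.at["mono", "mono"] == 1.0

    def test_missing_snp_raises(self, rng):
        panel = pd.DataFrame({"a": rng.integers(0, 3, 60)})
        with pytest.raises(KeyError):
            ivselect.compute_ld(panel, ["a", "ghost"])


def _ld_from(r2: dict, snps) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=snps, columns=snps)
    np.fill_diagonal(mat.values, 1.0)
    for (a, b), v in r2.items():
        mat.at[a, b] = mat.at[b, a] = v
    return mat


class TestGreedyClump:
    def test_correlated_close_pair_keeps_most_significant(self):
        df = _stats([_snp("lead", pos=1000, p=1e-10),
                     _snp("shadow", pos=6000, p=1e-9)])
        ld = _ld_from({("lead", "shadow"): 0.9}, ["lead", "shadow"])
        kept = ivselect.greedy_clump(df, ld)
        assert list(kept["snp"]) == ["lead"]

    def test_correlated_distant_pair_both_kept(self):
        df = _stats([_snp("a", pos=1000, p=1e-10),
                     _snp("b", pos=51_000, p=1e-9)])
        ld = _ld_from({("a", "b"): 0.9}, ["a", "b"])
        assert len(ivselect.greedy_clump(df, ld)) == 2

    def test_missing_snp_in_ld_named(self):
        df = _stats([_snp("a"), _snp("zzz", pos=2000)])
        ld = _ld_from({}, ["a"])
        with pytest.raises(KeyError, match="zzz"):
            ivselect.greedy_clump(df, ld)

    @staticmethod
    def _random_instance(rng):
        m = int(rng.integers(2, 11))
        pos = np.sort(rng.integers(1, 40_000, size=m))
        df = _stats([_snp(f"s{i}", pos=int(pos[i]),
                          p=float(rng.uniform(1e-12, 1e-6)))
                     for i in range(m)])
        r2 = np.clip(rng.uniform(0, 1, size=(m, m)), 0, 1)
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = pd.DataFrame(r2, index=df["snp"], columns=df["snp"])
        return df, ld

    def test_validity_on_random_instances_matches_bruteforce(self, rng):
        """200 random <=10-SNP instances: the kept set satisfies the
        pairwise criterion, every removed SNP is justified by a kept,
        more significant SNP, and row order does not matter."""
        for _ in range(200):
            df, ld = self._random_instance(rng)
            kept = ivselect.greedy_clump(df, ld)
            kept_set = set(kept["snp"])
            pos = dict(zip(df["snp"], df["pos"]))
            pv = dict(zip(df["snp"], df["p"]))

            for a in kept_set:  # pairwise validity
                for b in kept_set:
                    if a < b:
                        assert ld.at[a, b] < 0.05 or \
                            abs(pos[a] - pos[b]) > 10_000
            for s in set(df["snp"]) - kept_set:  # every removal justified
                assert any(ld.at[s, kposs] >= 0.05 and
                           abs(pos[s] - pos[kposs]) <= 10_000 and
                           (pv[kposs], pos[kposs], kposs) <
                           (pv[s], pos[s], s)
                           for kposs in kept_set)

            shuffled = df.sample(frac=1.0, random_state=0)
            kept2 = ivselect.greedy_clump(shuffled, ld)
            assert set(kept2["snp"]) == kept_set


class TestHarmonize:
    def _pair(self, exp_row, out_row):
        return _stats([exp_row]), _stats([out_row])

    def test_swapped_alleles_negate_outcome_beta(self):
        exp, out = self._pair(_snp("s", ea="A", oa="G", beta=0.5),
                              _snp("s", ea="G", oa="A", beta=0.3, eaf=0.7))
        h = ivselect.harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(-0.3)
        assert h.table["eaf_out"].iloc[0] == pytest.approx(0.3)

    def test_strand_complement_resolved(self):
        exp, out = self._pair(_snp("s", ea="A", oa="G", beta=0.5),
                              _snp("s", ea="T", oa="C", beta=0.3, eaf=0.3))
        h = ivselect.harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.3)

    def test_ambiguous_palindrome_dropped(self):
        exp, out = self._pair(_snp("s", ea="A", oa="T", eaf=0.50),
                              _snp("s", ea="A", oa="T", eaf=0.50))
        h = ivselect.harmonize(exp, out)
        assert len(h.table) == 0
        assert any(a["reason"] == "palindromic_ambiguous_eaf"
                   for a in h.audit)

    def test_informative_palindrome_oriented_by_eaf(self):
        exp, out = self._pair(_snp("s", ea="A", oa="T", eaf=0.10, beta=0.5),
                              _snp("s", ea="T", oa="A", eaf=0.88, beta=0.3))
        h = ivselect.harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(-0.3)

    def test_incompatible_alleles_dropped(self):
        exp, out = self._pair(_snp("s", ea="A", oa="G"),
                              _snp("s", ea="A", oa="C"))
        assert len(ivselect.harmonize(exp, out).table) == 0

    def test_duplicate_ids_rejected(self):
        exp = _stats([_snp("s"), _snp("s")])
        out = _stats([_snp("s")])
        with pytest.raises(ValueError):
            ivselect.harmonize(exp, out)

    def test_idempotent_on_aligned_data(self):
        exp = _stats([_snp("a", beta=0.4), _snp("b", pos=2000, beta=-0.2,
                                                 ea="C", oa="T")])
        out = _stats([_snp("a", beta=0.1), _snp("b", pos=2000, beta=0.2,
                                                ea="C", oa="T")])
        once = ivselect.harmonize(exp, out)
        # feed the aligned outcome back in: nothing should change
        out2 = out.copy()
        out2["beta"] = once.table["beta_out"].to_numpy()
        out2["eaf"] = once.table["eaf_out"].to_numpy()
        twice = ivselect.harmonize(exp, out2)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_corrupted_synthetic_data_recovered(self):
        """With strand/swap corruption at 30%, harmonised outcome effects
        equal the uncorrupted ground truth for every retained SNP."""
        cfg = synthio.SimConfig(seed=21, n_blocks=1, snps_per_block=20,
                                block_rho=0.0, n_exp=500, n_out=1000,
                                flip_fraction=0.3)
        rng = cfg.rng()
        panel = synthio.simulate_panel(cfg, rng)
        maf = panel.meta["maf"].to_numpy()
        gamma = 0.2 / np.sqrt(2 * maf * (1 - maf))
        exp = synthio.simulate_gene_summary(cfg, panel, gamma, rng)
        state = rng.bit_generator.state
        clean, _ = synthio.simulate_outcome_summary(
            cfg, panel, {"g": gamma}, {"g": 0.3}, rng, corrupt=False)
        rng.bit_generator.state = state  # same outcome sample, then corrupt
        corrupted, truth = synthio.simulate_outcome_summary(
            cfg, panel, {"g": gamma}, {"g": 0.3}, rng, corrupt=True)
        assert truth.corrupted_snps  # corruption must actually happen
        h = ivselect.harmonize(exp, corrupted)
        clean_beta = clean.set_index("snp")["beta"]
        for snp, beta in zip(h.table["snp"], h.table["beta_out"]):
            assert beta == pytest.approx(clean_beta[snp], abs=1e-12)


class TestSteiger:
    def _hset(self, beta_out, se_out=0.05, n_out=10_000):
        table = pd.DataFrame({
            "snp": [f"s{i}" for i in range(5)],
            "beta_exp": 0.2, "se_exp": 0.02,
            "beta_out": beta_out, "se_out": se_out,
            "eaf_exp": 0.3, "eaf_out": 0.3,
            "n_exp": 5000, "n_out": n_out})
        return ivselect.HarmonizedSet(gene="g", outcome="o", table=table)

    def test_zero_outcome_signal_passes(self):
        res = ivselect.steiger_filter(self._hset(beta_out=0.0))
        assert res.direction_ok and res.passed and res.p < 1e-6

    def test_symmetric_signal_is_null(self):
        h = self._hset(beta_out=0.2, se_out=0.02, n_out=5000)
        res = ivselect.steiger_filter(h)
        assert res.p == pytest.approx(1.0)
        assert not res.passed

    def test_valid_instruments_almost_always_pass(self):
        rate = calibration.steiger_pass_rate(n_rep=40, seed=8)
        assert rate >= 0.95

    def test_tiny_samples_rejected(self):
        h = self._hset(beta_out=0.0)
        h.table["n_out"] = 3
        with pytest.raises(ValueError):
            ivselect.steiger_filter(h)


class TestSelectInstruments:
    def test_stage_counts_account_for_every_snp(self, small_study):
        gene = next(iter(small_study.exposures))
        outcome = next(iter(small_study.outcomes))
        hset, counts = ivselect.select_instruments(
            small_study.exposures[gene], small_study.outcomes[outcome],
            small_study.panel.dosages, tss=small_study.gene_tss[gene],
            gene=gene, outcome=outcome)
        stages = ["input", "cis", "significance", "clump", "weak",
                  "harmonize"]
        assert list(counts) == stages
        for before, after in zip(stages, stages[1:]):
            dropped = sum(1 for a in hset.audit
                          if a["stage"] == after and a["action"] == "drop")
            assert counts[before] == counts[after] + dropped
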