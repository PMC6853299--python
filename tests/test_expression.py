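"""RPKM, detectability/ASE filters, d-score, log ratios and the NB
differential-expression contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from hybridreg import expression, simulate
from hybridreg.alleles import AlleleCountTable
from hybridreg.expression import (allelic_log_ratios, d_score,
                                  filter_ase_eligible, filter_detectable,
                                  fold_change_filter, parental_log_ratio,
                                  rpkm, sde_test)


def _groups(**kw):
    return pd.Series(kw)


class TestRpkm:
    def test_formula(self):
        counts = pd.DataFrame({"s1": [10, 0]}, index=["g1", "g2"])
        out = rpkm(counts, pd.Series({"g1": 1000, "g2": 500}),
                   pd.Series({"s1": 1_000_000}))
        assert out.loc["g1", "s1"] == pytest.approx(10.0)
        assert out.loc["g2", "s1"] == 0.0

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(20, 4)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 5000, 20).astype(float),
                            index=counts.index)
        libs = pd.Series(rng.integers(10 ** 5, 10 ** 7, 4).astype(float),
                         index=counts.columns)
        out = rpkm(counts, lengths, libs)
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (lengths[g] * libs[s])
                assert out.loc[g, s] == pytest.approx(expected)

    def test_zero_length_raises(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            rpkm(counts, pd.Series({"g1": 0}), pd.Series({"s1": 1e6}))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_invariant_to_joint_scaling(self, scale):
        counts = pd.DataFrame({"s1": [50.0]}, index=["g1"])
        lengths = pd.Series({"g1": 1000.0})
        base = rpkm(counts, lengths, pd.Series({"s1": 1e6}))
        scaled = rpkm(counts * scale, lengths, pd.Series({"s1": 1e6 * scale}))
        assert np.isclose(base, scaled).all()


class TestFilters:
    GROUPS = _groups(z1="ZF", z2="ZF", o1="OF", o2="OF")

    def test_detectable_either_species(self):
        expr = pd.DataFrame({"z1": [0.4, 0.9], "z2": [0.6, 0.9],
                             "o1": [1.1, 0.9], "o2": [1.3, 0.9]},
                            index=["keep", "drop"])
        kept = filter_detectable(expr, self.GROUPS)
        assert list(kept) == ["keep"]

    def test_detectable_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.uniform(0, 3, size=(10, 4)),
                            index=[f"g{i}" for i in range(10)],
                            columns=["z1", "z2", "o1", "o2"])
        kept = set(filter_detectable(expr, self.GROUPS))
        for g in expr.index:
            zf = expr.loc[g, ["z1", "z2"]].mean()
            of = expr.loc[g, ["o1", "o2"]].mean()
            assert (g in kept) == (zf >= 1 or of >= 1)

    def _table(self, depth):
        rows = []
        for ind in ("ZO_1", "ZO_2"):
            rows.append(("g1", ind, "chr1", 10, depth, depth))
        return AlleleCountTable(pd.DataFrame(
            rows, columns=AlleleCountTable.COLUMNS))

    def test_ase_eligibility_reasons(self):
        expr = pd.DataFrame(
            {f"i{k}": [50.0, 50.0, 9.99] for k in range(16)},
            index=["g1", "g2", "g3"])
        table = self._table(depth=10)
        kept, report = filter_ase_eligible(table, expr)
        assert list(kept) == ["g1"]
        assert not report.loc["g2", "has_snp"]     # no ss-SNP counts
        assert not report.loc["g3", "rpkm_ok"]     # median RPKM 9.99 < 10

    def test_min_reads_boundary_inclusive_vs_strict(self):
        expr = pd.DataFrame({f"i{k}": [50.0] for k in range(16)},
                            index=["g1"])
        table = self._table(depth=2)  # site depth 4 < 5 either way... use 5
        table = AlleleCountTable(pd.DataFrame(
            [("g1", "ZO_1", "chr1", 10, 3, 2)],
            columns=AlleleCountTable.COLUMNS))  # depth exactly 5
        kept_inc, _ = filter_ase_eligible(table, expr, min_reads=5,
                                          strict=False)
        kept_strict, _ = filter_ase_eligible(table, expr, min_reads=5,
                                             strict=True)
        assert list(kept_inc) == ["g1"]
        assert list(kept_strict) == []


class TestDScore:
    @pytest.mark.parametrize("a,b,expected", [
        (10, 10, 0.0),    # balanced expression
        (20, 0, 0.5),     # exclusive species-1 transcription
        (0, 20, -0.5),    # exclusive species-2 transcription
        (15, 5, 0.25),
    ])
    def test_reference_values(self, a, b, expected):
        assert d_score(a, b) == pytest.approx(expected)

    def test_undefined_for_zero_total(self):
        with pytest.raises(ValueError, match="undefined"):
            d_score(0, 0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.integers(0, 10 ** 6))
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        d = d_score(a, b)
        assert -0.5 <= d <= 0.5
        assert d == pytest.approx(-d_score(b, a))


class TestLogRatios:
    def test_x_from_species_average_rpkm(self):
        groups = _groups(z1="ZF", z2="ZF", o1="OF", o2="OF")
        expr = pd.DataFrame({"z1": [20.0], "z2": [20.0],
                             "o1": [10.0], "o2": [10.0]}, index=["g1"])
        assert parental_log_ratio(expr, groups).loc["g1"] == pytest.approx(1.0)

    def test_balanced_alleles_give_zero_y(self):
        table = AlleleCountTable(pd.DataFrame(
            [("g1", "ZO_1", "chr1", 1, 30, 30)],
            columns=AlleleCountTable.COLUMNS))
        y = allelic_log_ratios(table)
        assert y.loc["g1", "ZO_1"] == pytest.approx(0.0)

    def test_zero_pseudocount_with_zero_counts_raises(self):
        table = AlleleCountTable(pd.DataFrame(
            [("g1", "ZO_1", "chr1", 1, 10, 0)],
            columns=AlleleCountTable.COLUMNS))
        with pytest.raises(ValueError, match="pseudocount 0"):
            allelic_log_ratios(table, pseudocount=0)

    def test_simulated_cis_and_trans_gene_recovers_x2_y1(self):
        # c = 1, t = 1, deep coverage: X ~ 2, mean Y ~ 1
        cfg = simulate.SimulationConfig(
            n_genes=30, seed=6, nb_dispersion=1e-4,
            baseline_mean_dist=50_000.0, per_snp_depth_dist=20_000,
            cis_effect_dist=lambda rng, size: np.ones(size),
            trans_effect_dist=lambda rng, size: np.ones(size),
            class_proportions={"cis_and_trans": 1.0})
        arch, sc = simulate.simulate_dataset(cfg)
        pos = (arch["cis_effect"] > 0) & (arch["trans_effect"] > 0)
        all_counts = pd.concat([sc.parental_counts, sc.f1_counts], axis=1)
        expr = rpkm(all_counts, sc.gene_lengths, sc.library_sizes)
        x = parental_log_ratio(expr, sc.groups)
        y = allelic_log_ratios(sc.allele_counts)
        assert np.allclose(x[pos], 2.0, atol=0.1)
        assert np.allclose(y.loc[pos].mean(axis=1), 1.0, atol=0.05)


class TestSdeTest:
    GROUPS = _groups(**{f"z{i}": "ZF" for i in range(4)},
                     **{f"o{i}": "OF" for i in range(4)})

    def _counts(self, rng, n=200, fc_genes=0, fold=4.0):
        mu = rng.lognormal(np.log(200), 1, n)
        mean_a = mu.copy()
        mean_a[:fc_genes] *= fold
        cols = {}
        for i in range(4):
            cols[f"z{i}"] = rng.poisson(mean_a)
        for i in range(4):
            cols[f"o{i}"] = rng.poisson(mu)
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])

    def test_identical_groups_null(self):
        counts = pd.DataFrame(
            {c: [100, 200] for c in self.GROUPS.index},
            index=["g1", "g2"])
        res = sde_test(counts, self.GROUPS)
        assert (res["p_adj"] > 0.9).all()

    def test_bh_adjustment_closed_form(self):
        # BH on (0.01, 0.02, 0.03, 0.04) with m = 4 gives all 0.04
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_all_zero_gene_flagged_p1(self):
        counts = pd.DataFrame(
            {c: [0, 100] for c in self.GROUPS.index}, index=["g0", "g1"])
        res = sde_test(counts, self.GROUPS)
        assert res.loc["g0", "degenerate"]
        assert res.loc["g0", "p"] == 1.0

    def test_empirical_fdr_controlled_on_simulation(self):
        rng = np.random.default_rng(8)
        n, fc_genes = 1000, 100
        counts = self._counts(rng, n=n, fc_genes=fc_genes)
        res = sde_test(counts, self.GROUPS)
        called = res["p_adj"] < 0.05
        true = np.zeros(n, dtype=bool)
        true[:fc_genes] = True
        fdr = (called & ~true).sum() / max(called.sum(), 1)
        assert fdr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / max(called.sum(), 1))
        # and the strong signals are mostly found
        assert called[:fc_genes].mean() > 0.8

    def test_fold_change_filter_boundary_and_brute_force(self):
        rng = np.random.default_rng(9)
        counts = self._counts(rng, n=100, fc_genes=20, fold=8.0)
        res = sde_test(counts, self.GROUPS, "ZF", "OF")
        kept = set(fold_change_filter(counts, self.GROUPS, "ZF", "OF"))
        for g in counts.index:
            expected = (abs(res.loc[g, "log2_fc"]) > 2.0
                        and res.loc[g, "p"] < 0.05)
            assert (g in kept) == expected
        # a gene at exactly 4-fold is excluded by the strict inequality
        exact = pd.DataFrame(
            {**{f"z{i}": [400] for i in range(4)},
             **{f"o{i}": [100] for i in range(4)}}, index=["g"])
        lib = pd.Series(1e6, index=exact.columns)
        assert list(fold_change_filter(exact, self.GROUPS, "ZF", "OF",
                                       library_sizes=lib)) == []
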