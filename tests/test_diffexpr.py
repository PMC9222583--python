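"""Library-size normalization, dispersion, NB exact test, tiers, FPKM,
and the two artifact diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ecomorphdiv import diffexpr
from ecomorphdiv.io_formats import SampleSheet

from _oracles import fisher_two_sided_oracle, nb_exact_test_oracle
from conftest import two_morph_sheet


def _counts_frame(data, prefix="s"):
    data = np.asarray(data)
    return pd.DataFrame(
        data,
        index=[f"g{i}" for i in range(data.shape[0])],
        columns=[f"{prefix}{j}" for j in range(data.shape[1])],
    )


class TestNormalizeLibsizes:
    def test_identical_samples_equal_sizes(self, rng):
        col = rng.poisson(50, size=200)
        counts = _counts_frame(np.column_stack([col, col]))
        sizes = diffexpr.normalize_libsizes(counts)
        assert sizes.iloc[0] == pytest.approx(sizes.iloc[1])

    def test_doubled_sample_ratio_two(self, rng):
        col = rng.poisson(50, size=200) + 1
        counts = _counts_frame(np.column_stack([col, 2 * col]))
        sizes = diffexpr.normalize_libsizes(counts)
        assert sizes.iloc[1] / sizes.iloc[0] == pytest.approx(2.0)

    def test_asymmetric_de_nulls_centered(self, rng):
        # 5% of genes strongly up in sample B must not shift null genes
        n = 2000
        base = rng.poisson(100, size=n) + 1
        b = base.copy()
        de = rng.choice(n, size=n // 20, replace=False)
        b[de] *= 16
        counts = _counts_frame(np.column_stack([base, b]))
        sizes = diffexpr.normalize_libsizes(counts)
        norm = counts / sizes * sizes.mean()
        null = np.setdiff1d(np.arange(n), de)
        log_ratio = np.log2(norm.iloc[null, 1] / norm.iloc[null, 0])
        assert abs(np.median(log_ratio)) < 0.05

    def test_all_zero_sample_rejected(self):
        counts = _counts_frame([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            diffexpr.normalize_libsizes(counts)


class TestDispersion:
    def _sim(self, rng, phi, n_genes=5000, mean=120):
        sheet = two_morph_sheet(n_pools=3, tissues=("radula",))
        means = rng.lognormal(np.log(mean), 0.5, size=n_genes)
        if phi > 0:
            lam = rng.gamma(1 / phi, phi * means[:, None],
                            size=(n_genes, len(sheet)))
        else:
            lam = np.repeat(means[:, None], len(sheet), axis=1)
        counts = pd.DataFrame(
            rng.poisson(lam),
            index=[f"g{i}" for i in range(n_genes)],
            columns=list(sheet.samples),
        )
        return counts, sheet

    def test_poisson_counts_near_zero(self, rng):
        counts, sheet = self._sim(rng, phi=0.0)
        phi_hat = diffexpr.estimate_dispersion(
            counts, sheet, diffexpr.normalize_libsizes(counts)
        )
        assert phi_hat <= 0.02

    def test_nb_phi_02_recovered(self, rng):
        counts, sheet = self._sim(rng, phi=0.2)
        phi_hat = diffexpr.estimate_dispersion(
            counts, sheet, diffexpr.normalize_libsizes(counts)
        )
        assert 0.14 <= phi_hat <= 0.26  # within +-30%

    def test_constant_counts_zero(self):
        sheet = two_morph_sheet(n_pools=3, tissues=("radula",))
        counts = pd.DataFrame(
            np.full((100, len(sheet)), 50),
            index=[f"g{i}" for i in range(100)],
            columns=list(sheet.samples),
        )
        phi_hat = diffexpr.estimate_dispersion(
            counts, sheet, diffexpr.normalize_libsizes(counts)
        )
        assert phi_hat == 0.0

    def test_no_expressed_gene_error(self):
        sheet = two_morph_sheet(n_pools=3, tissues=("radula",))
        counts = pd.DataFrame(
            np.ones((10, len(sheet)), dtype=int),
            index=[f"g{i}" for i in range(10)],
            columns=list(sheet.samples),
        )
        with pytest.raises(ValueError, match="mean >= 5"):
            diffexpr.estimate_dispersion(counts, sheet, counts.sum())


class TestExactTest:
    LIB = np.array([1.0, 1.0, 1.0])

    def test_identical_sums_p_one(self):
        p, lfc = diffexpr.exact_test(
            np.array([50, 60, 70]), np.array([70, 60, 50]),
            self.LIB, self.LIB, 0.1,
        )
        assert p == 1.0
        assert lfc == pytest.approx(0.0, abs=0.01)

    def test_eightfold_shift_tiny_p(self):
        p, lfc = diffexpr.exact_test(
            np.array([100, 100, 100]), np.array([800, 800, 800]),
            self.LIB, self.LIB, 0.01,
        )
        assert p < 1e-10
        assert lfc == pytest.approx(3.0, abs=0.02)

    def test_zero_group_sign(self):
        p, lfc = diffexpr.exact_test(
            np.array([0, 0, 0]), np.array([500, 400, 450]),
            self.LIB, self.LIB, 0.05,
        )
        assert lfc > 5
        p2, lfc2 = diffexpr.exact_test(
            np.array([500, 400, 450]), np.array([0, 0, 0]),
            self.LIB, self.LIB, 0.05,
        )
        assert lfc2 < -5

    def test_both_groups_zero(self):
        p, lfc = diffexpr.exact_test(
            np.zeros(3), np.zeros(3), self.LIB, self.LIB, 0.1
        )
        assert p == 1.0 and lfc == 0.0

    @pytest.mark.parametrize(
        "s1,s2,phi",
        [(300, 450, 0.05), (120, 80, 0.2), (30, 90, 0.01), (500, 510, 0.1)],
    )
    def test_matches_enumeration_oracle(self, s1, s2, phi):
        c1 = np.array([s1 // 3, s1 // 3, s1 - 2 * (s1 // 3)])
        c2 = np.array([s2 // 3, s2 // 3, s2 - 2 * (s2 // 3)])
        p, _ = diffexpr.exact_test(c1, c2, self.LIB, self.LIB, phi)
        expected = nb_exact_test_oracle(int(c1.sum()), int(c2.sum()), 3, 3, phi)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_poisson_limit_binomial(self):
        # phi ~ 0 falls back to the exact binomial split
        from scipy.stats import binom

        c1, c2 = np.array([10, 12, 8]), np.array([20, 22, 18])
        p, _ = diffexpr.exact_test(c1, c2, self.LIB, self.LIB, 0.0)
        s1, total = 30, 90
        left = binom.cdf(s1, total, 0.5)
        right = 1 - binom.cdf(s1 - 1, total, 0.5)
        assert p == pytest.approx(min(1.0, 2 * min(left, right)), rel=1e-9)


class TestTiers:
    def _single(self, pvalue, log2fc, tissue="radula"):
        de = pd.DataFrame(
            {"gene": ["g1"], "tissue": [tissue], "log2fc": [log2fc],
             "pvalue": [pvalue]}
        )
        return diffexpr.classify_tiers(de).iloc[0]

    @pytest.mark.parametrize(
        "p,lfc,tier",
        [
            (1e-3, np.log2(5), "DE"),        # clears DE, misses highlyDE
            (1e-12, np.log2(3.9), "none"),   # FDR fine, FC fails
            (1e-11, np.log2(6), "highlyDE"),
            (1e-12, -np.log2(6), "highlyDE"),  # down-regulation counts too
            (0.5, 5.0, "none"),
            (1e-3, 2.0, "DE"),               # |log2FC| exactly at the gate
            (5e-2, 5.0, "none"),             # FDR above 1e-2
        ],
    )
    def test_threshold_grid(self, p, lfc, tier):
        assert self._single(p, lfc)["tier"] == tier

    def test_bh_within_tissue_and_nesting(self, rng):
        rows = []
        for tissue in ("radula", "mantle", "foot"):
            pv = rng.random(200)
            pv[:5] = 1e-15
            for i, p in enumerate(pv):
                rows.append((f"g{i}", tissue, 4.0, p))
        de = diffexpr.classify_tiers(
            pd.DataFrame(rows, columns=["gene", "tissue", "log2fc", "pvalue"])
        )
        # BH monotone in p within each tissue
        for _, grp in de.groupby("tissue"):
            srt = grp.sort_values("pvalue")
            assert srt["fdr"].is_monotonic_increasing
        # highlyDE subset of DE thresholds
        high = de[de["tier"] == "highlyDE"]
        assert (high["fdr"] <= 1e-10).all()
        assert set(high.index) <= set(de[de["tier"] != "none"].index)


class TestFpkm:
    def test_formula_examples(self):
        sheet = SampleSheet(("a",), ("wood",), ("radula",), (1,))
        counts = pd.DataFrame({"a": [10, 0, 5]}, index=["g1", "g2", "g3"])
        lengths = pd.Series({"g1": 1000, "g2": 1000, "g3": 500})
        libs = pd.Series({"a": 1e6})
        tab = diffexpr.fpkm_summary(counts, lengths, sheet, libs)
        vals = tab.set_index("gene")["mean_fpkm"]
        assert vals["g1"] == pytest.approx(10.0)
        assert vals["g2"] == 0.0
        assert tab.set_index("gene").loc["g2", "expressed"] == False  # noqa: E712
        libs2 = pd.Series({"a": 5e5})
        tab2 = diffexpr.fpkm_summary(counts, lengths, sheet, libs2)
        assert tab2.set_index("gene").loc["g3", "mean_fpkm"] == pytest.approx(20.0)

    def test_expressed_aggregation(self):
        fpkm_tab = pd.DataFrame(
            {
                "gene": ["g1", "g1"],
                "tissue": ["radula", "radula"],
                "morph": ["wood", "rock"],
                "mean_fpkm": [2.0, 0.1],
                "expressed": [True, False],
            }
        )
        either = diffexpr.expressed_in_tissue(fpkm_tab, "either")
        both = diffexpr.expressed_in_tissue(fpkm_tab, "both")
        assert either["expressed"].iloc[0]
        assert not both["expressed"].iloc[0]


class TestMappingBias:
    def test_equal_proportions(self):
        # DE proportion 2/10 in the af stratum and 18/90 in the rest
        af = pd.Series(False, index=range(100))
        af[list(range(10))] = True
        de = pd.Series(False, index=range(100))
        de[[0, 1]] = True
        de[list(range(20, 38))] = True
        odds, p, table = diffexpr.mapping_bias_test(de, af)
        assert odds == pytest.approx(1.0)
        assert p == 1.0

    def test_matches_hypergeometric_oracle(self):
        af = pd.Series([True] * 100 + [False] * 100, index=range(200))
        de = pd.Series([True] * 20 + [False] * 80 + [True] * 5 + [False] * 95,
                       index=range(200))
        _, p, table = diffexpr.mapping_bias_test(de, af)
        assert table.tolist() == [[20, 80], [5, 95]]
        assert p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)

    def test_degenerate_margin_warns(self):
        de = pd.Series(True, index=range(50))
        af = pd.Series([True] * 25 + [False] * 25, index=range(50))
        with pytest.warns(UserWarning, match="degenerate"):
            _, p, _ = diffexpr.mapping_bias_test(de, af)
        assert p == 1.0


class TestAlleleCollapse:
    def _high(self, genes_lfc, tissue="radula"):
        return pd.DataFrame(
            {
                "gene": list(genes_lfc),
                "tissue": tissue,
                "log2fc": list(genes_lfc.values()),
                "tier": "highlyDE",
            }
        )

    def test_identical_opposite_flagged(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        high = self._high({"gA": 3.0, "gB": -3.0})
        pairs, frac = diffexpr.allele_collapse_check(high, {"gA": seq, "gB": seq})
        assert len(pairs) == 1
        assert frac["radula"] == 1.0

    def test_random_unrelated_not_flagged(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = "".join(rng.choice(list("ACGT"), size=400))
        high = self._high({"gA": 3.0, "gB": -3.0})
        pairs, frac = diffexpr.allele_collapse_check(high, {"gA": a, "gB": b})
        assert len(pairs) == 0
        assert frac["radula"] == 0.0

    def test_96pct_identity_over_60pct_flagged(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        # 60% of a with ~2% mismatches, plus an unrelated tail
        core = list(a[:180])
        for pos in range(0, 180, 60):  # 3 mismatches -> ~98% identity
            core[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[core[pos]]
        b = "".join(core) + "".join(rng.choice(list("ACGT"), size=120))
        high = self._high({"gA": 3.0, "gB": -3.0})
        pairs, _ = diffexpr.allele_collapse_check(high, {"gA": a, "gB": b})
        assert len(pairs) == 1
        assert pairs["identity"].iloc[0] > 0.95

    def test_same_direction_not_compared(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        high = self._high({"gA": 3.0, "gB": 3.0})
        pairs, frac = diffexpr.allele_collapse_check(high, {"gA": seq, "gB": seq})
        assert len(pairs) == 0
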