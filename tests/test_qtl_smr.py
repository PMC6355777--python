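"""cis-QTL mapping, SMR, HEIDI, intersect rule, correlations, conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from postgwas.qtl_smr import (_ols_assoc, cis_pairs, conditional_eqtl, fit_qtl,
                              gene_correlation, heidi_test, intersect_rule, run_smr,
                              smr_test)


class TestCisPairs:
    def _features(self):
        return pd.DataFrame({
            "feature_id": ["fA", "fB", "fC"],
            "gene": ["gA", "gB", "gC"],
            "chrom": "chr1",
            "tss": [1_000_000, 2_000_000, 2_000_001],
        })

    def test_window_inclusive_boundary(self):
        snps = pd.DataFrame({"id": ["s"], "chrom": "chr1", "pos": [1_000_000],
                             "is_enhancer": [True], "gene": [""]})
        out = cis_pairs(snps, self._features(), window=1_000_000)
        # fB at exactly 1 Mb is included; fC at 1 Mb + 1 is not
        assert set(out["feature_id"]) == {"fA", "fB"}

    def test_non_enhancer_host_gene_only(self):
        snps = pd.DataFrame({"id": ["s"], "chrom": "chr1", "pos": [1_000_000],
                             "is_enhancer": [False], "gene": ["gB"]})
        out = cis_pairs(snps, self._features())
        assert set(out["feature_id"]) == {"fB"}

    def test_no_host_gene_no_pairs(self):
        snps = pd.DataFrame({"id": ["s"], "chrom": "chr1", "pos": [10],
                             "is_enhancer": [False], "gene": [""]})
        assert len(cis_pairs(snps, self._features())) == 0


class TestOLS:
    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.integers(0, 3, 60).astype(float)
            y = 0.3 * x + rng.normal(size=60)
            b, se, p, degen = _ols_assoc(x, y)
            ref = sps.linregress(x, y)
            assert not degen
            assert b == pytest.approx(ref.slope)
            assert se == pytest.approx(ref.stderr)
            assert p == pytest.approx(ref.pvalue)

    def test_constant_genotype_degenerate(self):
        _, _, p, degen = _ols_assoc(np.ones(10), np.arange(10.0))
        assert degen and p == 1.0


class TestFitQTL:
    def test_planted_eqtl_significant(self, panel, pheno):
        row = pheno.causal_map[pheno.causal_map["analysis"] == "eQTL"].iloc[0]
        pairs = pd.DataFrame({"id": [row["snp_id"]], "feature_id": [row["gene"]],
                              "gene": [row["gene"]]})
        dosages = pd.DataFrame(panel.dosages.T, index=panel.variants["id"].to_numpy(),
                               columns=panel.samples)
        out = fit_qtl(pairs, dosages, pheno.expression["brain"], "eQTL", "brain")
        assert out["q"].iloc[0] < 1e-8

    def test_missing_ids_skipped(self, panel, pheno):
        pairs = pd.DataFrame({"id": ["nope"], "feature_id": ["nah"], "gene": ["x"]})
        dosages = pd.DataFrame(panel.dosages.T, index=panel.variants["id"].to_numpy(),
                               columns=panel.samples)
        out = fit_qtl(pairs, dosages, pheno.expression["brain"], "eQTL", "brain")
        assert len(out) == 0


class TestSMR:
    def test_symmetric_z_worked_example(self):
        # z_gwas = z_eqtl = 2 -> T = 16/8 = 2
        res = smr_test(b_gwas=0.2, se_gwas=0.1, b_eqtl=0.4, se_eqtl=0.2)
        assert res["t_smr"] == pytest.approx(2.0)
        assert res["p_smr"] == pytest.approx(float(sps.chi2.sf(2.0, 1)))
        assert res["b_xy"] == pytest.approx(0.5)

    def test_limited_by_weaker_zscore(self):
        # huge eQTL z: T -> z_gwas^2
        res = smr_test(0.3, 0.1, 10.0, 0.01)
        assert res["t_smr"] == pytest.approx(9.0, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            smr_test(0.1, 0.0, 0.2, 0.1)
        with pytest.raises(ValueError):
            smr_test(0.1, 0.1, 0.0, 0.1)


class TestHEIDI:
    def _homogeneous(self, m=6):
        se_e = np.full(m, 0.02)
        se_g = np.full(m, 0.01)
        b_e = np.full(m, 0.5)
        b_g = 0.4 * b_e  # identical b_xy everywhere
        R = np.eye(m)
        return b_g, se_g, b_e, se_e, R

    def test_homogeneous_high_p(self):
        b_g, se_g, b_e, se_e, R = self._homogeneous()
        res = heidi_test(b_g, se_g, b_e, se_e, R, top=0)
        assert res["p_heidi"] > 0.9

    def test_heterogeneous_low_p(self):
        b_g, se_g, b_e, se_e, R = self._homogeneous()
        b_g = b_g.copy()
        b_g[3] = -b_g[3]  # one instrument with an opposite trait effect
        res = heidi_test(b_g, se_g, b_e, se_e, R, top=0)
        assert res["p_heidi"] < 1e-6

    def test_too_few_instruments_absent(self):
        b_g, se_g, b_e, se_e, R = self._homogeneous(m=3)
        # only 2 non-top SNPs -> below the minimum of 3 -> p absent
        res = heidi_test(b_g, se_g, b_e, se_e, R, top=0)
        assert np.isnan(res["p_heidi"]) and res["n_instruments"] == 2

    def test_weak_instruments_excluded(self):
        b_g, se_g, b_e, se_e, R = self._homogeneous()
        b_e = b_e.copy()
        b_e[1:] = 0.001  # eQTL p >> 1.6e-3 for all but the top SNP
        res = heidi_test(b_g, se_g, b_e, se_e, R, top=0)
        assert np.isnan(res["p_heidi"]) and res["n_instruments"] == 0

    def test_prune_near_duplicates_of_top(self):
        b_g, se_g, b_e, se_e, R = self._homogeneous()
        R = R.copy()
        R[0, 1] = R[1, 0] = 0.99  # r^2 ~ 0.98 > 0.9 with the top SNP
        res = heidi_test(b_g, se_g, b_e, se_e, R, top=0)
        assert res["n_instruments"] == 4


class TestRunSMR:
    def _tables(self):
        gwas = pd.DataFrame({"id": ["s1", "s2", "s3", "s4"],
                             "b": [0.06, 0.05, 0.055, 0.001],
                             "se": [0.01, 0.01, 0.01, 0.01]})
        eqtl = pd.DataFrame({"id": ["s1", "s2", "s3", "s4"],
                             "gene": ["gA"] * 4,
                             "beta": [0.6, 0.5, 0.55, 0.02],
                             "se": [0.05, 0.05, 0.05, 0.05],
                             "p": [1e-30, 1e-22, 1e-25, 0.7]})
        return gwas, eqtl

    def test_pass_flag(self):
        gwas, eqtl = self._tables()
        out = run_smr(gwas, eqtl, lambda ids: np.eye(len(ids)), "brain")
        row = out.iloc[0]
        assert row["top_snp"] == "s1"
        assert row["q_smr"] < 0.05 and row["p_eqtl_top"] < 0.05
        assert bool(row["pass_smr"])

    def test_heidi_absent_policy(self):
        gwas, eqtl = self._tables()
        eqtl = eqtl.copy()
        eqtl.loc[1:, "p"] = 0.5  # no eligible instruments -> HEIDI absent
        lenient = run_smr(gwas, eqtl, lambda ids: np.eye(len(ids)), "brain")
        strict = run_smr(gwas, eqtl, lambda ids: np.eye(len(ids)), "brain",
                         heidi_absent_fails=True)
        assert bool(lenient["pass_smr"].iloc[0])
        assert not bool(strict["pass_smr"].iloc[0])

    def test_intersect_rule(self):
        eqtl_genes = {"brain": {"a", "b"}, "blood": {"b", "c"}}
        smr_pass = {"brain": {"b"}, "blood": {"c", "d"}}
        out = intersect_rule(eqtl_genes, smr_pass)
        assert out["per_class"]["brain"] == {"b"}
        assert out["per_class"]["blood"] == {"c"}
        assert out["union"] == {"b", "c"}


class TestCorrelationAndConditioning:
    def test_pearson_frozen_toy(self):
        expr = pd.DataFrame([[1, 2, 3, 4, 5], [2, 1, 4, 3, 6]],
                            index=["gA", "gB"], dtype=float)
        out = gene_correlation(expr, [("gA", "gB"), ("gA", "gA")])
        r_ref, p_ref = sps.pearsonr([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert out["r"].iloc[0] == pytest.approx(float(r_ref))
        assert out["p"].iloc[0] == pytest.approx(float(p_ref))
        assert out["r"].iloc[1] == 1.0

    def test_conditioning_removes_mediated_signal(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 3, 400).astype(float)
        mediator = 0.9 * x + 0.3 * rng.normal(size=400)
        target = 1.0 * mediator + 0.3 * rng.normal(size=400)
        res = conditional_eqtl(x, target, np.array([mediator]))
        assert res["p_unadjusted"] < 1e-10
        assert res["p_conditional"] > 1e-4  # mediated association collapses

    def test_independent_signal_survives(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 3, 400).astype(float)
        cov = rng.normal(size=400)
        target = 0.5 * x + cov + 0.5 * rng.normal(size=400)
        res = conditional_eqtl(x, target, np.array([cov]))
        assert res["still_significant"]

    def test_no_covariates_equals_unadjusted(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 3, 100).astype(float)
        y = rng.normal(size=100)
        res = conditional_eqtl(x, y, None)
        assert res["p_conditional"] == res["p_unadjusted"]
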