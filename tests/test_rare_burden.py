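"""Rare-variant QC, Hardy–Weinberg, Firth regression, burden tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from celliability import rare_burden as rb
from celliability.synthetic import VariantTable


def make_samples(n, seed=0, cases=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"sample_id": [f"S{i:04d}" for i in range(n)]})
    df["status"] = (np.arange(n) < (cases if cases is not None else n // 2)).astype(int)
    df["sex"] = rng.integers(0, 2, n)
    df["platform"] = rng.integers(0, 2, n)
    df["mean_depth"] = rng.uniform(25, 50, n)
    df["ancestry_ok"] = True
    for j in range(10):
        df[f"PC{j + 1}"] = rng.normal(size=n)
    df["synonymous_count"] = rng.poisson(20, n)
    return df


class TestSampleQc:
    def _kin(self, pairs):
        return pd.DataFrame(pairs, columns=["id1", "id2", "kinship"])

    def test_related_pair_loses_one_member(self):
        samples = make_samples(4)
        kin = self._kin([("S0000", "S0001", 0.2)])
        out = rb.sample_qc(samples, kin)
        assert len(out) == 3
        assert len({"S0000", "S0001"} & set(out["sample_id"])) == 1

    def test_threshold_is_strict(self):
        samples = make_samples(4)
        kin = self._kin([("S0000", "S0001", 0.177)])
        assert len(rb.sample_qc(samples, kin)) == 4

    def test_chain_removes_middle_sample_only(self):
        samples = make_samples(5)
        kin = self._kin([("S0000", "S0001", 0.2), ("S0001", "S0002", 0.25)])
        out = rb.sample_qc(samples, kin)
        kept = set(out["sample_id"])
        assert "S0001" not in kept
        assert {"S0000", "S0002"} <= kept

    def test_depth_and_ancestry_filters(self):
        samples = make_samples(5)
        samples.loc[0, "mean_depth"] = 19.9
        samples.loc[1, "mean_depth"] = 20.0  # boundary: kept
        samples.loc[2, "ancestry_ok"] = False
        out = rb.sample_qc(samples, self._kin([]))
        assert set(out["sample_id"]) == {"S0001", "S0003", "S0004"}


def toy_variant_table(n_samples=20, seed=0):
    rng = np.random.default_rng(seed)
    samples = make_samples(n_samples, seed=seed)
    variants = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(4)],
        "chrom": "1", "pos": [100, 200, 300, 400],
        "ref": "C", "alt": "T",
        "gene_id": ["gA", "gA", "gB", "gB"],
        "consequence": ["stop_gained", "synonymous", "missense", "frameshift"],
        "in_external_ref": False, "vqsr_pass": True, "low_complexity": False,
    })
    GT = np.zeros((4, n_samples), dtype=np.int8)
    GT[0, 0] = 1
    GT[1, :5] = 1
    GT[2, 3] = 1
    GT[3, 7] = 1
    DP = np.full((4, n_samples), 30, dtype=np.int16)
    GQ = np.full((4, n_samples), 80, dtype=np.int16)
    AB = np.where(GT == 1, 0.5, np.where(GT == 2, 0.98, 0.01))
    return VariantTable(variants=variants, GT=GT, DP=DP, GQ=GQ, AB=AB,
                        samples=samples,
                        kinship=pd.DataFrame(columns=["id1", "id2", "kinship"]))


class TestGenotypeQc:
    def test_thresholds_inclusive_as_printed(self):
        vt = toy_variant_table()
        vt.AB[0, 0] = 0.25   # het at the lower AB bound: kept
        vt.DP[1, 0] = 9      # depth below 10: missing
        vt.AB[1, 1] = 0.15   # hom-ref with AB 0.15: missing
        vt.GQ[2, 3] = 29     # GQ below 30: missing
        out = rb.genotype_qc(vt)
        assert out.GT[0, 0] == 1
        assert out.GT[1, 0] == -1
        assert out.GT[1, 1] == -1
        assert out.GT[2, 3] == -1

    def test_idempotent(self):
        vt = toy_variant_table()
        vt.DP[0, 5] = 3
        once = rb.genotype_qc(vt)
        twice = rb.genotype_qc(once)
        np.testing.assert_array_equal(once.GT, twice.GT)


def hwe_oracle(n_aa, n_ab, n_bb):
    """Direct log-factorial computation of the exact HWE p-value."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab

    def log_prob(h):
        haa = (na - h) // 2
        hbb = (nb - h) // 2
        return (math.lgamma(n + 1) - math.lgamma(haa + 1) - math.lgamma(h + 1)
                - math.lgamma(hbb + 1) + h * math.log(2)
                + math.lgamma(na + 1) + math.lgamma(nb + 1)
                - math.lgamma(2 * n + 1))

    rare = min(na, nb)
    hets = range(rare % 2, rare + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets}
    obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)))


class TestHweExact:
    def test_balanced_homozygotes_match_oracle(self):
        assert rb.hwe_exact(5, 0, 5) == pytest.approx(hwe_oracle(5, 0, 5), rel=1e-10)

    def test_monomorphic_is_one(self):
        assert rb.hwe_exact(25, 0, 0) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_aa, n_ab, n_bb = rng.integers(0, 30, 3)
        if n_aa + n_ab + n_bb == 0:
            n_aa = 1
        assert rb.hwe_exact(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_oracle(n_aa, n_ab, n_bb), rel=1e-10
        )


class TestVariantQc:
    def test_requires_genotype_qc_first(self):
        vt = toy_variant_table()
        with pytest.raises(ValueError, match="genotype_qc"):
            rb.variant_qc(vt)
        with pytest.raises(ValueError, match="variant_qc"):
            rb.define_ptv_singletons(vt)

    def test_each_violation_removes_exactly_that_variant(self):
        vt = toy_variant_table(n_samples=40)
        vt.variants.loc[0, "vqsr_pass"] = False
        vt.variants.loc[1, "low_complexity"] = True
        vt.DP[2, :8] = 5  # call rate 32/40 = 0.8 < 0.9
        qcd = rb.variant_qc(rb.genotype_qc(vt))
        assert set(qcd.variants["variant_id"]) == {"v3"}

    def test_call_rate_boundary_kept(self):
        vt = toy_variant_table(n_samples=40)
        vt.DP[2, :4] = 5  # call rate exactly 36/40 = 0.9
        qcd = rb.variant_qc(rb.genotype_qc(vt))
        assert "v2" in set(qcd.variants["variant_id"])

    def test_hwe_violation_removed(self):
        vt = toy_variant_table(n_samples=40)
        vt.GT[2, :] = 0
        vt.GT[2, :12] = 2  # many hom-alts, no hets
        vt.AB = np.where(vt.GT == 1, 0.5, np.where(vt.GT == 2, 0.98, 0.01))
        assert rb.hwe_exact(28, 0, 12) < 1e-8
        qcd = rb.variant_qc(rb.genotype_qc(vt))
        assert "v2" not in set(qcd.variants["variant_id"])

    def test_idempotent(self):
        vt = rb.genotype_qc(toy_variant_table())
        once = rb.variant_qc(vt)
        twice = rb.variant_qc(once)
        assert once.variants.equals(twice.variants)


class TestPtvSingletons:
    def test_definition(self):
        vt = toy_variant_table(n_samples=30)
        # v0: stop_gained singleton -> qualifies
        # v1: synonymous -> no; v2: missense singleton -> no
        # v3: frameshift singleton -> qualifies unless external
        qual = rb.define_ptv_singletons(rb.variant_qc(rb.genotype_qc(vt)))
        assert qual == {"v0", "v3"}

    def test_two_carriers_excluded(self):
        vt = toy_variant_table(n_samples=30)
        vt.GT[0, 1] = 1  # second carrier
        vt.AB[0, 1] = 0.5
        qual = rb.define_ptv_singletons(rb.variant_qc(rb.genotype_qc(vt)))
        assert "v0" not in qual

    def test_external_reference_flag_excludes(self):
        vt = toy_variant_table(n_samples=30)
        vt.variants.loc[3, "in_external_ref"] = True
        qual = rb.define_ptv_singletons(rb.variant_qc(rb.genotype_qc(vt)))
        assert qual == {"v0"}


class TestFirthLogistic:
    @pytest.mark.parametrize("seed", range(6))
    def test_two_by_two_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 30, 4)  # exposed-case, exposed-ctrl, ...
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        fit = rb.firth_logistic(y, np.column_stack([np.ones_like(x), x]))
        expected = math.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
        assert fit.beta[1] == pytest.approx(expected, abs=1e-6)

    def test_complete_separation_stays_finite(self):
        x = np.concatenate([np.ones(10), np.zeros(10)])
        y = x.copy()
        fit = rb.firth_logistic(y, np.column_stack([np.ones_like(x), x]))
        assert np.isfinite(fit.beta).all()
        assert abs(fit.beta[1]) < 10

    def test_zero_penalty_matches_ordinary_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.8 * X[:, 1])))).astype(float)
        fit = rb.firth_logistic(y, X, penalty=0.0)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-4)

    def test_rank_deficiency_rejected(self):
        x = np.linspace(0, 1, 20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        y = (x > 0.5).astype(float)
        with pytest.raises(ValueError, match="rank"):
            rb.firth_logistic(y, X)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rb.firth_logistic(np.ones(10), np.ones((10, 1)))


class TestBurdenTest:
    def _prepped(self, rare_bundle):
        vt = rare_bundle["vt"]
        qcd = rb.variant_qc(rb.genotype_qc(vt))
        qual = rb.define_ptv_singletons(qcd)
        passed = rb.sample_qc(vt.samples, vt.kinship)
        return qcd, qual, passed

    def test_runs_and_reports_counts(self, rare_bundle):
        qcd, qual, passed = self._prepped(rare_bundle)
        res = rb.burden_test(passed, qcd, qual, rare_bundle["truth"].burden_genes)
        assert res.odds_ratio > 0
        assert 0 < res.p <= 1
        assert res.n_cases + res.n_controls == len(passed)

    def test_zero_burden_is_error(self, rare_bundle):
        qcd, qual, passed = self._prepped(rare_bundle)
        with pytest.raises(ValueError, match="zero total burden"):
            rb.burden_test(passed, qcd, qual, {"no_such_gene"})

    def test_background_equal_to_set_is_collinear(self, rare_bundle):
        qcd, qual, passed = self._prepped(rare_bundle)
        all_genes = set(qcd.variants["gene_id"])
        with pytest.raises(ValueError, match="rank"):
            rb.burden_test(passed, qcd, qual, all_genes,
                           background_covariate="all_expressed",
                           expressed_genes=all_genes)

    def test_background_adjusted_set_test_runs(self, rare_bundle):
        qcd, qual, passed = self._prepped(rare_bundle)
        all_genes = set(qcd.variants["gene_id"])
        res = rb.burden_test(passed, qcd, qual, rare_bundle["truth"].burden_genes,
                             background_covariate="all_expressed",
                             expressed_genes=all_genes)
        assert np.isfinite(res.coefficient)

    def test_label_shuffle_null_is_calibrated(self, rare_bundle):
        qcd, qual, passed = self._prepped(rare_bundle)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(100):
            shuffled = passed.copy()
            shuffled["status"] = rng.permutation(shuffled["status"].to_numpy())
            res = rb.burden_test(shuffled, qcd, qual,
                                 rare_bundle["truth"].burden_genes)
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
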