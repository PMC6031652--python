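"""Single-variant scans, conditional analysis, meta-analysis and heritability."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from kiv2cn import (
    SimConfig,
    allelic_composition_test,
    compare_cn_functional_form,
    conditional_scan,
    estimate_cn,
    heritability_he,
    meta_fixed_effects,
    simulate_cohort,
    single_variant_scan,
)
from kiv2cn.core import CohortBundle, allele_stats


def _bundle_from(dosages, pheno_cols, positions=None):
    n, m = dosages.shape
    st = allele_stats(dosages)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "6",
            "pos": positions if positions is not None else np.arange(m) * 1000 + 1,
            "ref": "A",
            "alt": "G",
            "maf": st["maf"],
            "mac": st["mac"],
            "info_score": 1.0,
        }
    )
    samples = [f"s{i}" for i in range(n)]
    pheno = pd.DataFrame(pheno_cols, index=pd.Index(samples, name="sample_id"))
    return CohortBundle(samples=samples, dosages=dosages, variants=variants, phenotypes=pheno)


class TestSingleVariantScan:
    def test_matches_closed_form_ols_on_toy_fixture(self):
        # n=6, hand-set dosages and phenotype, no covariates beyond intercept
        g = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, 2.0, 2.5, 0.5, 1.8, 3.1])
        bundle = _bundle_from(g[:, None], {"y": y})
        res = single_variant_scan(bundle, "y", adjust_cn=False, maf_min=0.0)
        fit = sm.OLS(y, sm.add_constant(g)).fit()
        assert res["beta"].iloc[0] == pytest.approx(fit.params[1], rel=1e-10)
        assert res["se"].iloc[0] == pytest.approx(fit.bse[1], rel=1e-10)
        assert res["p"].iloc[0] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_matches_statsmodels_with_covariates_and_cn(self, rng):
        n = 200
        d = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        age = rng.uniform(40, 70, n)
        cn = rng.normal(40, 7, n)
        y = 0.3 * d[:, 2] - 0.05 * cn + 0.01 * age + rng.normal(size=n)
        bundle = _bundle_from(d, {"y": y, "age": age})
        res = single_variant_scan(bundle, "y", covariates=["age"], cn=cn, adjust_cn=True, maf_min=0.0)
        X = sm.add_constant(np.column_stack([age, cn, d[:, 2]]))
        fit = sm.OLS(y, X).fit()
        row = res[res["variant_id"] == "v2"].iloc[0]
        assert row["beta"] == pytest.approx(fit.params[-1], rel=1e-8)
        assert row["se"] == pytest.approx(fit.bse[-1], rel=1e-8)

    def test_null_type_one_error_calibrated(self, rng):
        n, m = 800, 1000
        d = rng.binomial(2, rng.uniform(0.05, 0.5, m), size=(n, m)).astype(float)
        y = rng.normal(size=n)
        bundle = _bundle_from(d, {"y": y})
        res = single_variant_scan(bundle, "y", adjust_cn=False, maf_min=0.001)
        frac = (res["p"] < 0.05).mean()
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / len(res))
        assert abs(frac - 0.05) < half_width + 0.005

    def test_cn_mediated_snp_nullified_by_adjustment(self):
        # SNP influences the phenotype only through CN (tagging); CN adjustment removes it
        cfg = SimConfig(n_samples=2000, n_variants=120, cn_effect=-0.07,
                        n_causal_snps=0, snp_h2=0.0, tagging_r2=0.6, seed=8)
        bundle, truth = simulate_cohort(cfg)
        cn = estimate_cn(bundle.depth)["kiv2_cn"].to_numpy()
        unadj = single_variant_scan(bundle, "lp_a_norm", adjust_cn=False)
        adj = single_variant_scan(bundle, "lp_a_norm", cn=cn, adjust_cn=True)
        top = unadj.sort_values("p").iloc[0]
        assert top["p"] < 1e-8  # tagging makes some SNP strongly associated
        adj_top = adj[adj["variant_id"] == top["variant_id"]].iloc[0]
        assert adj_top["p"] > 1e-3
        assert abs(adj_top["beta"]) < abs(top["beta"]) / 2

    def test_lmm_with_identity_kinship_equals_ols(self, rng):
        n = 150
        d = rng.binomial(2, 0.3, size=(n, 8)).astype(float)
        y = 0.4 * d[:, 1] + rng.normal(size=n)
        bundle = _bundle_from(d, {"y": y})
        ols = single_variant_scan(bundle, "y", adjust_cn=False, maf_min=0.0, mode="ols")
        lmm = single_variant_scan(bundle, "y", adjust_cn=False, maf_min=0.0, mode="lmm",
                                  kinship=np.eye(n))
        np.testing.assert_allclose(lmm["beta"], ols["beta"], rtol=1e-5)
        np.testing.assert_allclose(lmm["se"], ols["se"], rtol=1e-3)

    def test_lmm_requires_kinship(self, rng):
        d = rng.binomial(2, 0.3, size=(50, 5)).astype(float)
        bundle = _bundle_from(d, {"y": rng.normal(size=50)})
        with pytest.raises(ValueError, match="kinship"):
            single_variant_scan(bundle, "y", adjust_cn=False, mode="lmm")


class TestConditionalScan:
    def test_one_causal_variant_with_proxies_yields_one_hit(self, rng):
        n = 2000
        g = rng.binomial(2, 0.4, size=n).astype(float)
        flip = rng.random((n, 3)) < 0.02
        proxies = np.where(flip, np.clip(g[:, None] + 1, 0, 2), g[:, None])
        d = np.column_stack([g, proxies, rng.binomial(2, 0.3, size=(n, 6)).astype(float)])
        y = 0.5 * g + rng.normal(size=n)
        bundle = _bundle_from(d, {"y": y})
        hits = conditional_scan(bundle, "y", adjust_cn=False, maf_min=0.0)
        assert len(hits) == 1

    def test_two_unlinked_causal_variants_found_in_effect_order(self, rng):
        n = 3000
        d = rng.binomial(2, 0.4, size=(n, 10)).astype(float)
        y = 0.6 * d[:, 2] + 0.3 * d[:, 7] + rng.normal(size=n)
        bundle = _bundle_from(d, {"y": y})
        hits = conditional_scan(bundle, "y", adjust_cn=False, maf_min=0.0)
        assert list(hits["variant_id"]) == ["v2", "v7"]

    def test_no_significant_variant_gives_empty_list(self, rng):
        d = rng.binomial(2, 0.3, size=(300, 6)).astype(float)
        bundle = _bundle_from(d, {"y": rng.normal(size=300)})
        hits = conditional_scan(bundle, "y", adjust_cn=False, maf_min=0.0)
        assert hits.empty


class TestMetaFixedEffects:
    @staticmethod
    def _table(vids, betas, ses, n=100):
        return pd.DataFrame({"variant_id": vids, "beta": betas, "se": ses, "n": n})

    def test_equal_cohorts_pool_to_shared_beta_and_shrunk_se(self):
        t = self._table(["v1"], [0.4], [0.1])
        out = meta_fixed_effects({"a": t, "b": t.copy()})
        assert out["beta"].iloc[0] == pytest.approx(0.4)
        assert out["se"].iloc[0] == pytest.approx(0.1 / np.sqrt(2))
        assert out["q"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["het_p"].iloc[0] == pytest.approx(1.0)

    def test_opposite_effects_pool_to_zero(self):
        out = meta_fixed_effects({
            "a": self._table(["v1"], [0.3], [0.1]),
            "b": self._table(["v1"], [-0.3], [0.1]),
        })
        assert out["beta"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["q"].iloc[0] > 0

    def test_three_cohort_example_matches_brute_force(self):
        betas, ses = [0.2, 0.5, -0.1], [0.05, 0.2, 0.1]
        tables = {f"c{k}": self._table(["v1"], [betas[k]], [ses[k]]) for k in range(3)}
        out = meta_fixed_effects(tables)
        w = [1 / s**2 for s in ses]
        pooled = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
        se = (1 / sum(w)) ** 0.5
        q = sum(wi * (bi - pooled) ** 2 for wi, bi in zip(w, betas))
        assert out["beta"].iloc[0] == pytest.approx(pooled, rel=1e-12)
        assert out["se"].iloc[0] == pytest.approx(se, rel=1e-12)
        assert out["q"].iloc[0] == pytest.approx(q, rel=1e-12)
        from scipy import stats as st

        assert out["het_p"].iloc[0] == pytest.approx(st.chi2.sf(q, 2), rel=1e-12)

    def test_pooled_estimate_bounded_by_cohort_betas(self, rng):
        for _ in range(20):
            betas = rng.normal(size=3)
            ses = rng.uniform(0.05, 0.3, 3)
            tables = {f"c{k}": self._table(["v1"], [betas[k]], [ses[k]]) for k in range(3)}
            out = meta_fixed_effects(tables)
            assert betas.min() - 1e-12 <= out["beta"].iloc[0] <= betas.max() + 1e-12
            assert out["se"].iloc[0] <= ses.min()

    def test_single_cohort_variant_passes_through_flagged(self):
        out = meta_fixed_effects({
            "a": self._table(["v1", "v2"], [0.1, 0.2], [0.1, 0.1]),
            "b": self._table(["v1"], [0.1], [0.1]),
        })
        assert bool(out[out["variant_id"] == "v2"]["single_cohort"].iloc[0])

    def test_invalid_se_rows_rejected(self):
        out = meta_fixed_effects({
            "a": self._table(["v1"], [0.1], [0.0]),
            "b": self._table(["v1"], [0.2], [0.1]),
        })
        assert out["n_cohorts"].iloc[0] == 1


class TestFunctionalForm:
    def test_linear_generator_yields_uniform_added_term_p(self, rng):
        from scipy import stats as st

        pvals = []
        for _ in range(200):
            cn = rng.normal(40, 7, 300)
            y = -0.07 * cn + rng.normal(0, 0.8, 300)
            pvals.append(compare_cn_functional_form(y, cn)["p"])
        assert st.kstest(pvals, "uniform").pvalue > 0.01

    def test_reciprocal_generator_detected(self, rng):
        detected = 0
        for _ in range(20):
            cn = rng.normal(40, 7, 2000).clip(12)
            y = 40.0 / cn + rng.normal(0, 0.15, 2000)
            detected += compare_cn_functional_form(y, cn)["p"] < 0.05
        assert detected >= 18

    def test_nonpositive_cn_excluded(self, rng):
        cn = np.concatenate([rng.normal(40, 7, 100), [-5.0, 0.0]])
        y = rng.normal(size=102)
        out = compare_cn_functional_form(y, cn)
        assert out["n_excluded"] == 2 and out["n"] == 100

    def test_constant_cn_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compare_cn_functional_form(np.zeros(10), np.full(10, 40.0))


class TestAllelicComposition:
    def test_total_cn_generator_is_null(self, rng):
        from scipy import stats as st

        pvals = []
        for _ in range(100):
            a = rng.normal(20, 4, size=(500, 2))
            y = -0.07 * a.sum(axis=1) + rng.normal(0, 0.5, 500)
            pvals.append(allelic_composition_test(y, a, tol=2.0)["p"])
        assert st.kstest(pvals, "uniform").pvalue > 0.01

    def test_allele_specific_effect_detected(self, rng):
        detected = 0
        for _ in range(20):
            a = rng.normal(20, 4, size=(2000, 2))
            eq = np.abs(a[:, 0] - a[:, 1]) < 2.0
            slope = np.where(eq, -0.12, -0.05)
            y = slope * a.sum(axis=1) + rng.normal(0, 0.5, 2000)
            detected += allelic_composition_test(y, a, tol=2.0)["p"] < 0.05
        assert detected >= 18

    def test_zero_tolerance_with_continuous_alleles_errors(self, rng):
        a = rng.normal(20, 4, size=(100, 2))
        with pytest.raises(ValueError, match="group"):
            allelic_composition_test(rng.normal(size=100), a, tol=0.0)


class TestHeritability:
    def _h2_bundle(self, h2, seed, n=1000, m=1200):
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.05, 0.5, m)
        d = rng.binomial(2, freqs, size=(n, m)).astype(float)
        z = (d - d.mean(0)) / d.std(0)
        beta = rng.normal(0, np.sqrt(h2 / m), m)
        y = z @ beta + rng.normal(0, np.sqrt(1 - h2), n)
        return _bundle_from(d, {"y": y})

    def test_null_heritability_recovered(self):
        bundle = self._h2_bundle(0.0, seed=1)
        out = heritability_he(bundle, "y")
        assert abs(out["h2_raw"]) < 0.1

    def test_h2_075_recovered_within_tolerance(self):
        # per-seed sampling SD is ~0.08 at n=1000, so average over a seed band
        ests = [heritability_he(self._h2_bundle(0.75, seed=s), "y")["h2"] for s in range(2, 10)]
        assert np.mean(ests) == pytest.approx(0.75, abs=0.1)

    def test_jackknife_se_reported(self):
        out = heritability_he(self._h2_bundle(0.5, seed=5), "y")
        assert 0 < out["se"] < 0.5

    def test_cn_conditioning_reduces_mediated_h2(self):
        # phenotype driven purely by CN; the GRM excludes the locus window
        cfg = SimConfig(n_samples=1000, n_variants=1300, cn_effect=-0.1,
                        n_causal_snps=0, snp_h2=0.0, mutation_rate=0.3, seed=6)
        bundle, truth = simulate_cohort(cfg)
        cn = estimate_cn(bundle.depth)["kiv2_cn"].to_numpy()
        window = (161_050_232 - 500_000, 161_050_232 + 500_000)
        kw = dict(exclude_window=window, min_variants=500)
        unadj = heritability_he(bundle, "lp_a_norm", **kw)
        adj = heritability_he(bundle, "lp_a_norm", cn=cn, **kw)
        assert adj["h2"] <= unadj["h2"] + 0.02

    def test_variant_floor_enforced(self):
        bundle = self._h2_bundle(0.5, seed=7, m=300)
        with pytest.raises(ValueError, match="floor"):
            heritability_he(bundle, "y")
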