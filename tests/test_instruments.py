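"""Genetic instruments, calibration, Cox and quantitative outcome models."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from kiv2cn import (
    SimConfig,
    build_cn_score,
    build_grs,
    combine_scores,
    estimate_cn,
    mr_cox,
    mr_quantitative,
    normalize_instrument,
    simulate_cohort,
    single_variant_scan,
    variance_explained,
)
from kiv2cn.instruments import Instrument
from kiv2cn.simulate import simulate_outcomes
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


class TestBuildGRS:
    def test_single_variant_score_is_weighted_dosage(self):
        d = np.array([[0.0], [1.0], [2.0]])
        bundle = _bundle_from(d, {"y": [0.0, 1.0, 2.0]})
        results = pd.DataFrame({
            "variant_id": ["v0"], "chrom": ["6"], "pos": [1], "p": [1e-6],
            "beta": [1.0], "variant_idx": [0], "skipped": [False],
        })
        instr = build_grs(results, bundle)
        np.testing.assert_allclose(instr.raw, [0.0, 1.0, 2.0])

    def test_no_subthreshold_variant_is_a_clean_error(self, rng):
        d = rng.binomial(2, 0.3, size=(50, 2)).astype(float)
        bundle = _bundle_from(d, {"y": rng.normal(size=50)})
        results = pd.DataFrame({
            "variant_id": ["v0", "v1"], "chrom": "6", "pos": [1, 1001], "p": [0.5, 0.9],
            "beta": [0.1, 0.2], "variant_idx": [0, 1], "skipped": [False, False],
        })
        with pytest.raises(ValueError, match="p <="):
            build_grs(results, bundle)

    def test_grs_recovers_snp_component_of_signal(self):
        cfg = SimConfig(n_samples=2000, snp_h2=0.2, seed=17)
        bundle, truth = simulate_cohort(cfg)
        cn = estimate_cn(bundle.depth)["kiv2_cn"].to_numpy()
        scan = single_variant_scan(bundle, "lp_a_norm", cn=cn, adjust_cn=True)
        instr = build_grs(scan, bundle)
        r2 = np.corrcoef(instr.raw, truth.snp_score)[0, 1] ** 2
        assert r2 == pytest.approx(1.0, abs=0.25)  # most of the SNP pathway captured
        y = bundle.phenotypes["lp_a_norm"].to_numpy()
        grs_r2 = np.corrcoef(instr.raw, y)[0, 1] ** 2
        assert grs_r2 == pytest.approx(truth.snp_variance_frac, abs=0.1)


class TestCNScore:
    def test_cn_passes_through_as_raw_score(self, rng):
        cn = rng.normal(40, 7, 100)
        instr = build_cn_score(cn, [f"s{i}" for i in range(100)])
        np.testing.assert_array_equal(instr.raw, cn)

    def test_orientation_after_calibration_is_positive(self, rng):
        cn = rng.normal(40, 7, 2000)
        y = -0.07 * cn + rng.normal(0, 0.7, 2000)
        from kiv2cn import inverse_rank_normalize

        y_norm = inverse_rank_normalize(y)
        instr = normalize_instrument(build_cn_score(cn, list(range(2000))), y_norm)
        assert instr.scale_factor < 0  # inverse CN-phenotype relation
        slope = np.polyfit(instr.final, y_norm, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.01)

    def test_excess_missingness_rejected(self, rng):
        cn = rng.normal(40, 7, 100)
        cn[:20] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_cn_score(cn, list(range(100)), missing_max=0.1)

    def test_constant_cn_cannot_normalize(self):
        instr = build_cn_score(np.full(100, 40.0), list(range(100)))
        with pytest.raises(ValueError, match="constant"):
            normalize_instrument(instr, np.random.default_rng(0).normal(size=100))


class TestNormalization:
    def test_phenotype_equal_to_score_gives_unit_scale(self, rng):
        score = rng.normal(size=500)
        from kiv2cn import inverse_rank_normalize

        y = inverse_rank_normalize(score)
        instr = normalize_instrument(Instrument(kind="GRS", raw=score, samples=list(range(500))), y)
        assert instr.scale_factor == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(instr.final, instr.normalized)

    def test_independent_phenotype_raises_uninformative(self, rng):
        score = rng.normal(size=2000)
        y = rng.normal(size=2000)
        with pytest.raises(ValueError, match="uninformative"):
            normalize_instrument(Instrument(kind="GRS", raw=score, samples=list(range(2000))), y,
                                 min_slope=0.05)

    def test_calibration_identity_holds_for_all_instrument_kinds(self):
        cfg = SimConfig(n_samples=1500, seed=23)
        bundle, truth = simulate_cohort(cfg)
        cn = estimate_cn(bundle.depth)["kiv2_cn"].to_numpy()
        y = bundle.phenotypes["lp_a_norm"].to_numpy()
        scan = single_variant_scan(bundle, "lp_a_norm", cn=cn, adjust_cn=True)
        grs = normalize_instrument(build_grs(scan, bundle), y)
        cns = normalize_instrument(build_cn_score(cn, bundle.samples), y)
        comb = combine_scores(grs, cns, y)
        for instr in (grs, cns, comb):
            slope = np.polyfit(instr.final, y, 1)[0]
            assert slope == pytest.approx(1.0, abs=0.01), instr.kind


class TestCombine:
    def test_zero_signal_cn_leaves_combined_equal_to_grs(self, rng):
        from kiv2cn import inverse_rank_normalize

        g = rng.normal(size=3000)
        y = inverse_rank_normalize(g + rng.normal(0, 0.5, 3000))
        grs = normalize_instrument(Instrument(kind="GRS", raw=g, samples=list(range(3000))), y)
        # a score carrying (almost) no signal: just enough for calibration
        weak = rng.normal(size=3000) + 0.08 * g
        cns = normalize_instrument(Instrument(kind="KIV2CN", raw=weak, samples=list(range(3000))), y)
        comb = combine_scores(grs, cns, y)
        assert np.corrcoef(comb.final, grs.final)[0, 1] > 0.99

    def test_duplicated_grs_renormalizes_to_itself(self, rng):
        from kiv2cn import inverse_rank_normalize

        g = rng.normal(size=1000)
        y = inverse_rank_normalize(g + rng.normal(0, 0.7, 1000))
        grs = normalize_instrument(Instrument(kind="GRS", raw=g, samples=list(range(1000))), y)
        grs2 = Instrument(kind="KIV2CN", raw=g.copy(), samples=list(range(1000)))
        grs2 = normalize_instrument(grs2, y)
        comb = combine_scores(grs, grs2, y)
        assert abs(np.corrcoef(comb.final, grs.final)[0, 1]) > 0.9999

    def test_uncorrelated_informative_scores_raise_variance_explained(self, rng):
        from kiv2cn import inverse_rank_normalize

        a, b = rng.normal(size=4000), rng.normal(size=4000)
        y = inverse_rank_normalize(a + b + rng.normal(0, 1.0, 4000))
        ia = normalize_instrument(Instrument(kind="GRS", raw=a, samples=list(range(4000))), y)
        ib = normalize_instrument(Instrument(kind="KIV2CN", raw=b, samples=list(range(4000))), y)
        comb = combine_scores(ia, ib, y)
        va = variance_explained(ia, y)["r_squared"]
        vb = variance_explained(ib, y)["r_squared"]
        vc = variance_explained(comb, y)["r_squared"]
        assert vc >= max(va, vb) - 0.01

    def test_mismatched_samples_rejected(self, rng):
        a = Instrument(kind="GRS", raw=rng.normal(size=10), samples=list(range(10)), final=rng.normal(size=10))
        b = Instrument(kind="KIV2CN", raw=rng.normal(size=10), samples=list(range(1, 11)), final=rng.normal(size=10))
        with pytest.raises(ValueError, match="sample"):
            combine_scores(a, b, rng.normal(size=10))


def breslow_neg_log_partial_likelihood(beta, time, status, x):
    """Independent oracle: direct Breslow partial likelihood."""
    eta = x @ beta
    ll = 0.0
    for t in np.unique(time[status == 1]):
        events = (time == t) & (status == 1)
        risk = time >= t
        d = events.sum()
        ll += eta[events].sum() - d * np.log(np.sum(np.exp(eta[risk])))
    return -ll


class TestCox:
    def test_matches_brute_force_partial_likelihood(self, rng):
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))
        status = (t <= 8.0).astype(int)
        time = np.minimum(t, 8.0)
        instr = Instrument(kind="GRS", raw=x, samples=list(range(n)), final=x)
        events = pd.DataFrame({"time": time, "status": status})
        got = mr_cox(events, instr, min_events=5)
        res = optimize.minimize_scalar(
            lambda b: breslow_neg_log_partial_likelihood(np.array([b]), time, status, x[:, None])
        )
        assert np.log(got.effect) == pytest.approx(res.x, abs=1e-4)

    def test_null_instrument_covers_unity(self):
        covered = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(size=400)
            t = r.exponential(1.0 / 0.05, size=400)
            status = (t <= 10.0).astype(int)
            events = pd.DataFrame({"time": np.minimum(t, 10.0), "status": status})
            instr = Instrument(kind="GRS", raw=x, samples=list(range(400)), final=x)
            got = mr_cox(events, instr, min_events=5)
            covered += int(got.ci_low <= 1.0 <= got.ci_high)
        assert covered >= 93

    def test_recovers_hazard_ratio_with_perfect_instrument(self):
        cfg = SimConfig(n_samples=4000, event_loghr=np.log(1.25),
                        event_baseline_hazard=0.02, seed=31)
        bundle, truth = simulate_cohort(cfg)
        ev = simulate_outcomes(bundle.phenotypes, cfg, 99)
        y = bundle.phenotypes["lp_a_norm"].to_numpy()
        instr = Instrument(kind="GRS", raw=y, samples=bundle.samples, final=y)
        got = mr_cox(ev, instr)
        se = (np.log(got.ci_high) - np.log(got.effect)) / 1.96
        assert np.log(got.effect) == pytest.approx(np.log(1.25), abs=2 * se)

    def test_no_events_is_an_error(self, rng):
        instr = Instrument(kind="GRS", raw=rng.normal(size=30), samples=list(range(30)))
        events = pd.DataFrame({"time": np.full(30, 10.0), "status": np.zeros(30, dtype=int)})
        with pytest.raises(ValueError, match="events"):
            mr_cox(events, instr)

    def test_cox_agrees_with_logistic_in_rare_event_limit(self, rng):
        import statsmodels.api as sm

        n = 20000
        x = rng.normal(size=n)
        lam = 0.004 * np.exp(0.3 * x)
        t = rng.exponential(1.0 / lam)
        status = (t <= 2.0).astype(int)
        events = pd.DataFrame({"time": np.minimum(t, 2.0), "status": status})
        instr = Instrument(kind="GRS", raw=x, samples=list(range(n)), final=x)
        cox = mr_cox(events, instr)
        logit = sm.Logit(status, sm.add_constant(x)).fit(disp=0)
        assert abs(np.log(cox.effect) - logit.params[1]) / abs(logit.params[1]) < 0.05


class TestQuantitativeMR:
    def test_fixture_matches_closed_form_ols(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(0, 0.5, 200)
        instr = Instrument(kind="GRS", raw=x, samples=list(range(200)), final=x)
        got = mr_quantitative(y, instr)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert got.effect == pytest.approx(fit.params[1], rel=1e-10)
        assert got.p == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_slope_recovery_and_null_calibration(self, rng):
        x = rng.normal(size=3000)
        y = 0.25 * x + rng.normal(0, 1.0, 3000)
        instr = Instrument(kind="GRS", raw=x, samples=list(range(3000)), final=x)
        got = mr_quantitative(y, instr)
        se = (got.ci_high - got.effect) / 1.96
        assert got.effect == pytest.approx(0.25, abs=2 * se)
        rejections = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            xn, yn = r.normal(size=300), r.normal(size=300)
            i = Instrument(kind="GRS", raw=xn, samples=list(range(300)), final=xn)
            rejections += int(mr_quantitative(yn, i).p < 0.05)
        assert 1 <= rejections <= 11  # binomial band around 5/100


class TestVarianceExplained:
    def test_orthogonal_instrument_explains_nothing(self, rng):
        instr = Instrument(kind="GRS", raw=rng.normal(size=2000), samples=list(range(2000)))
        out = variance_explained(instr, rng.normal(size=2000))
        assert out["r_squared"] < 0.01

    def test_combined_instrument_recovers_genetic_variance_held_out(self):
        # genetic component (CN at ~26-27% plus CN-independent SNPs at ~20%)
        # totals ~47% of phenotype variance; the combined instrument should
        # recover that on samples never used for weights or calibration
        from kiv2cn.instruments import grs_raw_score, transfer_instrument

        cfg = SimConfig(n_samples=4000, snp_h2=0.20, seed=41)
        bundle, truth = simulate_cohort(cfg)
        cn = estimate_cn(bundle.depth)["kiv2_cn"].to_numpy()
        y = bundle.phenotypes["lp_a_norm"].to_numpy()
        cal, held = np.arange(2000), np.arange(2000, 4000)
        cal_b, held_b = bundle.subset_samples(cal), bundle.subset_samples(held)

        scan = single_variant_scan(cal_b, "lp_a_norm", cn=cn[cal], adjust_cn=True)
        y_cal = y[cal]
        grs = normalize_instrument(build_grs(scan, cal_b), y_cal)
        cns = normalize_instrument(build_cn_score(cn[cal], cal_b.samples), y_cal)
        comb = combine_scores(grs, cns, y_cal)

        grs_h = transfer_instrument(grs, grs_raw_score(grs, held_b), held_b.samples)
        cns_h = transfer_instrument(cns, cn[held], held_b.samples)
        comb_h = Instrument(kind="COMBINED", raw=grs_h.final + cns_h.final,
                            samples=held_b.samples, final=grs_h.final + cns_h.final,
                            scale_factor=comb.scale_factor)
        genetic_frac = truth.cn_variance_frac + truth.snp_variance_frac
        out = variance_explained(comb_h, y[held])
        assert out["r_squared"] == pytest.approx(genetic_frac, abs=0.07)
        # optimism: calibration-cohort fit is at least as good on average
        out_cal = variance_explained(comb, y_cal, cohort_label="calibration")
        assert out_cal["r_squared"] >= out["r_squared"] - 0.03

    def test_small_n_rejected(self, rng):
        instr = Instrument(kind="GRS", raw=rng.normal(size=10), samples=list(range(10)))
        with pytest.raises(ValueError):
            variance_explained(instr, rng.normal(size=10))
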