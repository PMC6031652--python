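"""Association scans, meta-analysis and heritability.

Single-variant scans regress the rank-normalized phenotype on allele dosage
with covariates (and, when requested, diploid KIV2-CN) per variant.  Two
engines are provided:

* ``ols`` — ordinary least squares with principal components or any other
  fixed covariates; exactly the closed-form normal-equations solution.
* ``lmm`` — a kinship linear mixed model solved by eigen-rotation: the
  kinship eigendecomposition whitens the data, the variance ratio
  delta = sigma_e^2 / sigma_g^2 is profiled once under the null model, and
  every variant is then a weighted least-squares fit.  With an identity
  kinship this reduces exactly to OLS.

Cross-cohort pooling is inverse-variance fixed-effects with Cochran's Q
heterogeneity.  Heritability uses Haseman-Elston regression of phenotype
cross-products on off-diagonal genomic relatedness, with a sample-block
jackknife standard error.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .core import CohortBundle, standardize_dosages
from .cn_impute import ld_prune

log = logging.getLogger("kiv2cn")


def _design(bundle: CohortBundle, covariates, cn, extra_dosage_idx=()):
    """Covariate design matrix with intercept; returns (X, complete-case mask)."""
    n = bundle.n_samples
    cols = [np.ones(n)]
    for c in covariates or []:
        cols.append(bundle.phenotypes[c].to_numpy(dtype=float))
    if cn is not None:
        cols.append(np.asarray(cn, dtype=float))
    for j in extra_dosage_idx:
        d = bundle.dosages[:, j]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        cols.append(d)
    X = np.column_stack(cols)
    mask = ~np.isnan(X).any(axis=1)
    return X, mask


def _ols_scan_core(y: np.ndarray, X: np.ndarray, G: np.ndarray, df_extra: int = 0):
    """Vectorized per-variant OLS given residualizing covariates X.

    Returns beta, se, p, ok (variants with usable residual dosage variance).
    """
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    den = np.einsum("ij,ij->j", G_r, G_r)
    ok = den > 1e-10
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    pval = np.full(G.shape[1], np.nan)
    num = G_r.T @ y_r
    yy = float(y_r @ y_r)
    dof = n - p - 1 - df_extra
    with np.errstate(invalid="ignore", divide="ignore"):
        b = num / den
        rss = yy - b**2 * den
        sigma2 = rss / dof
        s = np.sqrt(sigma2 / den)
        t = b / s
        pv = 2 * stats.t.sf(np.abs(t), dof)
    beta[ok], se[ok], pval[ok] = b[ok], s[ok], pv[ok]
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return beta, se, pval, ok


def _profile_lmm_delta(y: np.ndarray, X: np.ndarray, eigvals: np.ndarray):
    """Null-model ML profile of the variance ratio on the rotated data."""

    def negll(log_delta):
        delta = np.exp(log_delta)
        w = 1.0 / (eigvals + delta)
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        n = len(y)
        sigma2 = float(r @ r) / n
        return 0.5 * (n * np.log(sigma2) - np.sum(np.log(w)) + n)

    res = optimize.minimize_scalar(negll, bounds=(-10, 10), method="bounded")
    return float(np.exp(res.x))


def single_variant_scan(bundle: CohortBundle, phenotype, covariates=None, cn=None,
                        adjust_cn: bool = True, maf_min: float = 0.001,
                        mode: str = "ols", kinship: np.ndarray | None = None,
                        window: tuple[int, int] | None = None,
                        condition_idx=(), analysis: str = "single_variant") -> pd.DataFrame:
    """Per-variant effect of dosage on the phenotype with covariates (+CN).

    ``phenotype`` is a phenotype-table column name or an array.  Variants
    with MAF <= ``maf_min`` are excluded; rank-deficient variants are skipped
    with a flag.  ``mode="lmm"`` requires a kinship matrix (or uses
    ``bundle.kinship``).
    """
    y = bundle.phenotypes[phenotype].to_numpy(dtype=float) if isinstance(phenotype, str) else np.asarray(phenotype, dtype=float)
    X, mask = _design(bundle, covariates, cn if adjust_cn else None, condition_idx)
    mask &= ~np.isnan(y)
    keep = bundle.variants["maf"].to_numpy() > maf_min
    if window is not None:
        pos = bundle.variants["pos"].to_numpy()
        keep &= (pos >= window[0]) & (pos <= window[1])
    vidx = np.where(keep)[0]

    Xc, yc = X[mask], y[mask]
    G = bundle.dosages[np.ix_(mask, vidx)]
    # mean-impute sparse missingness inside the scan; fully-missing columns drop out
    if np.isnan(G).any():
        mu = np.nanmean(G, axis=0)
        inds = np.where(np.isnan(G))
        G = G.copy()
        G[inds] = np.take(mu, inds[1])

    if mode == "ols":
        beta, se, pval, ok = _ols_scan_core(yc, Xc, G)
    elif mode == "lmm":
        K = kinship if kinship is not None else bundle.kinship
        if K is None:
            raise ValueError("lmm mode requires a kinship matrix")
        K = K[np.ix_(mask, mask)]
        eigvals, U = np.linalg.eigh(K)
        eigvals = np.maximum(eigvals, 1e-9)
        yr, Xr, Gr = U.T @ yc, U.T @ Xc, U.T @ G
        delta = _profile_lmm_delta(yr, Xr, eigvals)
        sw = np.sqrt(1.0 / (eigvals + delta))
        beta, se, pval, ok = _ols_scan_core(yr * sw, Xr * sw[:, None], Gr * sw[:, None])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_skip = int((~ok).sum())
    if n_skip:
        log.info("single_variant_scan: skipped %d rank-deficient variants", n_skip)
    out = bundle.variants.iloc[vidx][["variant_id", "chrom", "pos", "maf"]].copy()
    out["beta"], out["se"], out["p"] = beta, se, pval
    out["n"] = int(mask.sum())
    out["analysis"] = analysis
    out["skipped"] = ~ok
    out["variant_idx"] = vidx
    return out.reset_index(drop=True)


def conditional_scan(bundle: CohortBundle, phenotype, window=None, p_stop: float = 5e-8,
                     max_iter: int = 50, **scan_kwargs) -> pd.DataFrame:
    """Iterative conditional analysis: add the top variant as a covariate and
    rescan until the minimum p-value exceeds ``p_stop``.

    Ties on p are broken by position (lower first).  Returns the ordered list
    of independent hits (possibly empty).
    """
    hits = []
    cond: list[int] = []
    for it in range(max_iter + 1):
        if it == max_iter:
            raise RuntimeError(f"conditional scan did not converge in {max_iter} iterations")
        res = single_variant_scan(bundle, phenotype, window=window, condition_idx=tuple(cond), **scan_kwargs)
        res = res[~res["variant_idx"].isin(cond) & ~res["skipped"]]
        if res.empty:
            break
        res = res.sort_values(["p", "pos"], kind="mergesort")
        top = res.iloc[0]
        if top["p"] > p_stop:
            break
        hits.append(top)
        cond.append(int(top["variant_idx"]))
    if not hits:
        return pd.DataFrame(columns=["variant_id", "chrom", "pos", "maf", "beta", "se", "p", "n", "analysis"])
    return pd.DataFrame(hits).reset_index(drop=True)


def meta_fixed_effects(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effects meta-analysis with Cochran's Q.

    ``tables`` maps cohort name to a result table (variant_id, beta, se, n).
    Variants present in a single cohort pass through flagged.  Rows with
    non-positive SE are rejected.
    """
    frames = []
    for cohort, t in tables.items():
        t = t[["variant_id", "beta", "se", "n"]].copy()
        bad = ~(t["se"] > 0) | ~np.isfinite(t["beta"])
        if bad.any():
            log.info("meta: rejecting %d rows with invalid se from %s", int(bad.sum()), cohort)
        t = t[~bad]
        t["cohort"] = cohort
        frames.append(t)
    allrows = pd.concat(frames, ignore_index=True)
    out = []
    for vid, grp in allrows.groupby("variant_id", sort=False):
        w = 1.0 / grp["se"] ** 2
        pooled_beta = float(np.sum(w * grp["beta"]) / np.sum(w))
        pooled_se = float(np.sqrt(1.0 / np.sum(w)))
        z = pooled_beta / pooled_se
        k = len(grp)
        q = float(np.sum(w * (grp["beta"] - pooled_beta) ** 2))
        het_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else np.nan
        out.append(
            {
                "variant_id": vid,
                "beta": pooled_beta,
                "se": pooled_se,
                "p": float(2 * stats.norm.sf(abs(z))),
                "n": int(grp["n"].sum()),
                "n_cohorts": k,
                "q": q,
                "het_p": het_p,
                "single_cohort": k < 2,
            }
        )
    return pd.DataFrame(out)


def compare_cn_functional_form(y: np.ndarray, cn: np.ndarray, covariates: np.ndarray | None = None) -> dict:
    """Partial-F test for adding 1/CN to a linear-in-CN model.

    Samples with CN <= 0 are excluded (count logged).  Returns the added-term
    p-value and the fit summaries.
    """
    cn = np.asarray(cn, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = cn > 0
    n_excl = int((~pos).sum())
    if n_excl:
        log.info("compare_cn_functional_form: excluding %d samples with CN <= 0", n_excl)
    if np.std(cn[pos]) == 0:
        raise ValueError("CN is constant")
    base = [np.ones(pos.sum()), cn[pos]]
    if covariates is not None:
        base.append(np.asarray(covariates)[pos])
    X0 = np.column_stack(base)
    X1 = np.column_stack(base + [1.0 / cn[pos]])
    fit0 = sm.OLS(y[pos], X0).fit()
    fit1 = sm.OLS(y[pos], X1).fit()
    f, p, df = fit1.compare_f_test(fit0)
    return {"p": float(p), "f": float(f), "n": int(pos.sum()), "n_excluded": n_excl}


def allelic_composition_test(y: np.ndarray, allelic_cn: np.ndarray,
                             covariates: np.ndarray | None = None,
                             tol: float = 1.0, min_group: int = 10) -> dict:
    """Do equal-allele (homozygous-like) samples share the overall CN slope?

    Samples with |allele1 - allele2| < ``tol`` form the equal-allele group; a
    group-by-CN interaction term tests for a slope difference.
    """
    a = np.asarray(allelic_cn, dtype=float)
    dip = a.sum(axis=1)
    grp = (np.abs(a[:, 0] - a[:, 1]) < tol).astype(float)
    n_eq = int(grp.sum())
    if n_eq < min_group or len(grp) - n_eq < min_group:
        raise ValueError(f"equal-allele group has {n_eq} samples; need >= {min_group} per group")
    cn_c = dip - dip.mean()
    cols = [np.ones(len(dip)), cn_c, grp, grp * cn_c]
    if covariates is not None:
        cols.append(np.asarray(covariates))
    X = np.column_stack(cols)
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return {"p": float(fit.pvalues[3]), "beta_interaction": float(fit.params[3]), "n_equal": n_eq}


def heritability_he(bundle: CohortBundle, phenotype, covariates=None, cn=None,
                    maf_min: float = 0.001, miss_max: float = 0.01,
                    prune_r2: float = 0.9, thin_factor: int = 1,
                    exclude_window: tuple[int, int] | None = None,
                    min_samples: int = 500, min_variants: int = 1000,
                    n_jackknife: int = 20) -> dict:
    """Haseman-Elston narrow-sense heritability with block-jackknife SE.

    Pipeline: MAF/missingness filters, optional region exclusion, LD pruning
    (50/5 window at ``prune_r2``), optional deterministic index thinning;
    genomic relationship matrix from standardized dosages; regression of
    phenotype cross-products on off-diagonal relatedness.  The estimate is
    clipped to [0, 1]; the jackknife deletes sample blocks.
    """
    n = bundle.n_samples
    if n < min_samples:
        raise ValueError(f"need >= {min_samples} samples")
    maf = bundle.variants["maf"].to_numpy()
    missing = np.isnan(bundle.dosages).mean(axis=0)
    keep = (maf > maf_min) & (missing <= miss_max)
    if exclude_window is not None:
        pos = bundle.variants["pos"].to_numpy()
        keep &= ~((pos >= exclude_window[0]) & (pos <= exclude_window[1]))
    idx = np.where(keep)[0]
    idx = ld_prune(bundle.dosages, idx, r2_max=prune_r2)
    if thin_factor > 1:
        idx = idx[::thin_factor]
    if len(idx) < min_variants:
        raise ValueError(f"{len(idx)} variants after filters; floor is {min_variants}")

    z = standardize_dosages(bundle.dosages[:, idx])
    grm = (z @ z.T) / z.shape[1]

    y = bundle.phenotypes[phenotype].to_numpy(dtype=float) if isinstance(phenotype, str) else np.asarray(phenotype, dtype=float)
    X, mask = _design(bundle, covariates, cn)
    mask &= ~np.isnan(y)
    yv, Xv = y[mask], X[mask]
    Q, _ = np.linalg.qr(Xv)
    r = yv - Q @ (Q.T @ yv)
    r = r / r.std()
    grm_m = grm[np.ix_(mask, mask)]

    def he_slope(sample_keep: np.ndarray) -> float:
        g = grm_m[np.ix_(sample_keep, sample_keep)]
        rr = r[sample_keep]
        iu = np.triu_indices(len(rr), k=1)
        k_off = g[iu]
        prod = np.outer(rr, rr)[iu]
        kc = k_off - k_off.mean()
        denom = float(kc @ kc)
        if denom == 0:
            return np.nan
        return float(kc @ (prod - prod.mean()) / denom)

    nm = len(r)
    full = he_slope(np.ones(nm, dtype=bool))
    blocks = np.array_split(np.arange(nm), n_jackknife)
    pseudo = []
    for b in blocks:
        keep_b = np.ones(nm, dtype=bool)
        keep_b[b] = False
        pseudo.append(he_slope(keep_b))
    pseudo = np.asarray(pseudo)
    B = len(pseudo)
    se = float(np.sqrt((B - 1) / B * np.sum((pseudo - pseudo.mean()) ** 2)))
    return {
        "h2": float(np.clip(full, 0.0, 1.0)),
        "h2_raw": full,
        "se": se,
        "n": nm,
        "n_variants": len(idx),
    }
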