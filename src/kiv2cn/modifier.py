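"""Variant-by-KIV2-CN interaction (modifier) scan and multiplicity control.

Per variant with minor allele count above the cohort filter, the model

    phenotype ~ CN + variant + CN x variant + covariates

is fit by OLS; the modifier effect is the ``CN x variant`` coefficient (SD
per allele per CN copy).  Multiplicity is controlled by LD clumping the full
interaction results (500 kb, r^2 0.25, p1 = p2 = 1) and Bonferroni-dividing
alpha by the clump count.  Sensitivity checks guard against hits that merely
tag CN, lack any marginal phenotype association, or dissolve when
conditioning on the independent main-effect variants.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortBundle
from .cn_impute import pairwise_r2

log = logging.getLogger("kiv2cn")


def interaction_scan(bundle: CohortBundle, phenotype, cn: np.ndarray, covariates=None,
                     window: tuple[int, int] | None = None, mac_min: int = 20,
                     condition_idx=(), analysis: str = "cn_interaction") -> pd.DataFrame:
    """Per-variant CN-interaction OLS scan.

    Only variants with MAC > ``mac_min`` enter.  Uses the estimated CN (never
    simulation truth).  Rank-deficient fits are skipped with a flag.
    """
    y = bundle.phenotypes[phenotype].to_numpy(dtype=float) if isinstance(phenotype, str) else np.asarray(phenotype, dtype=float)
    cn = np.asarray(cn, dtype=float)
    keep = bundle.variants["mac"].to_numpy() > mac_min
    if window is not None:
        pos = bundle.variants["pos"].to_numpy()
        keep &= (pos >= window[0]) & (pos <= window[1])
    vidx = np.where(keep)[0]

    cov_cols = [np.ones(bundle.n_samples)]
    for c in covariates or []:
        cov_cols.append(bundle.phenotypes[c].to_numpy(dtype=float))
    for j in condition_idx:
        d = bundle.dosages[:, j]
        cov_cols.append(np.where(np.isnan(d), np.nanmean(d), d))
    C = np.column_stack(cov_cols)
    mask = ~np.isnan(C).any(axis=1) & ~np.isnan(y) & ~np.isnan(cn)
    Cm, ym, cnm = C[mask], y[mask], cn[mask]
    cn_c = cnm - cnm.mean()

    rows = []
    for j in vidx:
        g = bundle.dosages[mask, j]
        ok = ~np.isnan(g)
        Xj = np.column_stack([Cm[ok], cn_c[ok], g[ok], g[ok] * cn_c[ok]])
        yj = ym[ok]
        nj, pj = Xj.shape
        XtX = Xj.T @ Xj
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            log.info("interaction_scan: variant %d rank-deficient, skipped", j)
            continue
        beta = XtX_inv @ (Xj.T @ yj)
        resid = yj - Xj @ beta
        dof = nj - pj
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(np.diag(XtX_inv) * sigma2)
        if not np.isfinite(se[-1]) or se[-1] <= 0:
            continue
        t_int = beta[-1] / se[-1]
        rows.append(
            {
                "variant_id": bundle.variants["variant_id"].iloc[j],
                "chrom": bundle.variants["chrom"].iloc[j],
                "pos": int(bundle.variants["pos"].iloc[j]),
                "maf": float(bundle.variants["maf"].iloc[j]),
                "mac": float(bundle.variants["mac"].iloc[j]),
                "beta_main": float(beta[-2]),
                "beta_cn": float(beta[-3]),
                "beta": float(beta[-1]),          # interaction effect, SD/allele/CN copy
                "se": float(se[-1]),
                "p": float(np.clip(2 * stats.t.sf(abs(t_int), dof), np.nextafter(0, 1), 1.0)),
                "n": int(nj),
                "analysis": analysis,
                "variant_idx": int(j),
            }
        )
    columns = ["variant_id", "chrom", "pos", "maf", "mac", "beta_main", "beta_cn",
               "beta", "se", "p", "n", "analysis", "variant_idx"]
    return pd.DataFrame(rows, columns=columns) if not rows else pd.DataFrame(rows)


def clump(results: pd.DataFrame, dosages: np.ndarray, kb: float = 500.0,
          p1: float = 1.0, p2: float = 1.0, r2: float = 0.25) -> list[dict]:
    """Greedy LD clumping of an association result table.

    Repeatedly take the best remaining variant with p <= p1 as an index and
    assign to its clump every unassigned variant with p <= p2, within ``kb``
    kilobases, and squared correlation > ``r2`` with the index.  Every
    p1-passing variant ends in exactly one clump.
    """
    res = results.dropna(subset=["p"]).sort_values(["p", "pos"], kind="mergesort").reset_index(drop=True)
    assigned = set()
    clumps = []
    for _, row in res.iterrows():
        if row["variant_idx"] in assigned or row["p"] > p1:
            continue
        members = [row["variant_idx"]]
        assigned.add(row["variant_idx"])
        g_index = dosages[:, int(row["variant_idx"])]
        near = res[
            (~res["variant_idx"].isin(assigned))
            & (res["p"] <= p2)
            & (np.abs(res["pos"] - row["pos"]) <= kb * 1000)
            & (res["chrom"] == row["chrom"])
        ]
        for _, other in near.iterrows():
            if pairwise_r2(g_index, dosages[:, int(other["variant_idx"])]) > r2:
                members.append(other["variant_idx"])
                assigned.add(other["variant_idx"])
        clumps.append(
            {
                "index_variant": row["variant_id"],
                "index_idx": int(row["variant_idx"]),
                "index_p": float(row["p"]),
                "index_beta": float(row["beta"]),
                "pos": int(row["pos"]),
                "members": [int(v) for v in members],
                "n_members": len(members),
            }
        )
    return clumps


def bonferroni_threshold(n_clumps: int, alpha: float = 0.05) -> float:
    """alpha / n_clumps, exact rational arithmetic before the float cast."""
    if n_clumps < 1:
        raise ValueError("need at least one clump")
    return float(Fraction(alpha).limit_denominator(10**6) / n_clumps)


def interaction_meta(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance pooling of interaction effects across cohorts."""
    from .assoc import meta_fixed_effects

    return meta_fixed_effects(tables)


def sensitivity_checks(hits: pd.DataFrame, bundle: CohortBundle, cn: np.ndarray,
                       phenotype, covariates=None, independent_hit_idx=(),
                       r2_cn_max: float = 0.1, marginal_alpha: float = 0.05) -> pd.DataFrame:
    """Per-hit confounding checks for interaction associations.

    (a) squared Pearson correlation of dosage with CN must be < ``r2_cn_max``;
    (b) the variant must be marginally associated with the phenotype
    (p < ``marginal_alpha``); (c) the interaction p is re-estimated
    conditioning on the supplied independent main-effect hits.
    """
    if hits.empty:
        raise ValueError("hit list is empty")
    cn = np.asarray(cn, dtype=float)
    if np.isnan(cn).all():
        raise ValueError("CN is missing")
    y = bundle.phenotypes[phenotype].to_numpy(dtype=float) if isinstance(phenotype, str) else np.asarray(phenotype, dtype=float)

    cov_cols = [np.ones(bundle.n_samples)]
    for c in covariates or []:
        cov_cols.append(bundle.phenotypes[c].to_numpy(dtype=float))
    C = np.column_stack(cov_cols)

    rows = []
    for _, hit in hits.iterrows():
        j = int(hit["variant_idx"])
        g = bundle.dosages[:, j]
        r2_cn = pairwise_r2(g, cn)

        ok = ~np.isnan(g) & ~np.isnan(y) & ~np.isnan(C).any(axis=1)
        import statsmodels.api as sm

        X = np.column_stack([C[ok], g[ok]])
        marg = sm.OLS(y[ok], X).fit()
        marginal_p = float(marg.pvalues[-1])

        cond = interaction_scan(
            bundle, y, cn, covariates=covariates, mac_min=0,
            window=(int(hit["pos"]), int(hit["pos"])),
            condition_idx=tuple(k for k in independent_hit_idx if k != j),
        )
        cond_row = cond[cond["variant_idx"] == j]
        cond_p = float(cond_row["p"].iloc[0]) if not cond_row.empty else np.nan

        rows.append(
            {
                "variant_id": hit["variant_id"],
                "variant_idx": j,
                "r2_with_cn": r2_cn,
                "pass_r2_cn": r2_cn < r2_cn_max,
                "marginal_p": marginal_p,
                "pass_marginal": marginal_p < marginal_alpha,
                "conditional_interaction_p": cond_p,
                "pass_all": (r2_cn < r2_cn_max) and (marginal_p < marginal_alpha),
            }
        )
    return pd.DataFrame(rows)
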