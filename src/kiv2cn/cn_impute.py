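"""Sparse SNP panel imputing diploid KIV2-CN from genotypes.

Protocol: split the cohort two-thirds / one-third keeping sibling pairs in
the same split; restrict to high-quality common variants in a window around
the locus; LD-prune (sliding 50-variant window, step 5, r^2 0.25); fit a
LASSO over a 100-point log-spaced lambda path with 10-fold cross-validation
choosing the CV-MSE minimizer; refit on the full training set; quantify
per-variant importance with a random-forest regression; validate by Pearson
correlation on the held-out split.  The training response is the read-depth
CN estimate, not the simulation truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .core import CohortBundle

log = logging.getLogger("kiv2cn")


@dataclass
class CNPanel:
    """A fitted CN imputation panel: selected variants, weights, metadata."""

    variant_ids: list[str]
    coefficients: np.ndarray        # on the raw dosage scale
    intercept: float
    lambda_: float
    training_r2: float
    training_mafs: np.ndarray = field(default_factory=lambda: np.array([]))
    validation_r: float = np.nan
    validation_r2: float = np.nan
    seed: int = 0

    def to_json(self, path: str) -> None:
        obj = {
            "variant_ids": list(self.variant_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "training_r2": float(self.training_r2),
            "training_mafs": [float(m) for m in self.training_mafs],
            "validation_r": None if np.isnan(self.validation_r) else float(self.validation_r),
            "validation_r2": None if np.isnan(self.validation_r2) else float(self.validation_r2),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "CNPanel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            variant_ids=obj["variant_ids"],
            coefficients=np.asarray(obj["coefficients"], dtype=float),
            intercept=obj["intercept"],
            lambda_=obj["lambda"],
            training_r2=obj["training_r2"],
            training_mafs=np.asarray(obj.get("training_mafs", []), dtype=float),
            validation_r=np.nan if obj["validation_r"] is None else obj["validation_r"],
            validation_r2=np.nan if obj["validation_r2"] is None else obj["validation_r2"],
            seed=obj.get("seed", 0),
        )


def split_train_validate(bundle: CohortBundle, fraction: float = 2 / 3, seed: int = 0,
                         sib_pairs=None):
    """Disjoint, exhaustive train/validation split keeping siblings together.

    Sibling pairs (index pairs into the bundle) are treated as indivisible
    units; with no pairs the training size is exactly ``round(n * fraction)``
    and within one sample of it otherwise.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    n = bundle.n_samples
    if n < 30:
        raise ValueError("need at least 30 samples to split")
    target = int(round(n * fraction))
    groups = []
    in_pair = set()
    for i, j in (sib_pairs or []):
        groups.append([i, j])
        in_pair.update((i, j))
    groups.extend([[i] for i in range(n) if i not in in_pair])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    train_idx = []
    for gi in order:
        if len(train_idx) >= target:
            break
        if len(train_idx) + len(groups[gi]) <= target or len(groups[gi]) == 1:
            train_idx.extend(groups[gi])
        elif target - len(train_idx) >= 1 and len(train_idx) + len(groups[gi]) - target <= 1:
            train_idx.extend(groups[gi])  # pair straddling the boundary: keep together, +-1 allowed
    train_set = set(train_idx)
    val_idx = [i for i in range(n) if i not in train_set]
    return bundle.subset_samples(np.array(sorted(train_set))), bundle.subset_samples(np.array(val_idx))


def filter_panel_variants(variants: pd.DataFrame, window: tuple[int, int],
                          maf_min: float = 0.001, info_min: float = 0.8) -> np.ndarray:
    """Indices of variants inside the window passing MAF and quality filters."""
    pos = variants["pos"].to_numpy()
    in_win = (pos >= window[0]) & (pos <= window[1])
    pass_maf = variants["maf"].to_numpy() > maf_min
    pass_info = variants["info_score"].to_numpy() > info_min
    keep = in_win & pass_maf & pass_info
    if not keep.any():
        raise ValueError(
            f"no variants pass filters: window {int(in_win.sum())}, "
            f"maf {int((in_win & pass_maf).sum())}, info {int(keep.sum())} of {len(variants)}"
        )
    return np.where(keep)[0]


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on complete cases."""
    mx = ~np.isnan(x) & ~np.isnan(y)
    if mx.sum() < 3:
        return 0.0
    xv, yv = x[mx], y[mx]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


def ld_prune(dosages: np.ndarray, variant_idx=None, window_variants: int = 50,
             step: int = 5, r2_max: float = 0.25, drop: str = "later",
             mafs: np.ndarray | None = None) -> np.ndarray:
    """Greedy sliding-window LD pruning (50-variant window, step 5 semantics).

    Within each window, while any retained pair exceeds ``r2_max``, one of
    the pair is dropped: the later variant in position order by default, or
    the lower-MAF variant with ``drop="maf"``.  Output preserves input order
    and is deterministic given the input order.  Correlations are computed
    on mean-imputed dosages (identical to complete-case Pearson when nothing
    is missing).
    """
    if variant_idx is None:
        variant_idx = np.arange(dosages.shape[1])
    variant_idx = np.asarray(variant_idx)
    if len(variant_idx) < 2:
        return variant_idx
    from .core import standardize_dosages

    z = standardize_dosages(dosages[:, variant_idx])
    n = z.shape[0]
    kept = np.ones(len(variant_idx), dtype=bool)
    m = len(variant_idx)
    for start in range(0, max(m - window_variants, 0) + step, step):
        stop = min(start + window_variants, m)
        local = np.where(kept[start:stop])[0] + start
        if len(local) < 2:
            if stop >= m:
                break
            continue
        r2 = (z[:, local].T @ z[:, local] / n) ** 2
        np.fill_diagonal(r2, 0.0)
        alive = np.ones(len(local), dtype=bool)
        while True:
            sub = r2 * np.outer(alive, alive)
            a, b = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[a, b] <= r2_max:
                break
            a, b = min(a, b), max(a, b)
            if drop == "maf" and mafs is not None and mafs[variant_idx[local[a]]] < mafs[variant_idx[local[b]]]:
                alive[a] = False
            else:
                alive[b] = False
        kept[local[~alive]] = False
        if stop >= m:
            break
    return variant_idx[kept]


def fit_lasso_panel(bundle: CohortBundle, response: np.ndarray, candidate_idx: np.ndarray,
                    k_folds: int = 10, seed: int = 0, n_lambdas: int = 100) -> CNPanel:
    """LASSO over a log-spaced lambda path, 10-fold CV, refit at the minimizer.

    Predictors are standardized internally; reported coefficients are on the
    raw dosage scale.  Zero-variance candidates are dropped with a warning.
    """
    if bundle.n_samples <= k_folds:
        raise ValueError("training set smaller than fold count")
    X = bundle.dosages[:, candidate_idx]
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    if len(inds[0]):
        X = X.copy()
        X[inds] = np.take(col_mean, inds[1])
    sd = X.std(axis=0)
    nonconst = sd > 0
    if not nonconst.all():
        log.warning("fit_lasso_panel: dropping %d zero-variance candidates", int((~nonconst).sum()))
    candidate_idx = candidate_idx[nonconst]
    X = X[:, nonconst]
    sd = sd[nonconst]
    Xs = (X - X.mean(axis=0)) / sd
    y = np.asarray(response, dtype=float)
    yc = y - y.mean()

    lam_max = np.max(np.abs(Xs.T @ yc)) / len(y)
    alphas = np.logspace(np.log10(lam_max), np.log10(lam_max) - 4, n_lambdas)
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=alphas, cv=cv, max_iter=50_000, tol=1e-6)
    model.fit(Xs, y)
    best = Lasso(alpha=model.alpha_, max_iter=50_000, tol=1e-8)
    best.fit(Xs, y)

    sel = np.abs(best.coef_) > 0
    coef_raw = best.coef_[sel] / sd[sel]
    sel_idx = candidate_idx[sel]
    intercept = float(y.mean() - np.sum(coef_raw * X[:, sel].mean(axis=0))) if sel.any() else float(y.mean())
    fitted = intercept + bundle.dosages[:, sel_idx] @ coef_raw if sel.any() else np.full(len(y), intercept)
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return CNPanel(
        variant_ids=[bundle.variants["variant_id"].iloc[k] for k in sel_idx],
        coefficients=coef_raw,
        intercept=intercept,
        lambda_=float(model.alpha_),
        training_r2=float(1 - ss_res / ss_tot) if ss_tot > 0 else np.nan,
        training_mafs=bundle.variants["maf"].to_numpy()[sel_idx],
        seed=seed,
    )


def rank_importance(panel: CNPanel, bundle: CohortBundle, response: np.ndarray,
                    n_trees: int = 200, seed: int = 0) -> pd.DataFrame:
    """Random-forest importance of each panel variant, normalized to sum 1."""
    if not panel.variant_ids:
        raise ValueError("panel is empty")
    idx = _panel_columns(panel, bundle)
    X = np.nan_to_num(bundle.dosages[:, idx], nan=0.0)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(X, np.asarray(response, dtype=float))
    imp = rf.feature_importances_
    tot = imp.sum()
    imp = imp / tot if tot > 0 else np.full(len(imp), 1.0 / len(imp))
    out = pd.DataFrame({"variant_id": panel.variant_ids, "importance": imp})
    return out.sort_values("importance", ascending=False).reset_index(drop=True)


def _panel_columns(panel: CNPanel, bundle: CohortBundle) -> np.ndarray:
    lookup = {v: k for k, v in enumerate(bundle.variants["variant_id"])}
    missing = [v for v in panel.variant_ids if v not in lookup]
    if len(panel.variant_ids) and len(missing) / len(panel.variant_ids) > 0.2:
        raise ValueError(f"{len(missing)} of {len(panel.variant_ids)} panel variants absent")
    return np.array([lookup.get(v, -1) for v in panel.variant_ids])


def apply_panel(panel: CNPanel, bundle: CohortBundle) -> np.ndarray:
    """Impute CN: intercept + sum(coef * dosage); missing -> 2*MAF mean."""
    if not panel.variant_ids:
        return np.full(bundle.n_samples, panel.intercept)
    cols = _panel_columns(panel, bundle)
    score = np.full(bundle.n_samples, panel.intercept)
    for k, (col, coef) in enumerate(zip(cols, panel.coefficients)):
        if col < 0:
            fill = 2 * panel.training_mafs[k] if len(panel.training_mafs) else 0.0
            log.info("apply_panel: variant %s absent, mean-substituting %.4f", panel.variant_ids[k], fill)
            score += coef * fill
            continue
        d = bundle.dosages[:, col]
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        score += coef * d
    return score


def validate_panel(panel: CNPanel, bundle: CohortBundle, response: np.ndarray) -> dict:
    """Held-out Pearson r (and its square) between imputed and estimated CN."""
    pred = apply_panel(panel, bundle)
    y = np.asarray(response, dtype=float)
    if np.std(pred) == 0:
        log.warning("validate_panel: constant predictions, correlation undefined")
        return {"pearson_r": np.nan, "r_squared": np.nan, "n": len(y)}
    r = float(np.corrcoef(pred, y)[0, 1])
    panel.validation_r = r
    panel.validation_r2 = r**2
    return {"pearson_r": r, "r_squared": r**2, "n": len(y)}
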