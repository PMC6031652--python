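"""Mendelian-randomization instruments and outcome models.

Three genetic instruments are built per cohort:

* **GRS** — a weighted allele score over LD-clumped variants reaching
  sub-threshold significance (p < 1e-4) in the CN-adjusted single-variant
  scan, weighted by those CN-adjusted effect sizes;
* **KIV2-CN** — the directly estimated or imputed diploid repeat count;
* **combined** — the sum of the two calibrated instruments, re-calibrated.

Each instrument is inverse-rank normalized and rescaled so that a one-unit
increase equals one phenotype SD in the calibration cohort: the scale factor
is the OLS slope of the rank-normalized phenotype on the normalized score
(negative for the CN score, since copy number is inversely related to the
phenotype), and by construction the post-hoc slope of phenotype on the final
instrument is exactly 1.  Outcome models are Cox proportional hazards
(Breslow ties, via lifelines) for incident events and OLS for quantitative
outcomes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .core import CohortBundle, inverse_rank_normalize
from .modifier import clump

log = logging.getLogger("kiv2cn")


@dataclass
class Instrument:
    kind: str                                # "GRS" | "KIV2CN" | "COMBINED"
    raw: np.ndarray
    samples: list[str]
    variant_ids: list[str] = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    normalized: np.ndarray | None = None
    scale_factor: float = np.nan
    final: np.ndarray | None = None
    calibration_cohort: str = ""
    variance_explained: float = np.nan

    def to_json(self, path: str) -> None:
        obj = {
            "kind": self.kind,
            "variant_ids": list(self.variant_ids),
            "weights": [float(w) for w in self.weights],
            "scale_factor": None if np.isnan(self.scale_factor) else float(self.scale_factor),
            "calibration_cohort": self.calibration_cohort,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


@dataclass
class MRResult:
    outcome: str
    instrument: str
    effect: float          # HR per phenotype SD (events) or SD per SD (quantitative)
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_cases: int | None = None


def build_grs(results: pd.DataFrame, bundle: CohortBundle,
              window: tuple[int, int] | None = None, p1: float = 1e-4,
              clump_kb: float = 500.0, clump_r2: float = 0.25) -> Instrument:
    """Weighted allele score over clumped sub-threshold CN-adjusted hits.

    ``results`` must come from a scan run with ``adjust_cn=True``.  Missing
    dosages are substituted with twice the allele frequency (logged).
    """
    res = results[~results.get("skipped", False)].copy()
    if window is not None:
        res = res[(res["pos"] >= window[0]) & (res["pos"] <= window[1])]
    if not (res["p"] <= p1).any():
        raise ValueError(f"no variants reach p <= {p1}; cannot build GRS")
    clumps = clump(res, bundle.dosages, kb=clump_kb, p1=p1, p2=1.0, r2=clump_r2)
    idx = [c["index_idx"] for c in clumps]
    betas = np.array([c["index_beta"] for c in clumps])
    score = np.zeros(bundle.n_samples)
    for j, b in zip(idx, betas):
        d = bundle.dosages[:, j]
        if np.isnan(d).any():
            fill = 2 * bundle.variants["maf"].iloc[j]
            log.info("build_grs: mean-substituting %d missing dosages at %s",
                     int(np.isnan(d).sum()), bundle.variants["variant_id"].iloc[j])
            d = np.where(np.isnan(d), fill, d)
        score += b * d
    return Instrument(
        kind="GRS",
        raw=score,
        samples=list(bundle.samples),
        variant_ids=[bundle.variants["variant_id"].iloc[j] for j in idx],
        weights=betas,
    )


def build_cn_score(cn: np.ndarray, samples, missing_max: float = 0.1) -> Instrument:
    """The KIV2-CN instrument: the raw score is the copy number itself."""
    cn = np.asarray(cn, dtype=float)
    frac_missing = np.isnan(cn).mean()
    if frac_missing > missing_max:
        raise ValueError(f"CN missing for {frac_missing:.1%} of samples (max {missing_max:.0%})")
    return Instrument(kind="KIV2CN", raw=cn, samples=list(samples))


def normalize_instrument(instr: Instrument, phenotype_norm: np.ndarray,
                         cohort: str = "calibration", min_slope: float = 0.01) -> Instrument:
    """Calibrate so that one instrument unit equals one phenotype SD.

    The raw score is inverse-rank normalized; the scale factor is the OLS
    slope of the rank-normalized phenotype on the normalized score; the final
    instrument is ``scale_factor * normalized``.  An absolute slope below
    ``min_slope`` means the instrument carries no usable signal.
    """
    y = np.asarray(phenotype_norm, dtype=float)
    ok = ~np.isnan(instr.raw) & ~np.isnan(y)
    s_norm = np.full(len(instr.raw), np.nan)
    if np.nanstd(instr.raw[ok]) == 0:
        raise ValueError("constant score cannot be normalized")
    s_norm[ok] = inverse_rank_normalize(instr.raw[ok])
    X = sm.add_constant(s_norm[ok])
    slope = float(sm.OLS(y[ok], X).fit().params[1])
    if abs(slope) < min_slope:
        raise ValueError(f"uninformative instrument: |slope| = {abs(slope):.4f} < {min_slope}")
    instr.normalized = s_norm
    instr.scale_factor = slope
    instr.final = slope * s_norm
    instr.calibration_cohort = cohort
    return instr


def combine_scores(grs: Instrument, cn: Instrument, phenotype_norm: np.ndarray,
                   cohort: str = "calibration") -> Instrument:
    """Sum of the two calibrated instruments, re-calibrated as one score."""
    if grs.samples != cn.samples:
        raise ValueError("instruments were built on different sample sets")
    if grs.final is None or cn.final is None:
        raise ValueError("both instruments must be calibrated before combining")
    combined = Instrument(kind="COMBINED", raw=grs.final + cn.final, samples=list(grs.samples))
    return normalize_instrument(combined, phenotype_norm, cohort=cohort)


def grs_raw_score(instr: Instrument, bundle: CohortBundle) -> np.ndarray:
    """Apply a GRS instrument's variant weights to a (possibly new) cohort."""
    if not instr.variant_ids:
        raise ValueError("instrument has no variant weights")
    lookup = {v: k for k, v in enumerate(bundle.variants["variant_id"])}
    score = np.zeros(bundle.n_samples)
    for vid, w in zip(instr.variant_ids, instr.weights):
        j = lookup.get(vid)
        if j is None:
            log.info("grs_raw_score: variant %s absent from target cohort", vid)
            continue
        d = bundle.dosages[:, j]
        if np.isnan(d).any():
            d = np.where(np.isnan(d), 2 * bundle.variants["maf"].iloc[j], d)
        score += w * d
    return score


def transfer_instrument(instr: Instrument, raw_new: np.ndarray, samples) -> Instrument:
    """Carry a calibrated instrument to a new cohort without re-calibration.

    The new raw scores are inverse-rank normalized within the target cohort
    and scaled by the calibration cohort's stored scale factor, so the unit
    of the transferred instrument remains one calibration-phenotype SD.
    """
    if np.isnan(instr.scale_factor):
        raise ValueError("instrument must be calibrated before transfer")
    s_norm = inverse_rank_normalize(np.asarray(raw_new, dtype=float))
    out = Instrument(
        kind=instr.kind,
        raw=np.asarray(raw_new, dtype=float),
        samples=list(samples),
        variant_ids=list(instr.variant_ids),
        weights=np.asarray(instr.weights),
        normalized=s_norm,
        scale_factor=instr.scale_factor,
        final=instr.scale_factor * s_norm,
        calibration_cohort=instr.calibration_cohort,
    )
    return out


def mr_cox(events: pd.DataFrame, instr: Instrument, covariates: pd.DataFrame | None = None,
           min_events: int = 20, outcome: str = "event") -> MRResult:
    """Cox proportional-hazards association of an instrument with event times.

    Breslow tie handling; Wald CI and p.  Requires at least ``min_events``
    observed events.
    """
    score = instr.final if instr.final is not None else instr.raw
    df = pd.DataFrame({"time": events["time"].to_numpy(), "status": events["status"].to_numpy(),
                       "score": np.asarray(score, dtype=float)})
    if covariates is not None:
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy(dtype=float)
    df = df.dropna()
    n_cases = int(df["status"].sum())
    if n_cases == 0:
        raise ValueError("no events observed")
    if n_cases < min_events:
        raise ValueError(f"only {n_cases} events; need >= {min_events}")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="status")
    coef = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    return MRResult(
        outcome=outcome,
        instrument=instr.kind,
        effect=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        p=float(cph.summary.loc["score", "p"]),
        n=len(df),
        n_cases=n_cases,
    )


def mr_quantitative(outcome_norm: np.ndarray, instr: Instrument,
                    covariates: pd.DataFrame | None = None, outcome: str = "trait") -> MRResult:
    """OLS association of an instrument with a rank-normalized outcome."""
    score = instr.final if instr.final is not None else instr.raw
    y = np.asarray(outcome_norm, dtype=float)
    cols = [np.asarray(score, dtype=float)]
    names = ["score"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    ok = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    fit = sm.OLS(y[ok], sm.add_constant(X[ok])).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return MRResult(
        outcome=outcome,
        instrument=instr.kind,
        effect=beta,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p=float(fit.pvalues[1]),
        n=int(ok.sum()),
    )


def variance_explained(instr: Instrument, phenotype_norm: np.ndarray,
                       cohort_label: str = "held_out", min_n: int = 30) -> dict:
    """Squared correlation of the instrument with the normalized phenotype."""
    score = instr.final if instr.final is not None else instr.raw
    y = np.asarray(phenotype_norm, dtype=float)
    ok = ~np.isnan(score) & ~np.isnan(y)
    if ok.sum() < min_n:
        raise ValueError(f"need >= {min_n} samples")
    r = np.corrcoef(score[ok], y[ok])[0, 1]
    instr.variance_explained = float(r**2)
    return {"r_squared": float(r**2), "n": int(ok.sum()), "cohort": cohort_label}


def pca_covariates(dosages: np.ndarray, k: int = 5) -> pd.DataFrame:
    """Top principal components of the standardized dosage matrix."""
    from .core import standardize_dosages

    z = standardize_dosages(dosages)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    return pd.DataFrame(pcs, columns=[f"pc{i + 1}" for i in range(k)])
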