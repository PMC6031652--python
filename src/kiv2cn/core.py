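"""Domain types, phenotype preparation and allele statistics.

The central in-memory container is :class:`CohortBundle`: an aligned set of

* a dosage matrix (samples x variants, ``NaN`` marks missing genotypes),
* a variant table (``variant_id, chrom, pos, ref, alt, maf, mac, info_score``),
* a phenotype/covariate table indexed by sample id,
* optional per-sample depth summaries and an optional kinship matrix.

Coordinates in external files are 1-based inclusive (the convention used for
the printed locus intervals); everything in memory keeps the same 1-based
positions, and any half-open arithmetic is done locally where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "maf", "mac", "info_score"]

#: statin back-correction divisors for treated individuals
STATIN_TC_DIVISOR = 0.8
STATIN_LDL_DIVISOR = 0.7


@dataclass
class RepeatModel:
    """Geometry of the KIV2 repeat locus plus the copy-ratio transform.

    ``scale_a`` and ``offset_b`` map the diploid copy ratio rho (2 for a
    reference-structured diploid genome) to the diploid count of KIV2
    protein domains: ``cn = rho * scale_a - offset_b``.  With the defaults a
    reference-like sample (rho = 2) maps to 2 * 6.354 - 0.708 = 12 domains,
    i.e. 6 per haplotype as laid out in the hg19 reference.  The constants
    are configuration, never recomputed.
    """

    chrom: str = "6"
    start: int = 161_032_614          # 1-based inclusive, hg19 genotyping interval
    end: int = 161_067_851
    unit_length_range: tuple[int, int] = (5534, 5546)
    scale_a: float = 6.354
    offset_b: float = 0.708
    control_intervals: list[tuple[int, int]] = field(
        default_factory=lambda: [(159_000_000, 159_099_999), (163_000_000, 163_099_999)]
    )

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("repeat interval end must exceed start")
        if self.scale_a <= 0:
            raise ValueError("scale_a must be positive")
        if self.offset_b < 0:
            raise ValueError("offset_b must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CohortBundle:
    """Aligned genotype + phenotype container consumed by every stage."""

    samples: list[str]
    dosages: np.ndarray                 # n_samples x n_variants, NaN = missing
    variants: pd.DataFrame              # VARIANT_COLUMNS
    phenotypes: pd.DataFrame            # indexed by sample id
    depth: pd.DataFrame | None = None   # sample, chrom, start, end, mean_depth
    kinship: np.ndarray | None = None
    name: str = "cohort"

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample count does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant count does not match dosage columns")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(self.dosages, initial=0.0) > 2 + 1e-9:
                raise ValueError("dosages outside [0, 2]")
        if not self.phenotypes.index.equals(pd.Index(self.samples)):
            raise ValueError("phenotype table index must equal the sample list")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_samples(self, idx: np.ndarray) -> "CohortBundle":
        idx = np.asarray(idx)
        samples = [self.samples[i] for i in idx]
        depth = None
        if self.depth is not None:
            depth = self.depth[self.depth["sample"].isin(samples)].reset_index(drop=True)
        kin = self.kinship[np.ix_(idx, idx)] if self.kinship is not None else None
        return CohortBundle(
            samples=samples,
            dosages=self.dosages[idx],
            variants=self.variants.copy(),
            phenotypes=self.phenotypes.iloc[idx].copy(),
            depth=depth,
            kinship=kin,
            name=self.name,
        )


def inverse_rank_normalize(values, cohort_labels=None) -> np.ndarray:
    """Rank-based inverse normal transform, applied separately by cohort.

    Within each cohort the transform is ``Phi^-1((rank - 0.5) / n)`` over the
    non-missing values, with average ranks for ties.  Missing values stay
    missing.  A cohort whose non-missing values are all identical has no
    defined ranking and raises ``ValueError``.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    if cohort_labels is None:
        cohort_labels = np.zeros(len(values), dtype=int)
    cohort_labels = np.asarray(cohort_labels)
    for label in pd.unique(cohort_labels):
        sel = (cohort_labels == label) & ~np.isnan(values)
        n = int(sel.sum())
        if n < 2:
            raise ValueError(f"cohort {label!r}: need >= 2 non-missing values")
        v = values[sel]
        if np.all(v == v[0]):
            raise ValueError(f"cohort {label!r}: all values identical, ranks undefined")
        ranks = stats.rankdata(v, method="average")
        out[sel] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def statin_adjust(total_chol, ldl, on_statin):
    """Back-correct lipid concentrations for statin treatment.

    For treated individuals total cholesterol is divided by 0.8 and LDL
    cholesterol by 0.7 (average on-treatment reductions); untreated values
    pass through unchanged.
    """
    tc = np.asarray(total_chol, dtype=float)
    ldl = np.asarray(ldl, dtype=float)
    on = np.asarray(on_statin, dtype=bool)
    if np.nanmin(tc) < 0 or np.nanmin(ldl) < 0:
        raise ValueError("concentrations must be non-negative")
    tc_adj = np.where(on, tc / STATIN_TC_DIVISOR, tc)
    ldl_adj = np.where(on, ldl / STATIN_LDL_DIVISOR, ldl)
    return tc_adj, ldl_adj


def allele_stats(dosages: np.ndarray) -> pd.DataFrame:
    """Per-variant minor-allele frequency and count from a dosage matrix.

    Missing dosages (NaN) are excluded per variant.  ``maf`` is folded to the
    minor allele; ``mac`` is the rounded minor-allele dosage sum over
    non-missing samples.  Variants with every genotype missing get
    ``maf = NaN`` and are flagged.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty genotype matrix")
    n_obs = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        alt_sum = np.nansum(d, axis=0)
        af = np.where(n_obs > 0, alt_sum / (2 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(af, 1 - af)
    minor_sum = np.where(af <= 0.5, alt_sum, 2 * n_obs - alt_sum)
    mac = np.where(n_obs > 0, np.round(minor_sum), np.nan)
    return pd.DataFrame(
        {
            "maf": maf,
            "mac": mac,
            "n_obs": n_obs,
            "all_missing": n_obs == 0,
        }
    )


def empirical_kinship(dosages: np.ndarray, maf_min: float = 0.01) -> np.ndarray:
    """Empirical kinship (genomic relationship) matrix from standardized dosages."""
    st = allele_stats(dosages)
    keep = (st["maf"].to_numpy() > maf_min) & ~st["all_missing"].to_numpy()
    z = standardize_dosages(dosages[:, keep])
    m = z.shape[1]
    if m == 0:
        raise ValueError("no variants left for kinship construction")
    return (z @ z.T) / m


def standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages and scale each variant to mean 0, SD 1.

    Monomorphic variants come back as all-zero columns.
    """
    d = np.array(dosages, dtype=float)
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return (d - d.mean(axis=0)) / sd
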