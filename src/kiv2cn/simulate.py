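"""Synthetic-cohort generator with complete truth tables.

The generator emulates the features of real sequencing cohorts the downstream
analyses rely on, without coalescent realism:

* **SNP haplotypes with blockwise LD.**  Each haplotype walks along a small
  pool of backbone haplotypes with a per-site switch probability (a
  phenomenological recombination analogue) plus per-site mutation noise, so
  nearby sites are correlated and correlation decays with distance.
* **A multi-allelic repeat-CN allele in LD with the SNPs.**  Per-haplotype
  KIV2 copy number is a backbone-specific value plus noise, scaled so the
  SNP/backbone-explained fraction of diploid CN variance hits a configured
  tagging r-squared.  Diploid CN distributions differ by ancestry: African
  ancestry mean 38.5 (SD 7.4), European mean 43.7 (SD 6.2), bounded to
  [12, 85] copies.
* **Read depth proportional to copy count.**  Interval mean depth is
  negative-binomial around coverage (control intervals) or around
  ``(coverage / 2) * (diploid_cn + offset_b) / scale_a`` (repeat interval),
  the exact inverse of the estimation transform.
* **An inverse CN -> phenotype effect on the SD scale** (default -0.07 SD per
  copy) plus independent SNP effects, covariates and optional variant-by-CN
  interaction terms.
* **Sibling pairs** sharing both locus haplotypes (hence allelic CN), for
  IBD2-based precision analysis.
* **Incident event times** with hazard depending on the phenotype (and
  optionally on the SNP genetic score directly, emulating pathways that
  bypass the lipoprotein level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CohortBundle, RepeatModel, allele_stats, inverse_rank_normalize

#: printed diploid CN distributions by ancestry: (mean, SD)
ANCESTRY_CN = {"african": (38.5, 7.4), "european": (43.7, 6.2)}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the conditions of the source cohorts: diploid CN
    distribution by ancestry, CN bounds 12-85 copies, a -0.07 SD-per-copy
    phenotype effect, SNP tagging r-squared 0.60, 30x sequencing depth.
    """

    n_samples: int = 2000
    n_variants: int = 400
    chrom: str = "6"
    window_start: int = 158_532_140       # ~4 Mb window around the locus
    window_end: int = 162_664_257
    repeat_pos: int = 161_050_232         # midpoint of the repeat interval

    ancestry: str = "african"
    cn_mean: float | None = None          # None -> ancestry default
    cn_sd: float | None = None
    cn_bounds: tuple[float, float] = (12.0, 85.0)

    # LD / tagging structure
    ld_mode: str = "backbone"             # "backbone" | "independent"
    n_backbones: int = 32
    backbone_switch_prob: float = 0.03    # per-site backbone switch probability
    mutation_rate: float = 0.01           # per-site allele flip probability
    tagging_r2: float = 0.60              # SNP-explained fraction of diploid CN variance
    n_tag_snps: int = 15                  # CN-tagging SNPs near the locus
    integer_alleles: bool = False

    # phenotype model
    cn_effect: float = -0.07              # SD per diploid copy
    n_causal_snps: int = 5
    snp_h2: float = 0.20                  # variance fraction of independent SNP effects
    n_interaction_snps: int = 0
    interaction_effect: float = 0.0       # SD per copy per allele
    age_effect: float = 0.0
    sex_effect: float = 0.0
    residual_sd: float | None = None      # None -> complete latent variance to 1

    sib_pair_fraction: float = 0.0

    # sequencing depth model
    coverage: float = 30.0
    depth_dispersion: float = 3e-5        # NB: var = mu + phi mu^2; 0 -> Poisson
    depth_noise: bool = True              # False -> deterministic expected depth
    read_length: int = 150

    # incident-event model
    event_baseline_hazard: float = 0.005  # per year
    event_loghr: float = 0.0              # per phenotype SD
    event_snp_direct_loghr: float = 0.0   # per SD of the SNP genetic score
    censor_time: float = 10.0             # years

    seed: int = 0
    panel_seed: int | None = None         # share variant panel across cohorts

    def __post_init__(self) -> None:
        if self.cn_mean is None or self.cn_sd is None:
            if self.ancestry not in ANCESTRY_CN:
                raise ValueError(f"unknown ancestry {self.ancestry!r} and no explicit cn_mean/cn_sd")
            mean, sd = ANCESTRY_CN[self.ancestry]
            self.cn_mean = mean if self.cn_mean is None else self.cn_mean
            self.cn_sd = sd if self.cn_sd is None else self.cn_sd
        if self.cn_sd <= 0:
            raise ValueError("cn_sd must be positive")
        if not (0 <= self.tagging_r2 < 1):
            raise ValueError("tagging_r2 must be in [0, 1)")
        if self.cn_bounds[0] <= 0:
            raise ValueError("CN bounds must be positive")
        if self.n_backbones < 1:
            raise ValueError("backbone pool must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Everything the generator knows that an analyst would not."""

    allelic_cn: np.ndarray                # n x 2, diploid CN = row sum
    snp_betas: np.ndarray                 # per-variant phenotype effects
    interaction_betas: np.ndarray         # per-variant CN-interaction effects
    causal_idx: np.ndarray
    interaction_idx: np.ndarray
    locus_site: int                       # variant index nearest the repeat
    tagging_r2_realized: float = np.nan
    cn_variance_frac: float = np.nan      # realized CN -> phenotype R^2
    snp_variance_frac: float = np.nan
    sib_pairs: list[tuple[int, int]] = field(default_factory=list)
    latent: np.ndarray | None = None
    snp_score: np.ndarray | None = None   # standardized SNP genetic component
    event_times_precensor: np.ndarray | None = None

    @property
    def diploid_cn(self) -> np.ndarray:
        return self.allelic_cn.sum(axis=1)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _draw_panel(config: SimConfig, seed: int):
    """Variant-panel definition: positions, site frequencies, backbone pool.

    Drawn from the panel seed when one is configured, so two cohorts (e.g.
    different ancestries) can share identical variant definitions and LD
    structure while sampling independent haplotypes.
    """
    rng = np.random.default_rng(config.panel_seed if config.panel_seed is not None else seed)
    m = config.n_variants
    pos = np.sort(rng.choice(np.arange(config.window_start, config.window_end), size=m, replace=False))
    if config.ld_mode == "independent":
        freqs = np.exp(rng.uniform(np.log(0.01), np.log(0.5), size=m))
        return pos, freqs, None, None
    K = config.n_backbones
    freqs = rng.uniform(0.02, 0.5, size=m)
    backbones = (rng.random((K, m)) < freqs).astype(np.int8)
    weights = rng.dirichlet(np.full(K, 5.0))
    return pos, freqs, backbones, weights


def _panel_maf_and_r2(backbones: np.ndarray, weights: np.ndarray):
    """Population-level MAF and pairwise allele r^2 implied by the backbone pool."""
    p = weights @ backbones
    cov = (backbones.T * weights) @ backbones - np.outer(p, p)
    var = p * (1 - p)
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, (cov / np.where(denom > 0, denom, 1.0)) ** 2, 1.0)
    np.fill_diagonal(r2, 0.0)
    return np.minimum(p, 1 - p), r2


def simulate_genotypes(config: SimConfig, seed: int):
    """Draw haplotypes and return (dosages, variant table, haplotype state).

    In ``backbone`` mode the third element is the (2n x m) backbone-index
    array underlying each haplotype; in ``independent`` mode it is the raw
    (2n x m) allele array.
    """
    if config.n_variants < 10:
        raise ValueError("need at least 10 variants")
    rng = np.random.default_rng(seed)
    n, m = config.n_samples, config.n_variants
    pos, freqs, backbones, weights = _draw_panel(config, seed)

    if config.ld_mode == "independent":
        haps = (rng.random((2 * n, m)) < freqs).astype(np.int8)
        state = haps
    elif config.ld_mode == "backbone":
        K = config.n_backbones
        chain = np.empty((2 * n, m), dtype=np.int16)
        chain[:, 0] = rng.choice(K, size=2 * n, p=weights)
        for s in range(1, m):
            switch = rng.random(2 * n) < config.backbone_switch_prob
            chain[:, s] = np.where(switch, rng.choice(K, size=2 * n, p=weights), chain[:, s - 1])
        haps = backbones[chain, np.arange(m)]
        if config.mutation_rate > 0:
            flip = rng.random((2 * n, m)) < config.mutation_rate
            haps = np.where(flip, 1 - haps, haps)
        state = chain
    else:
        raise ValueError(f"unknown ld_mode {config.ld_mode!r}")

    dosages = (haps[0::2] + haps[1::2]).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{j:05d}" for j in range(m)],
            "chrom": config.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "info_score": 1.0,
        }
    )
    st = allele_stats(dosages)
    variants["maf"] = st["maf"].to_numpy()
    variants["mac"] = st["mac"].to_numpy()
    return dosages, variants, haps, state


def simulate_repeat_alleles(config: SimConfig, variants: pd.DataFrame, haps: np.ndarray, seed: int):
    """Per-haplotype repeat CN tagged by the local haplotype alleles.

    The genetic component of each haplotype's CN is a weighted sum of its
    SNP alleles near the repeat locus, scaled so the SNP-explained fraction
    of diploid CN variance equals ``tagging_r2`` (the local SNPs carry the
    full tag by construction; LD with more distant sites follows from the
    backbone structure).  Diploid CN is clipped to the configured bounds
    (both alleles rescaled proportionally).  Returns ``(allelic_cn,
    locus_site, realized_r2)``.
    """
    if not (0 <= config.tagging_r2 < 1):
        raise ValueError("tagging_r2 must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pos = variants["pos"].to_numpy()
    locus_site = int(np.argmin(np.abs(pos - config.repeat_pos)))
    n2, m = haps.shape

    if config.tagging_r2 > 0:
        # tag SNPs: common sites near the locus without a strong LD proxy
        # anywhere in the panel, so standard pruning retains them
        from .core import standardize_dosages

        dosages = (haps[0::2] + haps[1::2]).astype(float)
        z = standardize_dosages(dosages)
        r2 = (z.T @ z / z.shape[0]) ** 2
        np.fill_diagonal(r2, 0.0)
        maf = np.minimum(dosages.mean(axis=0) / 2, 1 - dosages.mean(axis=0) / 2)
        half = max(8, m // 4)
        local = np.arange(max(0, locus_site - half), min(m, locus_site + half + 1))
        for cap, maf_floor in ((0.2, 0.1), (0.3, 0.05), (1.1, 0.0)):
            cand = local[(maf[local] >= maf_floor) & (r2[local].max(axis=1) < cap)]
            if len(cand) >= config.n_tag_snps:
                break
        if len(cand) == 0:
            raise ValueError("no eligible tag SNPs near the locus")
        n_tag = min(config.n_tag_snps, len(cand))
        sites = np.sort(rng.choice(cand, size=n_tag, replace=False))
        w = rng.normal(size=n_tag)
        g = haps[:, sites].astype(float) @ w
        sd = g.std()
        g = (g - g.mean()) / (sd if sd > 0 else 1.0)
    else:
        g = np.zeros(n2)

    hap_sd = config.cn_sd / np.sqrt(2.0)
    noise = rng.normal(size=n2)
    hap_cn = config.cn_mean / 2.0 + hap_sd * (
        np.sqrt(config.tagging_r2) * g + np.sqrt(1 - config.tagging_r2) * noise
    )
    hap_cn = np.maximum(hap_cn, 0.5)  # haploid CN cannot be negative
    if config.integer_alleles:
        hap_cn = np.round(hap_cn)
    allelic = np.column_stack([hap_cn[0::2], hap_cn[1::2]])

    dip = allelic.sum(axis=1)
    clipped = np.clip(dip, *config.cn_bounds)
    scale = np.where(dip > 0, clipped / dip, 1.0)
    allelic = allelic * scale[:, None]

    # realized tagging r2: regression of diploid CN on the genetic component
    g_dip = g[0::2] + g[1::2]
    dipc = allelic.sum(axis=1)
    realized = float(np.corrcoef(g_dip, dipc)[0, 1] ** 2) if g_dip.std() > 0 else 0.0
    return allelic, locus_site, realized


def simulate_depth(truth: SimTruth, model: RepeatModel, config: SimConfig, seed: int, samples=None) -> pd.DataFrame:
    """Per-sample mean depth over the repeat interval and control intervals.

    Counts over each interval are negative-binomial (gamma-Poisson) with mean
    ``expected_depth * length / read_length`` and dispersion
    ``depth_dispersion``; with ``depth_noise=False`` the expectation is
    returned exactly.  The repeat-interval expectation is the exact inverse
    of the copy-ratio transform, so a noise-free diploid-reference sample
    (CN 12 with default constants) shows depth equal to the coverage.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    dip = truth.diploid_cn
    n = len(dip)
    if samples is None:
        samples = [f"S{i:05d}" for i in range(n)]

    intervals = [(model.start, model.end, (config.coverage / 2.0) * (dip + model.offset_b) / model.scale_a)]
    for start, end in model.control_intervals:
        intervals.append((start, end, np.full(n, config.coverage)))

    rows = []
    for start, end, exp_depth in intervals:
        length = end - start + 1
        if config.depth_noise:
            mu = exp_depth * length / config.read_length
            if config.depth_dispersion > 0:
                lam = rng.gamma(shape=1.0 / config.depth_dispersion, scale=config.depth_dispersion * mu)
            else:
                lam = mu
            counts = rng.poisson(lam)
            depth = counts * config.read_length / length
        else:
            depth = exp_depth
        rows.append(pd.DataFrame({
            "sample": samples, "chrom": model.chrom, "start": start, "end": end, "mean_depth": depth,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_families(config: SimConfig, dosages: np.ndarray, haps: np.ndarray,
                      allelic_cn: np.ndarray, variants: pd.DataFrame, seed: int,
                      window_half_bp: int = 1_200_000):
    """Turn designated sample pairs into siblings IBD2 at the locus.

    The second member of each pair receives the first member's haplotypes
    (both of them) over a ~2.4 Mb IBD2 segment around the repeat and the same
    allelic CN.  The shared segment covers the CN tag SNPs, so sibling CN
    stays coherent with sibling genotypes; within-pair locus genotype
    discordance is zero before any genotyping-error injection.  Operates in
    place; returns the pair list.
    """
    n = dosages.shape[0]
    n_sib = int(round(n * config.sib_pair_fraction))
    if n_sib % 2:
        raise ValueError("sibling sample count must be even")
    pos = variants["pos"].to_numpy()
    window = (pos >= config.repeat_pos - window_half_bp) & (pos <= config.repeat_pos + window_half_bp)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)[:n_sib]
    pairs = [(int(order[2 * k]), int(order[2 * k + 1])) for k in range(n_sib // 2)]
    for i, j in pairs:
        haps[2 * j, window] = haps[2 * i, window]
        haps[2 * j + 1, window] = haps[2 * i + 1, window]
        dosages[j, window] = haps[2 * j, window] + haps[2 * j + 1, window]
        allelic_cn[j] = allelic_cn[i]
    return pairs


def inject_genotype_errors(dosages: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """With probability ``rate`` replace each genotype call by a different one.

    The error always changes the call, so the per-genotype error rate equals
    ``rate`` exactly.
    """
    rng = np.random.default_rng(seed)
    d = np.round(dosages).astype(int)
    err = rng.random(d.shape) < rate
    shift = rng.integers(1, 3, size=d.shape)  # +1 or +2 mod 3 is always a different call
    out = np.where(err, (d + shift) % 3, d)
    return out.astype(float)


def simulate_phenotypes(truth: SimTruth, dosages: np.ndarray, config: SimConfig, seed: int, samples=None) -> pd.DataFrame:
    """Latent phenotype and positive concentration scales.

    latent = cn_effect * (CN - mean) + sum_j beta_j g_j + covariates
             + interaction terms + N(0, residual_sd^2)

    With ``residual_sd=None`` the residual completes the latent variance to
    ~1 so that SD-scale effect sizes read directly as variance fractions.
    The concentration scale is a scaled exponential of the latent value
    (right-skewed, as lipoprotein(a) is); inference downstream always uses
    the rank-normalized columns, so the exact back-transform is cosmetic.
    """
    rng = np.random.default_rng(seed)
    n, m = dosages.shape
    if samples is None:
        samples = [f"S{i:05d}" for i in range(n)]
    dip = truth.diploid_cn

    cn_term = config.cn_effect * (dip - dip.mean())

    snp_term = np.zeros(n)
    betas = np.zeros(m)
    if config.n_causal_snps > 0 and config.snp_h2 > 0:
        betas[truth.causal_idx] = truth.snp_betas[truth.causal_idx]
        snp_term = dosages @ betas
        # SNP effects model CN-independent pathways: remove the LD-induced
        # projection onto diploid CN so the two genetic components are
        # orthogonal by construction.
        c = dip - dip.mean()
        snp_term = snp_term - (snp_term @ c) / (c @ c) * c

    age = rng.integers(35, 76, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)
    fasting = (rng.random(n) < 0.7).astype(float)
    on_statin = (rng.random(n) < 0.15).astype(float)
    cov_term = config.age_effect * (age - age.mean()) + config.sex_effect * (sex - sex.mean())

    inter_term = np.zeros(n)
    if len(truth.interaction_idx) > 0:
        cn_c = dip - dip.mean()
        for j, b in zip(truth.interaction_idx, truth.interaction_betas[truth.interaction_idx]):
            inter_term += b * dosages[:, j] * cn_c

    explained = cn_term + snp_term + cov_term + inter_term
    if config.residual_sd is not None:
        if config.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        res_sd = config.residual_sd
    else:
        res_sd = float(np.sqrt(max(0.05, 1.0 - explained.var())))
    latent = explained + rng.normal(scale=res_sd, size=n)

    truth.latent = latent
    ssd = snp_term.std()
    truth.snp_score = (snp_term - snp_term.mean()) / (ssd if ssd > 0 else 1.0)
    # realized marginal variance fractions (squared correlation with the latent)
    truth.cn_variance_frac = float(np.corrcoef(cn_term, latent)[0, 1] ** 2) if cn_term.std() > 0 else 0.0
    truth.snp_variance_frac = float(np.corrcoef(snp_term, latent)[0, 1] ** 2) if snp_term.std() > 0 else 0.0

    lp_a = np.exp(1.6 + 0.9 * latent)
    latent_c = 0.6 * latent + 0.8 * rng.normal(size=n)
    lp_a_c = np.exp(2.0 + 0.5 * latent_c)
    cohort = np.repeat(config.ancestry, n)
    df = pd.DataFrame(
        {
            "lp_a": lp_a,
            "lp_a_c": lp_a_c,
            "lp_a_norm": inverse_rank_normalize(lp_a, cohort),
            "lp_a_c_norm": inverse_rank_normalize(lp_a_c, cohort),
            "age": age,
            "sex": sex,
            "fasting_gt10h": fasting,
            "on_statin": on_statin,
            "cohort": cohort,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return df


def simulate_outcomes(phenotypes: pd.DataFrame, config: SimConfig, seed: int,
                      truth: SimTruth | None = None, phenotype_col: str = "lp_a_norm") -> pd.DataFrame:
    """Exponential event times with hazard h0 * exp(gamma * phenotype_SD).

    An optional direct SNP-score term (``event_snp_direct_loghr``) adds
    outcome pathways that bypass the phenotype.  Administrative censoring at
    ``censor_time``.
    """
    if config.event_baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = np.random.default_rng(seed)
    z = phenotypes[phenotype_col].to_numpy()
    loghaz = config.event_loghr * z
    if config.event_snp_direct_loghr != 0.0:
        if truth is None or truth.snp_score is None:
            raise ValueError("direct SNP hazard term requires SimTruth with snp_score")
        loghaz = loghaz + config.event_snp_direct_loghr * truth.snp_score
    rate = config.event_baseline_hazard * np.exp(loghaz)
    t = rng.exponential(1.0 / rate)
    if truth is not None:
        truth.event_times_precensor = t
    status = (t <= config.censor_time).astype(int)
    time = np.minimum(t, config.censor_time)
    return pd.DataFrame({"time": time, "status": status}, index=phenotypes.index)


def _draw_effect_sites(rng, locus_site, n_sites, maf, max_r2=None,
                       maf_min=0.05, exclusion=None, min_gap_sites=100):
    """Pick quasi-independent effect sites away from the repeat locus.

    The positional gap keeps effect SNPs outside the strong-LD shadow of the
    repeat so their phenotype pathway really is CN-independent; when a
    per-site maximum LD (``max_r2``) is supplied, sites with a strong LD
    proxy anywhere in the panel are also avoided, so the causal variants
    behave as independent signals.
    """
    maf = np.asarray(maf)
    m = len(maf)
    gap = min(min_gap_sites, max(5, m // 4))
    eligible = (maf >= maf_min) & (np.abs(np.arange(m) - locus_site) > gap)
    if exclusion is not None:
        eligible[np.asarray(exclusion, dtype=int)] = False
    if max_r2 is None:
        max_r2 = np.zeros(m)
    cand = np.array([], dtype=int)
    for cap in (0.15, 0.3, 1.1):
        cand = np.where(eligible & (max_r2 < cap))[0]
        if len(cand) >= n_sites:
            break
    if len(cand) < n_sites:
        raise ValueError("not enough eligible variants for effect sites")
    # keep effect sites apart so local LD does not collapse their joint variance
    spacing = max(1, min(m // (2 * n_sites), 40))
    chosen: list[int] = []
    for j in rng.permutation(cand):
        if all(abs(j - c) >= spacing for c in chosen):
            chosen.append(int(j))
        if len(chosen) == n_sites:
            break
    if len(chosen) < n_sites:  # relax spacing if the panel is small
        rest = [int(j) for j in rng.permutation(cand) if j not in chosen]
        chosen.extend(rest[: n_sites - len(chosen)])
    return np.sort(np.array(chosen, dtype=int))


def simulate_cohort(config: SimConfig, seed: int | None = None):
    """End-to-end cohort simulation; returns (CohortBundle, SimTruth)."""
    seed = config.seed if seed is None else seed
    s_geno, s_cn, s_fam, s_depth, s_pheno, s_eff = _child_seeds(seed, 6)

    dosages, variants, haps, state = simulate_genotypes(config, s_geno)
    allelic, locus_site, realized_r2 = simulate_repeat_alleles(config, variants, haps, s_cn)

    n, m = dosages.shape
    if config.panel_seed is not None and config.ld_mode == "backbone":
        # panel-level effect sites: identical across cohorts sharing the panel
        _, _, backbones, weights = _draw_panel(config, s_geno)
        eff_maf, panel_r2 = _panel_maf_and_r2(backbones, weights)
        eff_max_r2 = panel_r2.max(axis=1)
        rng = np.random.default_rng(config.panel_seed + 1)
    else:
        from .core import standardize_dosages

        z = standardize_dosages(dosages)
        r2 = (z.T @ z / z.shape[0]) ** 2
        np.fill_diagonal(r2, 0.0)
        eff_maf, eff_max_r2 = variants["maf"].to_numpy(), r2.max(axis=1)
        rng = np.random.default_rng(s_eff)
    snp_betas = np.zeros(m)
    causal_idx = np.array([], dtype=int)
    if config.n_causal_snps > 0 and config.snp_h2 > 0:
        causal_idx = _draw_effect_sites(rng, locus_site, config.n_causal_snps,
                                        maf=eff_maf, max_r2=eff_max_r2)
        p = variants["maf"].to_numpy()[causal_idx]
        base = np.sqrt(config.snp_h2 / np.sum(2 * p * (1 - p)))
        signs = np.where(np.arange(len(causal_idx)) % 2 == 0, 1.0, -1.0)
        snp_betas[causal_idx] = base * signs
    inter_betas = np.zeros(m)
    inter_idx = np.array([], dtype=int)
    if config.n_interaction_snps > 0 and config.interaction_effect != 0.0:
        inter_idx = _draw_effect_sites(rng, locus_site, config.n_interaction_snps,
                                       maf=eff_maf, max_r2=eff_max_r2,
                                       maf_min=0.1, exclusion=causal_idx)
        inter_betas[inter_idx] = config.interaction_effect

    truth = SimTruth(
        allelic_cn=allelic,
        snp_betas=snp_betas,
        interaction_betas=inter_betas,
        causal_idx=causal_idx,
        interaction_idx=inter_idx,
        locus_site=locus_site,
        tagging_r2_realized=realized_r2,
    )

    if config.sib_pair_fraction > 0:
        truth.sib_pairs = simulate_families(config, dosages, haps, truth.allelic_cn, variants, s_fam)
        st = allele_stats(dosages)
        variants["maf"] = st["maf"].to_numpy()
        variants["mac"] = st["mac"].to_numpy()

    samples = [f"S{i:05d}" for i in range(n)]
    model = RepeatModel(chrom=config.chrom)
    depth = simulate_depth(truth, model, config, s_depth, samples=samples)
    pheno = simulate_phenotypes(truth, dosages, config, s_pheno, samples=samples)

    bundle = CohortBundle(
        samples=samples,
        dosages=dosages,
        variants=variants,
        phenotypes=pheno,
        depth=depth,
        name=config.ancestry,
    )
    return bundle, truth


def truth_table(truth: SimTruth, samples) -> pd.DataFrame:
    """Per-sample truth as a TSV-ready frame."""
    return pd.DataFrame(
        {
            "allele1_cn": truth.allelic_cn[:, 0],
            "allele2_cn": truth.allelic_cn[:, 1],
            "diploid_cn": truth.diploid_cn,
            "latent": truth.latent,
        },
        index=pd.Index(samples, name="sample_id"),
    )
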