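"""Diploid KIV2 copy-number estimation from read-depth summaries.

The estimator is the affine copy-ratio transform: with rho the diploid copy
ratio (twice the repeat-interval mean depth over the pooled control-interval
mean depth, so a reference-structured diploid sample has rho = 2),

    kiv2_cn = rho * scale_a - offset_b

with default constants 6.354 and 0.708 derived from the reference layout of
the repeat (full copies represented in hg19, minus the flanking homologous
exons picked up by the aggregate-depth signal).  Negative estimates are
retained but flagged so downstream regression diagnostics see the raw
estimator.

Precision is quantified with sibling pairs identical-by-descent on both
haplotypes (IBD2) at the locus: true CN is shared within such a pair, so the
squared correlation of the two estimate vectors bounds estimator noise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import RepeatModel

log = logging.getLogger("kiv2cn")


def estimate_copy_ratio(depth: pd.DataFrame, model: RepeatModel) -> pd.DataFrame:
    """Diploid copy ratio per sample: 2 * repeat depth / pooled control depth.

    The control mean is pooled across control intervals weighted by interval
    length.  Missing repeat depth or zero/absent control depth is an error.
    """
    d = depth.copy()
    d["chrom"] = d["chrom"].astype(str)

    def interval_mask(start, end):
        return (d["chrom"] == str(model.chrom)) & (d["start"] == start) & (d["end"] == end)

    rep = d[interval_mask(model.start, model.end)].set_index("sample")["mean_depth"]
    if rep.empty:
        raise ValueError("no depth rows for the repeat interval")

    ctrl_num = pd.Series(0.0, index=rep.index)
    ctrl_len = 0.0
    for start, end in model.control_intervals:
        rows = d[interval_mask(start, end)].set_index("sample")["mean_depth"]
        if rows.empty:
            continue
        length = end - start + 1
        ctrl_num = ctrl_num.add(rows.reindex(rep.index) * length, fill_value=np.nan)
        ctrl_len += length
    if ctrl_len == 0:
        raise ValueError("no depth rows for any control interval")
    ctrl = ctrl_num / ctrl_len
    if ctrl.isna().any():
        raise ValueError("control depth missing for some samples")
    if (ctrl <= 0).any():
        raise ValueError("control mean depth must be positive")

    rho = 2.0 * rep / ctrl
    return pd.DataFrame({"sample": rep.index, "rho": rho.to_numpy()}).reset_index(drop=True)


def kiv2_cn_from_ratio(copy_ratio: pd.DataFrame, model: RepeatModel) -> pd.DataFrame:
    """Apply the affine transform; negative estimates flagged, not clamped."""
    rho = copy_ratio["rho"].to_numpy(dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("copy ratio must be finite")
    cn = rho * model.scale_a - model.offset_b
    return pd.DataFrame(
        {
            "sample": copy_ratio["sample"].to_numpy(),
            "kiv2_cn": cn,
            "qc_negative": cn < 0,
        }
    )


def estimate_cn(depth: pd.DataFrame, model: RepeatModel | None = None) -> pd.DataFrame:
    """Convenience: depth summaries -> per-sample diploid KIV2-CN estimates."""
    model = model or RepeatModel()
    return kiv2_cn_from_ratio(estimate_copy_ratio(depth, model), model)


def classify_ibd2(dosages: np.ndarray, variants: pd.DataFrame, pairs,
                  window: tuple[int, int] | None = None,
                  discordance_max: float = 0.01, floor: int = 50):
    """Classify candidate sample pairs as IBD2 at the locus window.

    A pair is IBD2 iff the genotype discordance fraction over comparable
    (both non-missing) window variants is strictly below ``discordance_max``.
    Pairs with fewer than ``floor`` comparable variants are excluded and
    logged.  Returns (ibd2_pairs, per-pair report frame).
    """
    pos = variants["pos"].to_numpy()
    if window is not None:
        sel = (pos >= window[0]) & (pos <= window[1])
    else:
        sel = np.ones(len(pos), dtype=bool)
    g = np.round(dosages[:, sel])
    poly = np.nanstd(g, axis=0) > 0
    g = g[:, poly]
    if g.shape[1] < floor:
        raise ValueError(f"locus window has {g.shape[1]} polymorphic variants; floor is {floor}")

    rows, ibd2 = [], []
    for i, j in pairs:
        ok = ~np.isnan(g[i]) & ~np.isnan(g[j])
        n_cmp = int(ok.sum())
        if n_cmp < floor:
            log.info("classify_ibd2: pair (%d, %d) excluded, only %d comparable variants", i, j, n_cmp)
            rows.append({"i": i, "j": j, "n_compared": n_cmp, "discordance": np.nan, "ibd2": False, "excluded": True})
            continue
        disc = float(np.mean(g[i, ok] != g[j, ok]))
        is_ibd2 = disc < discordance_max
        rows.append({"i": i, "j": j, "n_compared": n_cmp, "discordance": disc, "ibd2": is_ibd2, "excluded": False})
        if is_ibd2:
            ibd2.append((i, j))
    return ibd2, pd.DataFrame(rows)


def sibling_precision(cn: np.ndarray, pairs, seed: int = 0) -> dict:
    """Squared correlation of pair-member CN estimates across IBD2 pairs.

    Pair member order is randomized (seeded) so the statistic does not depend
    on how the pairs happen to be listed.  Requires >= 3 pairs.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 IBD2 pairs")
    rng = np.random.default_rng(seed)
    x, y = [], []
    for i, j in pairs:
        if rng.random() < 0.5:
            i, j = j, i
        x.append(cn[i])
        y.append(cn[j])
    x, y = np.asarray(x), np.asarray(y)
    r = np.corrcoef(x, y)[0, 1]
    slope = np.polyfit(x, y, 1)[0]
    return {"r_squared": float(r**2), "n_pairs": len(pairs), "slope": float(slope)}
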