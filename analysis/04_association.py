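#!/usr/bin/env python
"""CN-conditioned association scans, meta-analysis and heritability.

Runs the CN-adjusted single-variant scan per cohort, the iterative
conditional analysis at the locus, inverse-variance meta-analysis with
heterogeneity, the reciprocal-CN functional-form check, the homozygous-allele
composition check, and Haseman-Elston heritability with and without CN
conditioning.
"""

import sys
import os

sys.path.insert(0, os.path.dirname(__file__))

import numpy as np

from common import LOCUS_WINDOW, load_cohorts, results_path
from kiv2cn import (
    allelic_composition_test,
    compare_cn_functional_form,
    conditional_scan,
    heritability_he,
    meta_fixed_effects,
    single_variant_scan,
)
from kiv2cn.io import write_result_table


def main() -> None:
    cohorts = load_cohorts()
    scans = {}
    for name, (bundle, truth, cn, _) in cohorts.items():
        scan = single_variant_scan(bundle, "lp_a_norm", covariates=["age", "sex"],
                                   cn=cn, adjust_cn=True, analysis=f"{name}_cn_adjusted")
        scans[name] = scan
        write_result_table(results_path("assoc", f"{name}.scan.tsv"), scan)
        n_sig = int((scan["p"] < 5e-8).sum())
        print(f"{name}: {len(scan)} variants scanned, {n_sig} genome-wide significant "
              f"after CN adjustment (CN-independent SNP effects)")

        hits = conditional_scan(bundle, "lp_a_norm", window=LOCUS_WINDOW,
                                covariates=["age", "sex"], cn=cn, adjust_cn=True)
        print(f"{name}: {len(hits)} independent locus hits by iterative conditioning "
              f"(true CN-independent causal count: {len(truth.causal_idx)})")

    meta = meta_fixed_effects(scans)
    meta.to_csv(results_path("assoc", "meta.tsv"), sep="\t", index=False, float_format="%.5g")
    shared_sig = meta[(meta["p"] < 5e-8) & ~meta["single_cohort"]]
    print(f"meta-analysis: {len(shared_sig)} cross-cohort genome-wide hits; "
          f"median heterogeneity p {meta['het_p'].median():.2f}")

    bundle, truth, cn, _ = cohorts["african"]
    y = bundle.phenotypes["lp_a_norm"].to_numpy()
    ff = compare_cn_functional_form(y, cn)
    print(f"adding 1/CN to the linear CN model: partial-F p = {ff['p']:.2f} "
          "(no evidence against linearity, matching the generating model)")
    ac = allelic_composition_test(y, truth.allelic_cn, tol=2.0)
    print(f"equal-allele vs split-allele CN slope: interaction p = {ac['p']:.2f} "
          f"({ac['n_equal']} near-homozygous samples) — total CN is what matters")

    h2 = heritability_he(bundle, "lp_a_norm", covariates=["age", "sex"], min_variants=300)
    h2_cn = heritability_he(bundle, "lp_a_norm", covariates=["age", "sex"], cn=cn, min_variants=300)
    print(f"Haseman-Elston h^2 = {h2['h2']:.2f} (SE {h2['se']:.2f}); "
          f"conditioning on KIV2-CN: {h2_cn['h2']:.2f} (SE {h2_cn['se']:.2f}) — "
          "the drop is the CN-tagged share of heritability")
    np.savetxt(results_path("04_heritability.tsv"),
               np.array([[h2["h2"], h2["se"], h2_cn["h2"], h2_cn["se"]]]),
               header="h2\tse\th2_cn_adjusted\tse_cn_adjusted", delimiter="\t", comments="")


if __name__ == "__main__":
    main()
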