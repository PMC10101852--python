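"""Bayesian colocalization of two association signals in one region.

Simulates a 50-variant LD block where two traits either share a single
causal variant or carry two distinct causal variants in weak LD, and
evaluates the five colocalization hypotheses with approximate Bayes
factors (priors 1e-4 / 1e-4 / 5e-6).
"""

import numpy as np
import pandas as pd
from scipy.stats import chi2

from matfet import simdata, sumstat_models

cfg = simdata.ArchitectureConfig(
    n_snps=50, n_blocks=1, block_ld_rho=0.9, maf_range=(0.3, 0.5), seed=51
)
pool = simdata.simulate_haplotype_panel(cfg, 20000)
r = simdata.ld_reference_from_pool(pool).corr[0]
snps = pool.variants["SNP"].tolist()


def region(causal_idx, seed, n=50000):
    rng = np.random.default_rng(seed)
    beta = np.zeros(50)
    beta[causal_idx] = 0.04
    z = np.sqrt(n) * r @ beta + np.linalg.cholesky(
        r + 1e-8 * np.eye(50)
    ) @ rng.standard_normal(50)
    se = 1 / np.sqrt(n)
    return pd.DataFrame({"SNP": snps, "BETA": z * se, "SE": se,
                         "P": chi2.sf(z**2, 1)})


shared = sumstat_models.coloc_abf(region(25, 1), region(25, 2))
print("shared causal variant: "
      + ", ".join(f"{k}={v:.3f}" for k, v in shared.pp.items()))
print(f"  -> PP4 = {shared.pp4:.3f} (> 0.9 is strong colocalization: one "
      "variant drives both traits)\n")

distinct = sumstat_models.coloc_abf(region(20, 3), region(31, 4))
print("distinct causal variants (r2 ~ 0.1): "
      + ", ".join(f"{k}={v:.3f}" for k, v in distinct.pp.items()))
print(f"  -> PP3 = {distinct.pp['PP3']:.3f} beats PP4: two different "
      "variants, merely linked")
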