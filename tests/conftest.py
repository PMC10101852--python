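import numpy as np
import pandas as pd
import pytest

from matfet import simdata
from matfet.trio_alleles import resolve_trioset

FIVE_CLASS_MIX = {
    "maternal_only": 0.2,
    "fetal_only": 0.2,
    "poe_mt_only": 0.2,
    "both_same": 0.2,
    "both_opposite": 0.2,
    "null": 0.0,
}


@pytest.fixture(scope="session")
def small_world():
    """500 trios, 60 SNPs in 12 LD blocks: shared substrate for cheap tests."""
    cfg = simdata.ArchitectureConfig(
        n_snps=60, n_blocks=12, block_ld_rho=0.6, maf_range=(0.1, 0.5), seed=101
    )
    pool = simdata.simulate_haplotype_panel(cfg, 4000)
    trios = simdata.simulate_trios(pool, 500, seed=102)
    truth = simdata.simulate_truth(cfg, pool.variants)
    phenos = simdata.simulate_phenotypes(trios, truth, cfg)
    return {"cfg": cfg, "pool": pool, "trios": trios, "truth": truth, "phenos": phenos}


@pytest.fixture(scope="session")
def trio_dosages(small_world):
    return resolve_trioset(small_world["trios"])


@pytest.fixture(scope="session")
def ldsc_world():
    """Heterogeneous-LD panel for summary-statistic model tests."""
    cfg = simdata.ArchitectureConfig(
        n_snps=5000, n_blocks=250, block_ld_rho_range=(0.0, 0.95), seed=111
    )
    pool = simdata.simulate_haplotype_panel(cfg, 4000)
    ld = simdata.ld_reference_from_pool(pool)
    ld_scores = pd.DataFrame({"SNP": ld.variants["SNP"], "L2": ld.ld_scores()})
    return {"cfg": cfg, "pool": pool, "ld": ld, "ld_scores": ld_scores}


def make_sumstats(
    betas, ses, snps=None, eaf=0.3, n=10000, chrom=1, pos=None, ea="A", nea="G"
):
    """Hand-rolled summary-statistic frame for closed-form tests."""
    from scipy import stats

    betas = np.asarray(betas, dtype=float)
    ses = np.broadcast_to(np.asarray(ses, dtype=float), betas.shape)
    m = len(betas)
    return pd.DataFrame(
        {
            "SNP": snps if snps is not None else [f"rs{i + 1}" for i in range(m)],
            "CHR": chrom,
            "POS": pos if pos is not None else 1000 * (np.arange(m) + 1),
            "EA": ea,
            "NEA": nea,
            "EAF": eaf,
            "BETA": betas,
            "SE": ses,
            "P": 2 * stats.norm.sf(np.abs(betas / ses)),
            "N": n,
            "INFO": 1.0,
        }
    )
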