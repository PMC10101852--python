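"""Synthetic multi-cohort phased trio data with known maternal/fetal effect origin.

The generator produces the substrate every estimator in this package is
validated on: phased parental haplotypes, Mendelian transmission to a child,
gestational duration (GD, days) built from maternal, fetal and
parent-of-origin SNP effects, and birth weight (BW, grams) partly mediated
by gestational duration with optional antagonistic maternal-GD/fetal-BW
pleiotropy at shared causal SNPs.

LD is a first-order Markov allele-copying process within blocks (adjacent
haplotype correlation ``block_ld_rho``, independence across blocks) — enough
to give tunable LD for clumping/COJO/LD-score tests without coalescent
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDReference

EFFECT_CLASSES = (
    "maternal_only",
    "fetal_only",
    "poe_mt_only",
    "both_same",
    "both_opposite",
    "null",
)

_DEFAULT_MIX = {
    "maternal_only": 0.02,
    "fetal_only": 0.01,
    "poe_mt_only": 0.005,
    "both_same": 0.01,
    "both_opposite": 0.01,
    "null": 0.945,
}


@dataclass
class ArchitectureConfig:
    """Genetic architecture and phenotype model for the simulator.

    Defaults encode the world the analyses assume: mean gestation 282 days,
    per-allele effects of a fraction of a day to about a day, birth weight
    gaining 25 g per day of gestation, and antagonistic pleiotropy
    (correlation -0.8) between the maternal GD effect and the direct fetal
    BW effect at shared causal SNPs.
    """

    n_snps: int = 2000
    n_blocks: int = 100
    block_ld_rho: float = 0.8
    block_ld_rho_range: tuple[float, float] | None = None
    # per-block rho ~ Uniform(range) when set (heterogeneous LD scores,
    # needed for identifiable LD-score regressions); fixed rho otherwise
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_class_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    m_effect_sd: float = 0.4          # days / allele, maternal channel
    f_effect_sd: float = 0.4          # days / allele, fetal channel
    effect_magnitude_range: tuple[float, float] | None = None
    # if set, |m|,|f| ~ Uniform(range) with random sign instead of Normal(0, sd)
    gd_mean: float = 282.0            # days
    gd_sd: float = 12.0               # residual days
    bw_mean: float = 3500.0           # grams
    bw_sd: float = 400.0              # residual grams
    bw_per_gd_day: float = 25.0       # grams per day of gestation
    fetal_bw_effect_sd: float = 15.0  # grams / allele, direct fetal BW effect
    antagonism_rho: float = -0.8      # corr(m, f_bw) at maternal-effect SNPs
    nonspontaneous_frac: float = 0.2  # induced / planned cesarean flag rate
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.block_ld_rho < 1.0):
            raise ValueError(f"block_ld_rho must be in [0, 1), got {self.block_ld_rho}")
        if self.gd_sd < 0:
            raise ValueError("gd_sd must be >= 0")
        unknown = set(self.effect_class_mix) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        total = sum(self.effect_class_mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"effect_class_mix must sum to 1, sums to {total}")


@dataclass
class HaplotypePool:
    """Panel of phased haplotypes: ``haps`` is (n_haplotypes, n_snps) in {0,1}."""

    haps: np.ndarray
    variants: pd.DataFrame  # SNP, CHR, POS, EA, NEA, block
    seed: int

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haps.shape[1]

    def eaf(self) -> np.ndarray:
        return self.haps.mean(axis=0)


@dataclass
class PhasedTrioSet:
    """Phased mother/father/child genotypes with explicit transmission record.

    Haplotype arrays are (n_trios, n_snps) in {0,1}.  The child's maternal-
    origin haplotype is ``mother_h1`` where ``mat_transmitted == 0`` and
    ``mother_h2`` where it is 1; paternal side analogously.
    """

    mother_h1: np.ndarray
    mother_h2: np.ndarray
    father_h1: np.ndarray
    father_h2: np.ndarray
    mat_transmitted: np.ndarray  # (n_trios,) in {0,1}
    pat_transmitted: np.ndarray
    variants: pd.DataFrame
    family_ids: np.ndarray
    seed: int

    @property
    def n_trios(self) -> int:
        return self.mother_h1.shape[0]

    @property
    def n_snps(self) -> int:
        return self.mother_h1.shape[1]

    def child_maternal_hap(self) -> np.ndarray:
        return np.where(self.mat_transmitted[:, None] == 0, self.mother_h1, self.mother_h2)

    def child_paternal_hap(self) -> np.ndarray:
        return np.where(self.pat_transmitted[:, None] == 0, self.father_h1, self.father_h2)

    def mother_dosage(self) -> np.ndarray:
        return (self.mother_h1 + self.mother_h2).astype(np.int8)

    def father_dosage(self) -> np.ndarray:
        return (self.father_h1 + self.father_h2).astype(np.int8)

    def child_dosage(self) -> np.ndarray:
        return (self.child_maternal_hap() + self.child_paternal_hap()).astype(np.int8)

    def subset(self, idx: np.ndarray) -> "PhasedTrioSet":
        return PhasedTrioSet(
            mother_h1=self.mother_h1[idx],
            mother_h2=self.mother_h2[idx],
            father_h1=self.father_h1[idx],
            father_h2=self.father_h2[idx],
            mat_transmitted=self.mat_transmitted[idx],
            pat_transmitted=self.pat_transmitted[idx],
            variants=self.variants,
            family_ids=self.family_ids[idx],
            seed=self.seed,
        )


def _block_sizes(n_snps: int, n_blocks: int) -> np.ndarray:
    base = n_snps // n_blocks
    sizes = np.full(n_blocks, base, dtype=int)
    sizes[: n_snps - base * n_blocks] += 1
    return sizes


def simulate_haplotype_panel(
    cfg: ArchitectureConfig, n_haplotypes: int = 10000
) -> HaplotypePool:
    """Draw a panel of phased haplotypes under the block-Markov LD model.

    Within a block, the allele at SNP j+1 copies the allele state of SNP j
    (recoded through allele frequency) with probability ``block_ld_rho``,
    which yields adjacent-pair haplotype correlation equal to rho and
    correlation rho**d at lag d.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    sizes = _block_sizes(cfg.n_snps, cfg.n_blocks)
    if cfg.block_ld_rho_range is not None:
        rho_by_block = rng.uniform(*cfg.block_ld_rho_range, size=cfg.n_blocks)
    else:
        rho_by_block = np.full(cfg.n_blocks, cfg.block_ld_rho)
    # one effect-allele frequency per block: the copying chain then preserves
    # the marginal frequency exactly and corr(x_j, x_{j+d}) = rho**d.
    block_freq = rng.uniform(lo, hi, size=cfg.n_blocks)
    freqs = np.repeat(block_freq, sizes)

    haps = np.empty((n_haplotypes, cfg.n_snps), dtype=np.int8)
    start = 0
    for b, size in enumerate(sizes):
        p = block_freq[b]
        rho = rho_by_block[b]
        block = np.empty((n_haplotypes, size), dtype=np.int8)
        block[:, 0] = rng.random(n_haplotypes) < p
        for j in range(1, size):
            fresh = (rng.random(n_haplotypes) < p).astype(np.int8)
            copy = rng.random(n_haplotypes) < rho
            block[:, j] = np.where(copy, block[:, j - 1], fresh)
        haps[:, start : start + size] = block
        start += size

    block_id = np.repeat(np.arange(cfg.n_blocks), sizes)
    # one synthetic chromosome, 5 kb spacing; blocks are contiguous
    pos = 10_000 + 5_000 * np.arange(cfg.n_snps)
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(cfg.n_snps)],
            "CHR": np.ones(cfg.n_snps, dtype=int),
            "POS": pos,
            "EA": "A",
            "NEA": "G",
            "EAF": freqs,
            "block": block_id,
        }
    )
    return HaplotypePool(haps=haps, variants=variants, seed=cfg.seed)


def simulate_trios(pool: HaplotypePool, n_trios: int, seed: int) -> PhasedTrioSet:
    """Form trios: each parent draws two panel haplotypes, the child inherits
    one haplotype from each parent chosen uniformly at random."""
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    if pool.n_haplotypes == 0:
        raise ValueError("empty haplotype pool")
    rng = np.random.default_rng(seed)
    draw = rng.integers(0, pool.n_haplotypes, size=(n_trios, 4))
    mat_t = rng.integers(0, 2, size=n_trios).astype(np.int8)
    pat_t = rng.integers(0, 2, size=n_trios).astype(np.int8)
    return PhasedTrioSet(
        mother_h1=pool.haps[draw[:, 0]],
        mother_h2=pool.haps[draw[:, 1]],
        father_h1=pool.haps[draw[:, 2]],
        father_h2=pool.haps[draw[:, 3]],
        mat_transmitted=mat_t,
        pat_transmitted=pat_t,
        variants=pool.variants,
        family_ids=np.array([f"F{i:06d}" for i in range(n_trios)]),
        seed=seed,
    )


def simulate_truth(
    cfg: ArchitectureConfig, variants: pd.DataFrame, exact_counts: bool = False
) -> pd.DataFrame:
    """Draw the per-SNP ground truth (TruthManifest).

    Columns: SNP, true_class, m (maternal GD effect, days/allele), f (fetal
    GD effect), poe (extra effect of the maternally transmitted allele) and
    f_bw (direct fetal BW effect, grams/allele).  At SNPs with a maternal GD
    effect, f_bw is drawn jointly with m at correlation ``antagonism_rho``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(variants)
    classes = list(cfg.effect_class_mix)
    probs = np.array([cfg.effect_class_mix[c] for c in classes])
    if exact_counts:
        counts = np.round(probs * n).astype(int)
        counts[-1] += n - counts.sum()
        labels = rng.permutation(np.repeat(classes, counts))
    else:
        labels = rng.choice(classes, size=n, p=probs)

    def _mag(sd: float, size: int) -> np.ndarray:
        if cfg.effect_magnitude_range is not None:
            lo, hi = cfg.effect_magnitude_range
            return rng.uniform(lo, hi, size) * rng.choice([-1.0, 1.0], size)
        return rng.normal(0.0, sd, size)

    m = np.zeros(n)
    f = np.zeros(n)
    poe = np.zeros(n)
    f_bw = np.zeros(n)

    has_m = np.isin(labels, ["maternal_only", "both_same", "both_opposite"])
    has_f = np.isin(labels, ["fetal_only", "both_same", "both_opposite"])
    is_poe = labels == "poe_mt_only"

    m[has_m] = _mag(cfg.m_effect_sd, int(has_m.sum()))
    f[has_f] = _mag(cfg.f_effect_sd, int(has_f.sum()))
    poe[is_poe] = _mag(cfg.f_effect_sd, int(is_poe.sum()))
    # enforce the sign pattern of the shared-effect classes
    both_same = labels == "both_same"
    both_opp = labels == "both_opposite"
    f[both_same] = np.sign(m[both_same]) * np.abs(f[both_same])
    f[both_opp] = -np.sign(m[both_opp]) * np.abs(f[both_opp])

    # fetal BW effect: correlated with m where a maternal effect exists
    # (antagonistic pleiotropy), independent at fetal-only SNPs.
    rho = cfg.antagonism_rho
    z = rng.standard_normal(n)
    sd_bw = cfg.fetal_bw_effect_sd
    m_sd = np.std(m[has_m]) if has_m.sum() > 1 else 1.0
    if m_sd == 0:
        m_sd = 1.0
    f_bw[has_m] = sd_bw * (
        rho * (m[has_m] / m_sd) + np.sqrt(max(0.0, 1 - rho**2)) * z[has_m]
    )
    f_bw[has_f & ~has_m] = sd_bw * z[has_f & ~has_m]

    return pd.DataFrame(
        {
            "SNP": variants["SNP"].to_numpy(),
            "true_class": labels,
            "m": m,
            "f": f,
            "poe": poe,
            "f_bw": f_bw,
        }
    )


def simulate_phenotypes(
    trios: PhasedTrioSet, truth: pd.DataFrame, cfg: ArchitectureConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate gestational duration and birth weight for each pregnancy.

    GD_i = gd_mean + sum_j [ m_j (MnT+MT) + f_j (MT+PT) + poe_j MT ] + eps
    BW_i = bw_mean + bw_per_gd_day (GD_i - gd_mean) + sum_j f_bw_j (MT+PT) + eps_bw

    Also attaches two standard-normal "principal component" covariates, a
    genotyping batch, and a delivery-onset flag (a random fraction induced /
    planned cesarean, independent of genotype).
    """
    missing = set(truth["SNP"]) - set(trios.variants["SNP"])
    if missing:
        raise KeyError(f"truth SNPs absent from trio set: {sorted(missing)[:5]}")
    rng = np.random.default_rng(trios.seed + 17 if seed is None else seed)

    order = trios.variants.set_index("SNP").index.get_indexer(truth["SNP"])
    m = np.zeros(trios.n_snps)
    f = np.zeros(trios.n_snps)
    poe = np.zeros(trios.n_snps)
    f_bw = np.zeros(trios.n_snps)
    m[order] = truth["m"].to_numpy()
    f[order] = truth["f"].to_numpy()
    poe[order] = truth["poe"].to_numpy()
    f_bw[order] = truth["f_bw"].to_numpy()

    mnt = np.where(
        trios.mat_transmitted[:, None] == 0, trios.mother_h2, trios.mother_h1
    ).astype(np.float64)
    mt = trios.child_maternal_hap().astype(np.float64)
    pt = trios.child_paternal_hap().astype(np.float64)

    n = trios.n_trios
    gd = (
        cfg.gd_mean
        + (mnt + mt) @ m
        + (mt + pt) @ f
        + mt @ poe
        + rng.normal(0.0, cfg.gd_sd, n)
    )
    bw = (
        cfg.bw_mean
        + cfg.bw_per_gd_day * (gd - cfg.gd_mean)
        + (mt + pt) @ f_bw
        + rng.normal(0.0, cfg.bw_sd, n)
    )
    onset = np.where(
        rng.random(n) < cfg.nonspontaneous_frac,
        rng.choice(["induced", "planned_cesarean"], size=n),
        "spontaneous",
    )
    return pd.DataFrame(
        {
            "id": trios.family_ids,
            "gestational_duration": gd,
            "birth_weight": bw,
            "onset": onset,
            "PC1": rng.standard_normal(n),
            "PC2": rng.standard_normal(n),
            "batch": rng.integers(0, 3, n),
        }
    )


def split_cohorts(
    trios: PhasedTrioSet,
    phenos: pd.DataFrame,
    k_cohorts: int,
    seed: int,
    weights: list[float] | None = None,
) -> list[tuple[PhasedTrioSet, pd.DataFrame]]:
    """Randomly partition trios into disjoint cohorts (near-equal or weighted)."""
    if k_cohorts < 1:
        raise ValueError("k_cohorts must be >= 1")
    n = trios.n_trios
    if k_cohorts > n:
        raise ValueError(f"k_cohorts={k_cohorts} exceeds n_trios={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    if weights is None:
        bounds = [round(i * n / k_cohorts) for i in range(k_cohorts + 1)]
    else:
        if len(weights) != k_cohorts:
            raise ValueError("weights length must equal k_cohorts")
        cum = np.cumsum(weights) / np.sum(weights)
        bounds = [0] + [round(c * n) for c in cum]
        bounds[-1] = n
    out = []
    for i in range(k_cohorts):
        idx = np.sort(perm[bounds[i] : bounds[i + 1]])
        out.append((trios.subset(idx), phenos.iloc[idx].reset_index(drop=True)))
    return out


def ld_reference_from_pool(pool: HaplotypePool, sample_n: int | None = None) -> LDReference:
    """Build an LD reference (block correlation matrices + LD scores) from a
    haplotype panel, emulating an external reference cohort."""
    haps = pool.haps if sample_n is None else pool.haps[:sample_n]
    return LDReference.from_genotypes(
        haps.astype(np.float64), pool.variants, blocks=pool.variants["block"].to_numpy()
    )


def simulate_sumstats_pair(
    ld: LDReference,
    h2_a: float,
    h2_b: float,
    rg: float,
    n_a: int,
    n_b: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw paired GWAS z-scores for two traits under the polygenic model.

    Per variant j with LD score l_j and M variants in total:
        E[z_aj^2] = 1 + n_a h2_a l_j / M,  cov(z_aj, z_bj) propto rg.
    No sample overlap is modelled, so the cross-trait covariance has no
    intercept term.  Returns two summary-statistic tables on the
    standardized scale (beta = z / sqrt(n)).
    """
    for h2 in (h2_a, h2_b):
        if not (0.0 <= h2 <= 1.0):
            raise ValueError(f"h2 must be in [0, 1], got {h2}")
    if abs(rg) > 1.0:
        raise ValueError(f"|rg| must be <= 1, got {rg}")
    rng = np.random.default_rng(seed)
    ell = ld.ld_scores()
    m = len(ell)
    var_a = 1.0 + n_a * h2_a * ell / m
    var_b = 1.0 + n_b * h2_b * ell / m
    cov_ab = rg * np.sqrt(n_a * n_b * h2_a * h2_b) * ell / m
    det = var_a * var_b - cov_ab**2
    if np.any(det <= 0):
        raise ValueError("infeasible cross-trait covariance matrix")
    z1 = rng.standard_normal(m)
    z2 = rng.standard_normal(m)
    z_a = np.sqrt(var_a) * z1
    # conditional draw of z_b | z_a
    z_b = cov_ab / var_a * z_a + np.sqrt(var_b - cov_ab**2 / var_a) * z2

    from scipy.stats import chi2

    def _stats(z: np.ndarray, n: int) -> pd.DataFrame:
        se = 1.0 / np.sqrt(n)
        return pd.DataFrame(
            {
                "SNP": ld.variants["SNP"].to_numpy(),
                "CHR": ld.variants["CHR"].to_numpy(),
                "POS": ld.variants["POS"].to_numpy(),
                "EA": ld.variants["EA"].to_numpy(),
                "NEA": ld.variants["NEA"].to_numpy(),
                "EAF": ld.variants.get("EAF", pd.Series(np.full(m, 0.5))).to_numpy(),
                "BETA": z * se,
                "SE": se,
                "P": chi2.sf(z**2, df=1),
                "N": n,
                "INFO": 1.0,
            }
        )

    return _stats(z_a, n_a), _stats(z_b, n_b)


def simulate_mediation_sumstats(
    ld: LDReference,
    h2_a: float = 0.3,
    mediation_beta: float = 0.5,
    h2_b_direct: float = 0.05,
    n: int = 50000,
    n_a_causal: int = 150,
    n_b_causal: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Summary statistics for a mediated pair of traits: B = beta * A + noise.

    Trait A spreads its heritability over ``n_a_causal`` SNPs; trait B
    receives the mediated component of every A effect plus a sparse set of
    larger direct effects at B-specific SNPs.  Causal effects (standardized
    scale) are propagated through the reference LD (marginal = R beta per
    block) and z-scores carry block-correlated sampling noise, so LD-score
    regression, clumping and summary-level conditioning all behave as they
    would on real polygenic traits.
    """
    rng = np.random.default_rng(seed)
    m_variants = ld.n_variants
    beta_a = np.zeros(m_variants)
    idx_a = rng.choice(m_variants, n_a_causal, replace=False)
    beta_a[idx_a] = np.sqrt(h2_a / n_a_causal) * rng.choice([-1.0, 1.0], n_a_causal)
    beta_b_direct = np.zeros(m_variants)
    free = np.setdiff1d(np.arange(m_variants), idx_a)
    idx_b = rng.choice(free, n_b_causal, replace=False)
    beta_b_direct[idx_b] = np.sqrt(h2_b_direct / n_b_causal) * rng.choice(
        [-1.0, 1.0], n_b_causal
    )
    beta_b = mediation_beta * beta_a + beta_b_direct

    from scipy.stats import chi2

    blocks = ld.variants["block"].to_numpy()
    se = 1.0 / np.sqrt(n)

    def _stats(beta: np.ndarray, noise_seed: int) -> pd.DataFrame:
        nrng = np.random.default_rng(noise_seed)
        z = np.empty(m_variants)
        for b, r_mat in ld.corr.items():
            cols = np.flatnonzero(blocks == b)
            marg = r_mat @ beta[cols]
            chol = np.linalg.cholesky(r_mat + 1e-8 * np.eye(len(cols)))
            z[cols] = np.sqrt(n) * marg + chol @ nrng.standard_normal(len(cols))
        out = ld.variants[["SNP", "CHR", "POS", "EA", "NEA", "EAF"]].copy()
        out["BETA"] = z * se
        out["SE"] = se
        out["P"] = chi2.sf(z**2, df=1)
        out["N"] = n
        out["INFO"] = 1.0
        return out

    truth = {
        "beta_a": beta_a,
        "beta_b": beta_b,
        "mediation_beta": mediation_beta,
        "h2_a": float(np.sum(beta_a**2)),
        "h2_b": float(np.sum(beta_b**2)),
        "h2_b_mediated": float(np.sum((mediation_beta * beta_a) ** 2)),
    }
    return _stats(beta_a, seed + 1), _stats(beta_b, seed + 2), truth
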