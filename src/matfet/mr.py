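"""Two-sample Mendelian randomization and transmitted/nontransmitted scores.

Instrument tables are DataFrames with columns
(SNP, beta_exp, se_exp, beta_out, se_out), already harmonized to a common
effect allele per SNP.  The cross-genome variant regresses fetal outcome
effects on maternal-channel exposure effects across index SNPs — two
distinct genomes, so the slope is a pleiotropy summary, not a causal
estimate, and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MrResult:
    method: str
    slope: float
    slope_se: float
    slope_p: float
    n_instruments: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    causal_interpretation: bool = True

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.isf((1 - level) / 2)
        return self.slope - z * self.slope_se, self.slope + z * self.slope_se


def ivw(instruments: pd.DataFrame, random_effects: bool = False) -> MrResult:
    """Inverse-variance weighted estimate: regression of outcome effects on
    exposure effects through the origin, weights 1/se_out^2.

    ``random_effects`` applies the multiplicative random-effects variance
    (SE scaled by sqrt(max(1, chi2/(k-1)))), which keeps the test calibrated
    when per-SNP heterogeneity exceeds sampling noise; the default is the
    first-order fixed-effect SE.
    """
    if len(instruments) < 2:
        raise ValueError("IVW needs at least 2 instruments")
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    w = 1.0 / instruments["se_out"].to_numpy(dtype=float) ** 2
    denom = np.sum(w * bx**2)
    slope = np.sum(w * bx * by) / denom
    se = 1.0 / np.sqrt(denom)
    if random_effects:
        resid_q = float(np.sum(w * (by - slope * bx) ** 2))
        overdispersion = max(1.0, resid_q / max(len(bx) - 1, 1))
        se *= np.sqrt(overdispersion)
    p = 2 * stats.norm.sf(abs(slope / se))
    method = "IVW-mre" if random_effects else "IVW"
    return MrResult(method, float(slope), float(se), float(p), len(instruments))


def egger(instruments: pd.DataFrame, force_zero_intercept: bool = False) -> MrResult:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept (weights 1/se_out^2); the intercept tests directional
    pleiotropy.  With the intercept forced to zero this reproduces IVW."""
    if len(instruments) < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    if force_zero_intercept:
        res = ivw(instruments)
        return MrResult("Egger", res.slope, res.slope_se, res.slope_p,
                        res.n_instruments, 0.0, 0.0, 1.0)
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    w = 1.0 / instruments["se_out"].to_numpy(dtype=float) ** 2
    x = np.column_stack([bx, np.ones(len(bx))])
    xtwx = x.T @ (w[:, None] * x)
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    z = coef / se
    p = 2 * stats.norm.sf(np.abs(z))
    return MrResult(
        "Egger", float(coef[0]), float(se[0]), float(p[0]), len(bx),
        intercept=float(coef[1]), intercept_se=float(se[1]), intercept_p=float(p[1]),
    )


def tn_pgs_regression(
    weights: pd.DataFrame,
    dosages,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Joint regression of the phenotype on three polygenic scores built
    separately over the MnT, MT and PT allele slots.

    ``weights`` has columns (SNP, effect_weight); variants absent from the
    dosage set are ignored (error if none overlap).  Returns one row per
    score channel with beta, se and p, plus the sample size.
    """
    from .trio_alleles import TrioDosage

    assert isinstance(dosages, TrioDosage)
    wmap = weights.set_index("SNP")["effect_weight"]
    snps = dosages.variants["SNP"]
    overlap = snps.isin(wmap.index).to_numpy()
    if overlap.sum() == 0:
        raise ValueError("no overlapping variants between weights and dosages")
    wv = wmap.reindex(snps[overlap]).to_numpy(dtype=float)
    cols = np.flatnonzero(overlap)

    def _score(mat: np.ndarray) -> np.ndarray:
        sub = mat[:, cols]
        filled = np.where(np.isnan(sub), np.nanmean(sub, axis=0), sub)
        return filled @ wv

    s_mnt, s_mt, s_pt = _score(dosages.mnt), _score(dosages.mt), _score(dosages.pt)
    n = len(s_mnt)
    parts = [np.column_stack([s_mnt, s_mt, s_pt])]
    if covariates is not None:
        parts.append(np.asarray(covariates, dtype=float))
    parts.append(np.ones((n, 1)))
    x = np.column_stack(parts)
    y = np.asarray(phenotype, dtype=float)
    xtx_inv = np.linalg.pinv(x.T @ x)
    b = xtx_inv @ (x.T @ y)
    resid = y - x @ b
    dof = max(n - np.linalg.matrix_rank(x), 1)
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    z = np.divide(b, se, out=np.zeros_like(b), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "channel": ["MnT_PGS", "MT_PGS", "PT_PGS"],
            "beta": b[:3],
            "se": se[:3],
            "p": p[:3],
            "n": n,
        }
    )


CHANNELS = ("maternal_nontransmitted", "maternal_transmitted", "paternal_transmitted")
_CHANNEL_COLS = {
    "maternal_nontransmitted": ("beta_mnt", "se_mnt"),
    "maternal_transmitted": ("beta_mt", "se_mt"),
    "paternal_transmitted": ("beta_pt", "se_pt"),
}


def crossgenome_ivw(
    gd_effects: pd.DataFrame,
    bw_fetal_effects: pd.DataFrame,
    channel: str = "maternal_nontransmitted",
    random_effects: bool = True,
) -> MrResult:
    """IVW slope of fetal birth-weight effects on a maternal-channel
    gestational-duration exposure across index SNPs.

    ``gd_effects`` carries the trio-resolved GD effects (beta_mnt/mt/pt with
    SEs); ``bw_fetal_effects`` has columns (SNP, beta, se) for the fetal
    effect on birth weight.  Exposure and outcome come from two different
    genomes, so the result is flagged non-causal.  Defaults to the
    multiplicative random-effects SE because per-SNP pleiotropy spread is
    the expected regime here.
    """
    if channel not in _CHANNEL_COLS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    bcol, scol = _CHANNEL_COLS[channel]
    merged = gd_effects.merge(bw_fetal_effects, on="SNP")
    inst = pd.DataFrame(
        {
            "SNP": merged["SNP"],
            "beta_exp": merged[bcol],
            "se_exp": merged[scol],
            "beta_out": merged["beta"],
            "se_out": merged["se"],
        }
    ).dropna()
    res = ivw(inst, random_effects=random_effects)
    return MrResult(
        f"IVW[{channel}]", res.slope, res.slope_se, res.slope_p,
        res.n_instruments, causal_interpretation=False,
    )
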