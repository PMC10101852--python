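"""Polygenic scores by clumping + thresholding, with validation metrics.

A deliberate stand-in for shrinkage-based score methods: candidate weight
sets are produced by LD clumping the training summary statistics over a
grid of (r2, p-threshold) cells, the cell maximizing R2 in an independent
tuning sample is selected, and scores are z-standardized before validation
(variance explained, decile profile, odds ratio and ROC AUC for the
preterm dichotomy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_meta import clump
from .ld import LDReference


@dataclass
class PgsWeights:
    table: pd.DataFrame  # SNP, effect_allele, effect_weight
    training: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["SNP"].duplicated().any():
            raise ValueError("duplicate variants in weights")
        if not np.all(np.isfinite(self.table["effect_weight"])):
            raise ValueError("non-finite weights")


def build_ct(
    train_stats: pd.DataFrame,
    ld: LDReference,
    tune_dosages: np.ndarray,
    tune_variants: pd.DataFrame,
    tune_phenotype: np.ndarray,
    r2_grid: tuple[float, ...] = (0.001, 0.1, 0.5),
    p_grid: tuple[float, ...] = (5e-8, 1e-5, 1e-3, 0.05),
    kb: float = 1000,
) -> PgsWeights:
    """Clumping + thresholding score construction.

    For each (r2, p) cell, clump the training statistics at that stringency
    and take the marginal betas of the retained index SNPs as weights; pick
    the cell with the highest tuning-sample R2.
    """
    if len(r2_grid) == 0 or len(p_grid) == 0:
        raise ValueError("empty tuning grid")
    best = None
    for r2 in r2_grid:
        for p in p_grid:
            clumped = clump(train_stats, ld, r2=r2, kb=kb, p1=p, p2=p)
            if clumped.empty:
                continue
            w = PgsWeights(
                table=pd.DataFrame(
                    {
                        "SNP": clumped["SNP"],
                        "effect_allele": clumped["EA"],
                        "effect_weight": clumped["BETA"],
                    }
                )
            )
            try:
                s = score(w, tune_dosages, tune_variants)
            except ValueError:
                continue
            r = np.corrcoef(s, tune_phenotype)[0, 1]
            r2_tune = 0.0 if np.isnan(r) else r**2
            if best is None or r2_tune > best[0]:
                best = (r2_tune, r2, p, w)
    if best is None:
        # nothing passed any threshold: fall back to an empty score is not
        # usable, so surface it
        raise ValueError("no variants retained in any grid cell")
    r2_tune, r2_cell, p_cell, w = best
    w.training = {
        "r2_threshold": r2_cell,
        "p_threshold": p_cell,
        "tuning_r2": float(r2_tune),
        "tuning_n": int(len(tune_phenotype)),
        "method": "clumping+thresholding",
    }
    return w


def score(
    weights: PgsWeights, dosages: np.ndarray, variants: pd.DataFrame
) -> np.ndarray:
    """Apply a weight table to a dosage matrix; z-standardized output.

    Missing dosages are mean-imputed per variant.  Raises on zero variant
    overlap and on a constant (degenerate) score.
    """
    wmap = weights.table.set_index("SNP")["effect_weight"]
    snps = variants["SNP"]
    overlap = snps.isin(wmap.index).to_numpy()
    if overlap.sum() == 0:
        raise ValueError("no overlapping variants between weights and genotypes")
    cols = np.flatnonzero(overlap)
    w = wmap.reindex(snps[overlap]).to_numpy(dtype=float)
    g = np.asarray(dosages, dtype=float)[:, cols]
    g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
    raw = g @ w
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant score: cannot standardize")
    return (raw - raw.mean()) / sd


def validate_quantitative(
    scores: np.ndarray,
    gd: np.ndarray,
    covariates: np.ndarray | None = None,
    n_deciles: int = 10,
) -> dict:
    """Variance explained and decile profile of a score for a quantitative
    trait.

    Returns incremental R2 of the score over the covariates, the per-SD
    effect in trait units, and a decile table of mean trait value with
    normal-theory 95% CIs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(gd, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 samples")
    if n < 10 * n_deciles:
        raise ValueError(f"need at least {10 * n_deciles} samples for {n_deciles} deciles")

    def _r2(x_parts: list[np.ndarray]) -> float:
        x = np.column_stack(x_parts + [np.ones(n)])
        b, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ b
        tss = ((y - y.mean()) ** 2).sum()
        return 1.0 - (resid @ resid) / tss

    base = [] if covariates is None else [np.asarray(covariates, dtype=float)]
    r2_full = _r2(base + [s])
    r2_base = _r2(base) if base else 0.0
    # per-SD effect with covariate adjustment
    x = np.column_stack(base + [s, np.ones(n)])
    b, *_ = np.linalg.lstsq(x, y, rcond=None)
    effect = float(b[-2])

    ranks = stats.rankdata(s, method="ordinal") - 1
    decile = (ranks * n_deciles // n).astype(int)
    rows = []
    for d in range(n_deciles):
        v = y[decile == d]
        sem = v.std(ddof=1) / np.sqrt(len(v))
        rows.append(
            {"decile": d + 1, "n": len(v), "mean": v.mean(),
             "ci_low": v.mean() - 1.96 * sem, "ci_high": v.mean() + 1.96 * sem}
        )
    return {
        "r2": float(r2_full - r2_base),
        "effect_per_sd": effect,
        "decile_table": pd.DataFrame(rows),
        "n": n,
    }


def _bootstrap_auc_ci(
    y: np.ndarray, s: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].min() == y[idx].max():
            aucs[b] = np.nan
            continue
        aucs[b] = roc_auc_score(y[idx], s[idx])
    return tuple(np.nanpercentile(aucs, [2.5, 97.5]))


def validate_binary(
    scores: np.ndarray,
    labels: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Odds ratio per score SD (logistic model) and ROC AUC with bootstrap CI.

    AUC is reported both unadjusted and, when covariates are given, for the
    covariate-adjusted linear predictor.
    """
    import statsmodels.api as sm
    from sklearn.metrics import roc_auc_score

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = ~np.isnan(y)
    s, y = s[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    parts = [s]
    if covariates is not None:
        parts.append(np.asarray(covariates, dtype=float)[keep])
    x = sm.add_constant(np.column_stack(parts))
    try:
        fit = sm.Logit(y, x).fit(disp=0)
        or_per_sd = float(np.exp(fit.params[1]))
        or_ci = tuple(np.exp(fit.conf_int()[1]))
    except Exception:  # perfect separation: OR unbounded, AUC still defined
        fit = None
        or_per_sd, or_ci = np.inf, (np.nan, np.nan)
    auc = float(roc_auc_score(y, s))
    auc_ci = _bootstrap_auc_ci(y, s, n_boot=n_boot, seed=seed)
    out = {
        "odds_ratio": or_per_sd,
        "or_ci": or_ci,
        "auc": auc,
        "auc_ci": auc_ci,
        "n_cases": int(y.sum()),
        "n_controls": int((1 - y).sum()),
    }
    if covariates is not None and fit is not None:
        out["auc_adjusted"] = float(roc_auc_score(y, fit.predict(x)))
    return out


def train_validation_split(
    n: int, train_frac: float = 0.8, seed: int = 0, kinship_exclude: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """IID random train/validation split (80/20 by default).  A precomputed
    kinship exclusion list (sample indices) is removed from both halves."""
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    if kinship_exclude:
        idx = np.setdiff1d(idx, np.asarray(kinship_exclude))
    perm = rng.permutation(idx)
    cut = int(round(train_frac * len(perm)))
    return np.sort(perm[:cut]), np.sort(perm[cut:])
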