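"""LD reference panel: per-region correlation matrices and per-variant LD scores."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LDReference:
    """Variant-by-variant correlations within LD blocks, plus LD scores.

    ``corr`` maps block id -> correlation matrix over the block's variants
    (order as in ``variants`` restricted to the block).  Variants in
    different blocks are treated as uncorrelated.  ``var`` optionally holds
    the per-variant genotype variance of the reference sample, which lets
    summary-level joint models reproduce individual-level regression exactly
    when the reference *is* the analysis sample.
    """

    variants: pd.DataFrame  # SNP, CHR, POS (+ EAF when known), block
    corr: dict[int, np.ndarray]
    var: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.variants["SNP"])}
        for b, r in self.corr.items():
            if r.shape[0] != r.shape[1]:
                raise ValueError(f"block {b}: correlation matrix not square")
            if not np.allclose(np.diag(r), 1.0, atol=1e-6):
                raise ValueError(f"block {b}: correlation diagonal must be 1")

    @classmethod
    def from_genotypes(
        cls,
        geno: np.ndarray,
        variants: pd.DataFrame,
        blocks: np.ndarray | None = None,
    ) -> "LDReference":
        """Estimate block correlations from a genotype (or haplotype) matrix
        of shape (n_samples, n_variants)."""
        variants = variants.reset_index(drop=True).copy()
        if blocks is None:
            blocks = variants.get("block", pd.Series(np.zeros(len(variants), dtype=int))).to_numpy()
        variants["block"] = blocks
        corr: dict[int, np.ndarray] = {}
        for b in np.unique(blocks):
            cols = np.flatnonzero(blocks == b)
            sub = geno[:, cols]
            sd = sub.std(axis=0, ddof=1)
            if np.any(sd == 0):
                # monomorphic in reference: correlation undefined, use identity rows
                r = np.eye(len(cols))
                ok = sd > 0
                if ok.sum() > 1:
                    r_ok = np.corrcoef(sub[:, ok], rowvar=False)
                    r[np.ix_(ok, ok)] = r_ok
            else:
                r = np.corrcoef(sub, rowvar=False)
                if r.ndim == 0:
                    r = np.array([[1.0]])
            corr[int(b)] = r
        var = geno.var(axis=0, ddof=1)
        if "EAF" not in variants.columns:
            variants["EAF"] = geno.mean(axis=0) / (2.0 if geno.max() > 1 else 1.0)
        return cls(variants=variants, corr=corr, var=var)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def block_of(self, snp: str) -> int:
        return int(self.variants["block"].iloc[self._index[snp]])

    def has(self, snp: str) -> bool:
        return snp in self._index

    def r(self, snp_a: str, snp_b: str) -> float:
        """Pairwise correlation; 0 across blocks or for unknown variants."""
        if snp_a not in self._index or snp_b not in self._index:
            return 0.0
        ia, ib = self._index[snp_a], self._index[snp_b]
        ba = int(self.variants["block"].iloc[ia])
        bb = int(self.variants["block"].iloc[ib])
        if ba != bb:
            return 0.0
        blk = np.flatnonzero(self.variants["block"].to_numpy() == ba)
        pos = {v: i for i, v in enumerate(blk)}
        return float(self.corr[ba][pos[ia], pos[ib]])

    def submatrix(self, snps: list[str]) -> np.ndarray:
        """Correlation matrix for an arbitrary ordered variant list (zeros
        across blocks, identity diagonal; unknown variants treated unlinked)."""
        k = len(snps)
        out = np.eye(k)
        idx = [self._index.get(s) for s in snps]
        blocks = [
            int(self.variants["block"].iloc[i]) if i is not None else None for i in idx
        ]
        block_pos: dict[int, dict[int, int]] = {}
        for b in set(b for b in blocks if b is not None):
            cols = np.flatnonzero(self.variants["block"].to_numpy() == b)
            block_pos[b] = {v: i for i, v in enumerate(cols)}
        for a in range(k):
            for c in range(a + 1, k):
                if idx[a] is None or idx[c] is None or blocks[a] != blocks[c]:
                    continue
                b = blocks[a]
                r = self.corr[b][block_pos[b][idx[a]], block_pos[b][idx[c]]]
                out[a, c] = out[c, a] = r
        return out

    def ld_scores(self) -> np.ndarray:
        """Per-variant LD score l_j = sum_k r_jk^2 over the variant's block."""
        ell = np.empty(self.n_variants)
        blocks = self.variants["block"].to_numpy()
        for b, r in self.corr.items():
            cols = np.flatnonzero(blocks == b)
            ell[cols] = (r**2).sum(axis=1)
        return ell

    def variance_of(self, snps: list[str]) -> np.ndarray:
        """Per-variant genotype variance: measured when available, else
        2 eaf (1 - eaf) from the variant table."""
        out = np.empty(len(snps))
        for i, s in enumerate(snps):
            j = self._index.get(s)
            if j is None:
                out[i] = np.nan
            elif self.var is not None:
                out[i] = self.var[j]
            else:
                p = float(self.variants["EAF"].iloc[j])
                out[i] = 2 * p * (1 - p)
        return out
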