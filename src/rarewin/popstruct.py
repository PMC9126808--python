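"""Rare-variant population-structure inference via the Jaccard index.

Common-variant PCA captures old ancestry; principal components computed
from rare-variant *carrier sets* recover more recent admixture and finer
structure.  The pipeline: greedy windowed LD pruning (squared Pearson
correlation of dosages), random subsampling to a fixed variant budget,
the pairwise Jaccard similarity J_ij = |C_i ∩ C_j| / |C_i ∪ C_j| of
carrier sets, and a PCoA-style eigendecomposition of the double-centered
similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "PruneConfig",
    "ld_prune",
    "subsample_variants",
    "jaccard_matrix",
    "jaccard_pca",
    "rare_variant_pcs",
]


@dataclass
class PruneConfig:
    r2_max: float = 0.01
    window: int = 50  # variants per pruning block
    step: int = 5
    subsample: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r2_max < 1:
            raise ValueError("r2_max must be in (0, 1)")
        if self.window < self.step or self.step < 1:
            raise ValueError("need window ≥ step ≥ 1")


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns; constant
    columns get r² = 0 against everything."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(d, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 0.0)
    return c**2


def ld_prune(G: GenotypeMatrix, cfg: PruneConfig | None = None) -> np.ndarray:
    """Greedy windowed LD pruning on dosages (missing entries mean-imputed
    for the correlation computation only).

    Within each sliding block of ``cfg.window`` variants, while any pair
    exceeds ``r2_max``, the later-positioned variant of the worst pair is
    removed; the block then advances by ``cfg.step``.  Returns the kept
    variant indices (into ``G.variants``), in order.
    """
    cfg = cfg or PruneConfig()
    n_v = G.n_variants
    if n_v == 0:
        return np.array([], dtype=int)
    d = G.dosage.copy()
    if np.isnan(d).any():
        col_mean = np.nan_to_num(np.nanmean(d, axis=0))
        nr, nc = np.where(np.isnan(d))
        d[nr, nc] = col_mean[nc]
    keep = np.ones(n_v, dtype=bool)
    chroms = G.variants["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            block = idx[start : start + cfg.window]
            block = block[keep[block]]
            if len(block) > 1:
                r2 = _pairwise_r2(d[:, block])
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= cfg.r2_max:
                        break
                    drop = max(i, j)  # remove the later-positioned variant
                    keep[block[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
            start += cfg.step
    return np.flatnonzero(keep)


def subsample_variants(
    kept: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Random subset (without replacement) of the pruned variants; if
    fewer than ``m`` survive pruning, all are used."""
    kept = np.asarray(kept)
    if len(kept) <= m:
        return np.sort(kept)
    return np.sort(rng.choice(kept, size=m, replace=False))


def jaccard_matrix(G_subset: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity of rare-variant carrier sets.

    A sample's carrier set is the variants where it holds ≥ 1 ALT allele;
    missing dosages count as non-carrier.  An empty union gives J = 0 by
    convention, so a sample with no ALT alleles has a zero diagonal.
    """
    dosage = G_subset.dosage if isinstance(G_subset, GenotypeMatrix) else G_subset
    if dosage.shape[0] < 2:
        raise ValueError("need ≥ 2 samples")
    carrier = (np.nan_to_num(dosage) >= 1).astype(float)
    inter = carrier @ carrier.T
    sizes = carrier.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return J


def jaccard_pca(
    J: np.ndarray, k: int, center: bool = True, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a Jaccard similarity matrix.

    Double-centers J (PCoA-style; disable with ``center=False``), takes
    the top-k eigenpairs of the symmetric matrix, and returns coordinates
    scaled by √max(eigenvalue, 0).  Sign convention: the loading with the
    largest magnitude on each axis is positive.

    Returns
    -------
    (coords, eigenvalues) with coords of shape (n, k), eigenvalues
    descending.
    """
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    if J.shape != (n, n) or not np.allclose(J, J.T, atol=1e-10):
        raise ValueError("similarity matrix must be square and symmetric")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples {n}")
    M = J
    if center:
        row = M.mean(axis=0, keepdims=True)
        M = M - row - row.T + M.mean()
        M = (M + M.T) / 2.0
    if n > 500 and k < n // 4:
        from scipy.sparse.linalg import eigsh

        v0 = np.random.default_rng(seed).standard_normal(n)  # reproducible start
        vals, vecs = eigsh(M, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
    else:
        vals, vecs = np.linalg.eigh(M)
        order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))[None, :]
    return coords, vals


def rare_variant_pcs(
    G: GenotypeMatrix, cfg: PruneConfig | None = None, k: int = 4
) -> pd.DataFrame:
    """Prune → subsample → Jaccard → PCA, returning a PC table usable as
    covariates by the case-control tests."""
    cfg = cfg or PruneConfig()
    kept = ld_prune(G, cfg)
    rng = np.random.default_rng(cfg.seed)
    chosen = subsample_variants(kept, cfg.subsample, rng)
    J = jaccard_matrix(G.dosage[:, chosen])
    coords, _ = jaccard_pca(J, k, seed=cfg.seed)
    return pd.DataFrame(
        coords, index=pd.Index(G.samples, name="iid"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
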