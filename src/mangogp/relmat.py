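"""Genomic relationship matrices and structure covariates.

The GRM follows VanRaden's first method: G = WW' / (2 * sum_k p_k(1-p_k))
with W the dosage matrix centered at twice the allele frequency. Bending
lifts eigenvalues below a floor so near-singular matrices become positive
definite and invertible; principal components of the GRM summarise
population structure for use as fixed covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix

__all__ = ["GRM", "PCScores", "vanraden_grm", "bend", "grm_pca"]


@dataclass
class GRM:
    """Symmetric individuals x individuals additive relationship matrix."""

    ids: np.ndarray
    matrix: np.ndarray
    allele_freqs: np.ndarray
    bent: bool = False
    eigen_floor: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("GRM shape does not match id count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, individuals) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[v] for v in individuals])
        except KeyError as exc:
            raise KeyError(f"individual not in GRM: {exc}") from exc

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class PCScores:
    """Leading principal components of a GRM, scaled by sqrt(eigenvalue)."""

    ids: np.ndarray
    scores: np.ndarray  # n x k
    variance_proportion: np.ndarray  # per retained component
    cumulative_proportion: float

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def vanraden_grm(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> GRM:
    """VanRaden (method 1) GRM from complete dosages.

    With in-sample frequencies every row of G sums to zero and the mean
    diagonal is near 1 + f. Markers with p(1-p) = 0 carry no information
    and are excluded from numerator and denominator with a warning.
    """
    M = geno.dosages
    if np.isnan(M).any():
        raise ValueError("dosages contain missing values; impute first")
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (geno.n_markers,):
        raise ValueError("freqs length does not match marker count")
    het = p * (1.0 - p)
    keep = het > 0
    if not keep.any():
        raise ValueError("all markers monomorphic at the supplied frequencies")
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} monomorphic markers from GRM")
    W = M[:, keep] - 2.0 * p[keep]
    denom = 2.0 * het[keep].sum()
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return GRM(ids=geno.ids, matrix=G, allele_freqs=p)


def bend(grm: GRM, floor: float | None = None) -> GRM:
    """Raise eigenvalues below ``floor`` so the GRM is positive definite.

    Default floor is 1e-6 x (trace / n). A matrix whose smallest
    eigenvalue already meets the floor is returned unchanged
    (``bent=False``); bending is idempotent.
    """
    if not np.allclose(grm.matrix, grm.matrix.T, atol=1e-8):
        raise ValueError("bend requires a symmetric matrix")
    if floor is None:
        floor = 1e-6 * float(np.trace(grm.matrix)) / grm.n
    vals, vecs = np.linalg.eigh(grm.matrix)
    if vals[0] >= floor:
        return grm
    vals = np.maximum(vals, floor)
    fixed = (vecs * vals) @ vecs.T
    fixed = (fixed + fixed.T) / 2.0
    return GRM(
        ids=grm.ids,
        matrix=fixed,
        allele_freqs=grm.allele_freqs,
        bent=True,
        eigen_floor=floor,
    )


def grm_pca(grm: GRM, k: int) -> PCScores:
    """Top-k principal components of the GRM.

    Scores are eigenvectors scaled by sqrt(eigenvalue), so the outer
    product of the full score matrix reconstructs the GRM. Variance
    proportions are eigenvalues over their (negative-floored) total.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > grm.n:
        raise ValueError("k exceeds the number of individuals")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.maximum(vals, 0.0)
    total = pos.sum()
    props = pos / total if total > 0 else np.zeros_like(pos)
    scores = vecs[:, :k] * np.sqrt(pos[:k])
    return PCScores(
        ids=grm.ids,
        scores=scores,
        variance_proportion=props[:k],
        cumulative_proportion=float(props[:k].sum()),
    )
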