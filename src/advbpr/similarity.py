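"""Pairwise similarity kernels on expression profiles.

Four kernels are supported: Tanimoto coefficient (a real-valued extension of
intersection-over-union), cosine, a global structural-similarity index
(SSIM computed over the whole profile, with mean/variance/covariance read as
expression-change statistics rather than image windows), and Spearman rank
correlation. Assembled drug-drug and target-target similarity matrices feed
the Gaussian dual-similarity regularizer, whose target e^{-d^2} lies in
(0, 1]; negative kernel values are therefore clamped to 0 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import ProfileMatrix
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "tanimoto",
    "cosine",
    "ssim",
    "spearman",
    "similarity_matrix",
]

METHODS = ("tanimoto", "cosine", "ssim", "spearman")


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    method: str
    clamped: bool
    entity_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")

    def to_tsv(self, path) -> None:
        ids = self.entity_ids or [str(i) for i in range(self.values.shape[0])]
        pd.DataFrame(self.values, index=pd.Index(ids, name="id"), columns=ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, method: str = "unknown", clamped: bool = True):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(float),
            method=method,
            clamped=clamped,
            entity_ids=[str(i) for i in df.index],
        )


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def tanimoto(x, y) -> float:
    """Tanimoto coefficient x.y / (|x|^2 + |y|^2 - x.y) on real vectors."""
    x, y = _check_pair(x, y)
    dot = float(x @ y)
    denom = float(x @ x) + float(y @ y) - dot
    if denom <= 0.0:
        raise ValueError("tanimoto undefined: |x|^2 + |y|^2 - x.y <= 0")
    return dot / denom


def cosine(x, y) -> float:
    x, y = _check_pair(x, y)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine undefined for a zero-norm vector")
    return float(x @ y) / (nx * ny)


def ssim(x, y, c1: float = 0.001, c2: float = 0.001) -> float:
    """Global structural similarity over the whole profile (no windows).

    Population moments (mean, variance, covariance over the full vector) are
    used; c1, c2 > 0 keep the ratio defined for flat profiles.
    """
    x, y = _check_pair(x, y)
    if x.size < 2:
        raise ValueError("ssim needs vectors of length >= 2")
    if c1 <= 0 or c2 <= 0:
        raise ValueError("c1 and c2 must be positive")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = float(((x - mx) * (y - my)).mean())
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx * mx + my * my + c1) * (vx + vy + c2)
    )


def spearman(x, y) -> float:
    """Spearman rank correlation 1 - 6*sum(g^2)/(n(n^2-1)), average ranks on ties."""
    x, y = _check_pair(x, y)
    n = x.size
    if n < 2:
        raise ValueError("spearman needs vectors of length >= 2")
    g = rankdata(x) - rankdata(y)
    return 1.0 - 6.0 * float(g @ g) / (n * (n * n - 1))


_KERNELS = {"tanimoto": tanimoto, "cosine": cosine, "ssim": ssim, "spearman": spearman}


def similarity_matrix(
    pm: ProfileMatrix, method: str = "tanimoto", clamp: bool = True
) -> SimilarityMatrix:
    """All-pairs similarity of a profile matrix, vectorized per kernel.

    The result is symmetrized, the diagonal is set to exactly 1, and (by
    default) negative entries are clamped to 0 so the matrix is comparable
    with the Gaussian kernel of latent distances.
    """
    if method not in _KERNELS:
        raise ValueError(f"unknown similarity method: {method!r}")
    X = pm.features
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty profile matrix")
    if method == "tanimoto":
        G = X @ X.T
        sq = np.diag(G)
        denom = sq[:, None] + sq[None, :] - G
        bad = np.nonzero(denom <= 0)
        if bad[0].size:
            i, j = int(bad[0][0]), int(bad[1][0])
            raise ValueError(
                f"tanimoto undefined for pair ({pm.entity_ids[i]!r}, {pm.entity_ids[j]!r})"
            )
        S = G / denom
    elif method == "cosine":
        norms = np.linalg.norm(X, axis=1)
        zero = np.nonzero(norms == 0)[0]
        if zero.size:
            raise ValueError(
                f"cosine undefined: zero-norm profile {pm.entity_ids[int(zero[0])]!r}"
            )
        Xn = X / norms[:, None]
        S = Xn @ Xn.T
    elif method == "ssim":
        if X.shape[1] < 2:
            raise ValueError("ssim needs >= 2 features")
        mu = X.mean(axis=1)
        var = X.var(axis=1)
        C = (X - mu[:, None]) @ (X - mu[:, None]).T / X.shape[1]
        c1 = c2 = 0.001
        S = ((2 * np.outer(mu, mu) + c1) * (2 * C + c2)) / (
            (mu[:, None] ** 2 + mu[None, :] ** 2 + c1) * (var[:, None] + var[None, :] + c2)
        )
    else:  # spearman
        if X.shape[1] < 2:
            raise ValueError("spearman needs >= 2 features")
        R = rankdata(X, axis=1)
        d = X.shape[1]
        sq = (R * R).sum(axis=1)
        D = sq[:, None] + sq[None, :] - 2 * (R @ R.T)  # sum of squared rank diffs
        S = 1.0 - 6.0 * D / (d * (d * d - 1))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    if clamp:
        S = np.clip(S, 0.0, None)
    return SimilarityMatrix(
        values=S, method=method, clamped=clamp, entity_ids=list(pm.entity_ids)
    )
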