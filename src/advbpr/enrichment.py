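"""Enrichment of predicted edge lists against reference interaction sets.

Given a ranked list of predicted drug-target pairs and a reference edge
set (another interaction database restricted to the in-scope drug x target
universe), this module computes sliding-bin overlap curves, the fold
enrichment score ES = (k/n)/(m/N), the hypergeometric upper-tail
probability P(X >= k), and Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "overlap_curve",
    "enrichment_score",
    "hypergeom_pvalue",
    "fdr_correct",
    "restrict_reference",
]


@dataclass
class EnrichmentInput:
    """Overlap counts: k hits among n picks, m reference edges, N possible pairs."""

    k: int
    N: int
    n: int
    m: int

    def __post_init__(self) -> None:
        for name in ("k", "N", "n", "m"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n > self.N or self.m > self.N:
            raise ValueError("n and m cannot exceed N")
        if self.k > min(self.n, self.m):
            raise ValueError("k cannot exceed min(n, m)")


@dataclass
class EnrichmentResult:
    es: float
    p_value: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if self.p_adjusted < self.p_value - 1e-15:
            raise ValueError("adjusted p-value below raw p-value")


def overlap_curve(
    ranked_pairs,
    reference: set,
    bin_size: int,
    stride: int | None = None,
) -> list[tuple[int, int, int]]:
    """Overlap counts in sliding bins of consecutive ranked pairs.

    Returns (bin start index, actual bin size, overlap count) per window;
    stride defaults to bin_size (non-overlapping bins) and the final partial
    window is included with its actual size.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    stride = bin_size if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pairs = [(p[0], p[1]) for p in ranked_pairs]
    if len(set(pairs)) != len(pairs):
        raise ValueError("ranked pair list contains duplicates")
    hits = np.fromiter((p in reference for p in pairs), dtype=bool, count=len(pairs))
    curve = []
    for start in range(0, len(pairs), stride):
        window = hits[start : start + bin_size]
        if window.size == 0:
            break
        curve.append((start, int(window.size), int(window.sum())))
    return curve


def enrichment_score(ei: EnrichmentInput) -> float:
    """Fold enrichment (k/n)/(m/N): observed overlap over its expectation."""
    if ei.n == 0 or ei.m == 0 or ei.N == 0:
        raise ValueError("enrichment score undefined for zero n, m or N")
    return (ei.k / ei.n) / (ei.m / ei.N)


def hypergeom_pvalue(ei: EnrichmentInput) -> float:
    """Upper tail P(X >= k) of Hypergeometric(N, m, n), computed stably."""
    # scipy parametrization: population N, m marked, n drawn
    return float(hypergeom.sf(ei.k - 1, ei.N, ei.m, ei.n))


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def restrict_reference(
    reference_edges, drug_ids, target_ids
) -> set[tuple[str, str]]:
    """Intersect a reference edge set with the in-scope drug x target universe."""
    d = set(drug_ids)
    t = set(target_ids)
    return {(a, b) for a, b in reference_edges if a in d and b in t}
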