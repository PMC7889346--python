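"""Per-drug ranking metrics: pairwise AUC, Top_k, prec_k, AUPR and NDCG.

All metrics are macro-averages: computed per drug over that drug's
evaluated candidates, then averaged with equal weight across drugs. Rank
competition is pessimistic: a candidate tied with a positive counts against
it (the competitor condition uses score >=), and a tied triple contributes
0 to AUC (strict >).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FactorModel
from .data import InteractionMatrix, TripleSet

__all__ = [
    "EvaluationContext",
    "auc",
    "top_k",
    "prec_k",
    "aupr",
    "ndcg",
    "evaluate_model",
]


@dataclass
class EvaluationContext:
    """Scores and labels for a per-drug ranking evaluation.

    For every evaluated drug: the candidate target indices, their scores,
    and a boolean mask of test positives. Test triples (if available) drive
    the pairwise AUC.
    """

    candidates: dict[int, np.ndarray]
    scores: dict[int, np.ndarray]
    positive_mask: dict[int, np.ndarray]
    triples: TripleSet | None = None
    triple_scores: np.ndarray | None = None  # (n_triples, 2): r_ij, r_ik

    def __post_init__(self) -> None:
        for i in self.candidates:
            c, s, p = self.candidates[i], self.scores[i], self.positive_mask[i]
            if not (len(c) == len(s) == len(p)):
                raise ValueError(f"misaligned arrays for drug {i}")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"non-finite score for drug {i}")

    def drugs(self) -> list[int]:
        return sorted(self.candidates)

    @classmethod
    def from_model(
        cls,
        model: FactorModel,
        test_triples: TripleSet,
        im: InteractionMatrix | None = None,
        pool: str = "filtered",
    ) -> "EvaluationContext":
        """Build a context by scoring a trained model on held-out triples.

        The candidate pool per drug is every target column; with
        pool='filtered' the drug's known positives that are NOT among its
        test positives (i.e. its training edges) are removed, so recovering
        a training edge is not penalized. pool='full' keeps every column.
        """
        if pool not in ("filtered", "full"):
            raise ValueError(f"unknown pool mode {pool!r}")
        tri = test_triples.triples
        n = model.F_T.shape[0]
        candidates: dict[int, np.ndarray] = {}
        scores: dict[int, np.ndarray] = {}
        pos_mask: dict[int, np.ndarray] = {}
        for i in np.unique(tri[:, 0]).tolist():
            test_pos = np.unique(tri[tri[:, 0] == i, 1])
            keep = np.ones(n, dtype=bool)
            if pool == "filtered" and im is not None:
                train_pos = np.nonzero(im.y[i])[0]
                keep[np.setdiff1d(train_pos, test_pos)] = False
            cand = np.nonzero(keep)[0]
            candidates[i] = cand
            scores[i] = model.F_D[i] @ model.F_T[cand].T
            mask = np.zeros(n, dtype=bool)
            mask[test_pos] = True
            pos_mask[i] = mask[cand]
        tscores = np.column_stack(
            [
                np.einsum("ij,ij->i", model.F_D[tri[:, 0]], model.F_T[tri[:, 1]]),
                np.einsum("ij,ij->i", model.F_D[tri[:, 0]], model.F_T[tri[:, 2]]),
            ]
        )
        return cls(
            candidates=candidates,
            scores=scores,
            positive_mask=pos_mask,
            triples=test_triples,
            triple_scores=tscores,
        )


def _drugs_with_positives(ctx: EvaluationContext) -> list[int]:
    out = []
    for i in ctx.drugs():
        if ctx.positive_mask[i].any():
            out.append(i)
        else:
            warnings.warn(f"drug {i} has no test positives; excluded")
    return out


def auc(ctx: EvaluationContext) -> float:
    """Per-drug fraction of test triples ranked correctly (r_ij > r_ik)."""
    if ctx.triples is None or ctx.triple_scores is None:
        raise ValueError("AUC requires test triples with scores")
    tri = ctx.triples.triples
    correct = ctx.triple_scores[:, 0] > ctx.triple_scores[:, 1]
    vals = []
    for i in np.unique(tri[:, 0]).tolist():
        rows = tri[:, 0] == i
        vals.append(float(correct[rows].mean()))
    if not vals:
        raise ValueError("no drugs with test triples")
    return float(np.mean(vals))


def _in_top_k(scores: np.ndarray, pos: np.ndarray, k: int) -> int:
    """Count positives whose number of >=-scoring competitors is <= k-1."""
    hits = 0
    for idx in np.nonzero(pos)[0]:
        competitors = int(np.sum(scores >= scores[idx])) - 1  # excludes itself
        if competitors <= k - 1:
            hits += 1
    return hits


def top_k(ctx: EvaluationContext, k: int) -> float:
    """Per-drug recall among the k top-ranked candidates, macro-averaged."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = [
        _in_top_k(ctx.scores[i], ctx.positive_mask[i], k) / int(ctx.positive_mask[i].sum())
        for i in _drugs_with_positives(ctx)
    ]
    if not vals:
        raise ValueError("no drugs with test positives")
    return float(np.mean(vals))


def prec_k(ctx: EvaluationContext, k: int) -> float:
    """Per-drug precision among the k top-ranked candidates, macro-averaged."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = [
        _in_top_k(ctx.scores[i], ctx.positive_mask[i], k) / k
        for i in _drugs_with_positives(ctx)
    ]
    if not vals:
        raise ValueError("no drugs with test positives")
    return float(np.mean(vals))


def _aupr_single(scores: np.ndarray, pos: np.ndarray) -> float:
    n_cand = scores.size
    n_pos = int(pos.sum())
    recall = np.empty(n_cand + 1)
    precision = np.empty(n_cand + 1)
    hits = np.array([_in_top_k(scores, pos, k) for k in range(1, n_cand + 1)])
    recall[1:] = hits / n_pos
    precision[1:] = hits / np.arange(1, n_cand + 1)
    # anchor: recall 0 at the precision of the top-ranked item
    recall[0] = 0.0
    precision[0] = precision[1]
    return float(np.trapezoid(precision, recall))


def aupr(ctx: EvaluationContext) -> float:
    """Area under the per-drug (Top_k, prec_k) curve swept over k, averaged.

    The curve is integrated by trapezoid over the recall axis, anchored at
    (recall=0, precision of the top-ranked candidate).
    """
    vals = [
        _aupr_single(ctx.scores[i], ctx.positive_mask[i])
        for i in _drugs_with_positives(ctx)
    ]
    if not vals:
        raise ValueError("no drugs with test positives")
    return float(np.mean(vals))


def _ndcg_single(scores: np.ndarray, pos: np.ndarray, k: int | None) -> float:
    cand = np.arange(scores.size)
    order = np.lexsort((cand, -scores))  # desc score, ties by ascending index
    ranked_pos = pos[order]
    depth = scores.size if k is None else min(k, scores.size)
    discounts = 1.0 / np.log2(np.arange(2, depth + 2))
    dcg = float(discounts[ranked_pos[:depth]].sum())
    ideal_hits = min(int(pos.sum()), depth)
    idcg = float(discounts[:ideal_hits].sum())
    return dcg / idcg


def ndcg(ctx: EvaluationContext, k: int | None = None) -> float:
    """Binary-relevance NDCG with 1/log2(rank+1) discount, macro-averaged."""
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    vals = [
        _ndcg_single(ctx.scores[i], ctx.positive_mask[i], k)
        for i in _drugs_with_positives(ctx)
    ]
    if not vals:
        raise ValueError("no drugs with test positives")
    return float(np.mean(vals))


def evaluate_model(
    model: FactorModel,
    test_triples: TripleSet,
    im: InteractionMatrix | None = None,
    ks: tuple[int, ...] = (1, 5, 10),
    pool: str = "filtered",
) -> dict[str, float]:
    """Convenience wrapper: score held-out triples and compute all metrics."""
    ctx = EvaluationContext.from_model(model, test_triples, im=im, pool=pool)
    out = {"auc": auc(ctx), "aupr": aupr(ctx), "ndcg": ndcg(ctx)}
    for k in ks:
        out[f"top_{k}"] = top_k(ctx, k)
        out[f"prec_{k}"] = prec_k(ctx, k)
    return out
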