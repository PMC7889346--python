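"""Adversarial BPR matrix-factorization engine with dual similarity regularization.

The model scores a drug-target pair by the inner product of two latent
factor rows, r_ij = F_i^D . F_j^T. Training minimizes, over partial-order
triples (i, j, k):

    -ln sigma(r_ij - r_ik) + lambda_theta * L2(F_i, F_j, F_k)          (ranking)
  + lambda_adv * [-ln sigma(r~_ij - r~_ik)]                            (adversarial)
  + lambda_sim * [SimGaus(S^D,F^D,i) + SimGaus(S^T,F^T,j) + SimGaus(S^T,F^T,k)]

where r~ is the score after adding the worst-case (fast-gradient) bounded
perturbation Delta_adv to the three touched factor rows, and SimGaus matches
profile similarity S to the Gaussian kernel e^{-||F_a - F_b||^2} of latent
distances. Optimization is plain SGD over triples in a seeded shuffle; each
step accumulates all gradient contributions for the three touched rows and
applies them simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TripleSet
from .similarity import SimilarityMatrix

__all__ = [
    "Hyperparams",
    "FactorModel",
    "Perturbation",
    "TrainResult",
    "score",
    "bpr_loss",
    "bpr_gradients",
    "ranking_gradients",
    "adversarial_delta",
    "simgaus_term",
    "simgaus_gradient",
    "train",
    "predict_ranking",
    "top_fraction",
]

INIT_SCALE = 0.01  # stddev of the Gaussian factor initialization


@dataclass
class Hyperparams:
    """Training hyperparameters (names follow the usual BPR conventions)."""

    f: int = 25
    lambda_theta: float = 0.1
    lambda_sim: float = 0.3
    lambda_adv: float = 0.3
    epsilon: float = 0.1
    learning_rate: float = 0.03
    n_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f < 1:
            raise ValueError("latent dimension f must be >= 1")
        for name in ("lambda_theta", "lambda_sim", "lambda_adv", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass
class FactorModel:
    """Latent factor matrices: F_D (drugs, m x f) and F_T (targets, n x f)."""

    F_D: np.ndarray
    F_T: np.ndarray
    drug_ids: list[str] | None = None
    target_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.F_D = np.asarray(self.F_D, dtype=float)
        self.F_T = np.asarray(self.F_T, dtype=float)
        if self.F_D.ndim != 2 or self.F_T.ndim != 2:
            raise ValueError("factor matrices must be 2-D")
        if self.F_D.shape[1] != self.F_T.shape[1]:
            raise ValueError("drug and target factors must share the latent dimension")
        if not (np.all(np.isfinite(self.F_D)) and np.all(np.isfinite(self.F_T))):
            raise ValueError("factors must be finite")

    @property
    def f(self) -> int:
        return self.F_D.shape[1]

    def score_table(self) -> np.ndarray:
        return self.F_D @ self.F_T.T

    def save(self, drug_path, target_path) -> None:
        for M, ids, path in (
            (self.F_D, self.drug_ids, drug_path),
            (self.F_T, self.target_ids, target_path),
        ):
            idx = ids if ids is not None else [str(i) for i in range(M.shape[0])]
            pd.DataFrame(
                M, index=pd.Index(idx, name="id"), columns=[f"z{c}" for c in range(M.shape[1])]
            ).to_csv(path, sep="\t")

    @classmethod
    def load(cls, drug_path, target_path) -> "FactorModel":
        dd = pd.read_csv(drug_path, sep="\t", index_col=0)
        dt = pd.read_csv(target_path, sep="\t", index_col=0)
        return cls(
            F_D=dd.to_numpy(float),
            F_T=dt.to_numpy(float),
            drug_ids=[str(i) for i in dd.index],
            target_ids=[str(i) for i in dt.index],
        )


@dataclass
class Perturbation:
    """Adversarial perturbation blocks for the three rows of one triple."""

    delta_di: np.ndarray
    delta_tj: np.ndarray
    delta_tk: np.ndarray


@dataclass
class TrainResult:
    model: FactorModel
    loss_trace: np.ndarray  # mean objective per epoch


def _sigmoid(x: float) -> float:
    # stable logistic
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def _softplus(x: float) -> float:
    # ln(1 + e^x), stable for large |x|; -ln sigma(g) == softplus(-g)
    return float(np.logaddexp(0.0, x))


def score(model: FactorModel, i: int, j: int) -> float:
    """Predicted interaction score r_ij = F_i^D . F_j^T."""
    m, n = model.F_D.shape[0], model.F_T.shape[0]
    if not (0 <= i < m) or not (0 <= j < n):
        raise IndexError(f"indices ({i}, {j}) out of range for ({m}, {n})")
    return float(model.F_D[i] @ model.F_T[j])


def bpr_loss(triple, model: FactorModel, lambda_theta: float) -> float:
    """Per-triple BPR objective: -ln sigma(r_ij - r_ik) + L2 regularization."""
    i, j, k = triple
    fi, fj, fk = model.F_D[i], model.F_T[j], model.F_T[k]
    g = float(fi @ (fj - fk))
    reg = lambda_theta * (float(fi @ fi) + float(fj @ fj) + float(fk @ fk))
    return _softplus(-g) + reg


def ranking_gradients(
    triple, model: FactorModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the unregularized ranking term -ln sigma(r_ij - r_ik)."""
    i, j, k = triple
    fi, fj, fk = model.F_D[i], model.F_T[j], model.F_T[k]
    g = float(fi @ (fj - fk))
    s = _sigmoid(-g)
    return -s * (fj - fk), -s * fi, s * fi


def bpr_gradients(
    triple, model: FactorModel, lambda_theta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of bpr_loss w.r.t. the rows F_i^D, F_j^T, F_k^T."""
    i, j, k = triple
    gi, gj, gk = ranking_gradients(triple, model)
    return (
        gi + 2.0 * lambda_theta * model.F_D[i],
        gj + 2.0 * lambda_theta * model.F_T[j],
        gk + 2.0 * lambda_theta * model.F_T[k],
    )


def _normalized(block: np.ndarray, epsilon: float) -> np.ndarray:
    nrm = float(np.linalg.norm(block))
    if nrm == 0.0 or epsilon == 0.0:
        return np.zeros_like(block)
    return (epsilon / nrm) * block

def adversarial_delta(triple, model: FactorModel, epsilon: float) -> Perturbation:
    """Fast-gradient adversarial perturbation of the triple's factor rows.

    Each block is the ranking-loss gradient scaled to L2 norm epsilon
    (ascent direction = worst case to first order); zero-gradient blocks
    stay zero. The perturbation is treated as a constant afterwards.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    gi, gj, gk = ranking_gradients(triple, model)
    return Perturbation(
        delta_di=_normalized(gi, epsilon),
        delta_tj=_normalized(gj, epsilon),
        delta_tk=_normalized(gk, epsilon),
    )


def simgaus_term(S: SimilarityMatrix | np.ndarray, F: np.ndarray, idx: int) -> float:
    """Sum over entities of (S[idx,.] - e^{-||F_idx - F_.||^2})^2."""
    Sv = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, float)
    if Sv.shape[0] != F.shape[0]:
        raise ValueError("similarity matrix and factor matrix are misaligned")
    diff = F[idx] - F
    e = np.exp(-(diff * diff).sum(axis=1))
    r = Sv[idx] - e
    return float(r @ r)


def simgaus_gradient(S: SimilarityMatrix | np.ndarray, F: np.ndarray, idx: int) -> np.ndarray:
    """Gradient of simgaus_term w.r.t. the row F[idx]."""
    Sv = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, float)
    if Sv.shape[0] != F.shape[0]:
        raise ValueError("similarity matrix and factor matrix are misaligned")
    diff = F[idx] - F
    e = np.exp(-(diff * diff).sum(axis=1))
    w = 4.0 * (Sv[idx] - e) * e
    return w @ diff


def train(
    ts: TripleSet,
    S_D: SimilarityMatrix | np.ndarray | None,
    S_T: SimilarityMatrix | np.ndarray | None,
    hp: Hyperparams,
    n_drugs: int | None = None,
    n_targets: int | None = None,
    drug_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> TrainResult:
    """SGD minimax training over the triple set.

    Per epoch the triples are visited in a seeded shuffle; each step builds
    the adversarial perturbation at the current parameters, accumulates the
    ranking, adversarial and similarity gradients for the three touched
    rows, and applies one simultaneous learning-rate step. Returns the final
    model and the mean per-triple objective per epoch.
    """
    SD = S_D.values if isinstance(S_D, SimilarityMatrix) else S_D
    ST = S_T.values if isinstance(S_T, SimilarityMatrix) else S_T
    m = SD.shape[0] if SD is not None else n_drugs
    n = ST.shape[0] if ST is not None else n_targets
    if m is None or n is None:
        raise ValueError("entity counts unavailable: pass similarity matrices or counts")
    if hp.lambda_sim > 0 and (SD is None or ST is None):
        raise ValueError("lambda_sim > 0 requires both similarity matrices")
    if len(ts) == 0:
        raise ValueError("empty triple set")
    tri = ts.triples
    if tri[:, 0].max() >= m or max(tri[:, 1].max(), tri[:, 2].max()) >= n:
        raise ValueError("triple indices exceed entity counts")

    rng = np.random.default_rng(hp.seed)
    F_D = rng.normal(0.0, INIT_SCALE, size=(m, hp.f))
    F_T = rng.normal(0.0, INIT_SCALE, size=(n, hp.f))
    lr = hp.learning_rate
    lth = hp.lambda_theta
    trace = np.empty(hp.n_epochs)

    for epoch in range(hp.n_epochs):
        order = rng.permutation(len(ts))
        total = 0.0
        for pos, row in enumerate(order):
            i, j, k = tri[row]
            fi, fj, fk = F_D[i], F_T[j], F_T[k]
            g = float(fi @ (fj - fk))
            s = _sigmoid(-g)
            gi = -s * (fj - fk) + 2.0 * lth * fi
            gj = -s * fi + 2.0 * lth * fj
            gk = s * fi + 2.0 * lth * fk
            loss = _softplus(-g) + lth * (
                float(fi @ fi) + float(fj @ fj) + float(fk @ fk)
            )

            if hp.lambda_adv > 0.0:
                di = _normalized(-s * (fj - fk), hp.epsilon)
                dj = _normalized(-s * fi, hp.epsilon)
                dk = _normalized(s * fi, hp.epsilon)
                pfi, pfj, pfk = fi + di, fj + dj, fk + dk
                gp = float(pfi @ (pfj - pfk))
                sp = _sigmoid(-gp)
                gi += hp.lambda_adv * (-sp * (pfj - pfk))
                gj += hp.lambda_adv * (-sp * pfi)
                gk += hp.lambda_adv * (sp * pfi)
                loss += hp.lambda_adv * _softplus(-gp)

            if hp.lambda_sim > 0.0:
                dD = fi - F_D
                eD = np.exp(-(dD * dD).sum(axis=1))
                rD = SD[i] - eD
                gi += hp.lambda_sim * ((4.0 * rD * eD) @ dD)

                dJ = fj - F_T
                eJ = np.exp(-(dJ * dJ).sum(axis=1))
                rJ = ST[j] - eJ
                gj += hp.lambda_sim * ((4.0 * rJ * eJ) @ dJ)

                dK = fk - F_T
                eK = np.exp(-(dK * dK).sum(axis=1))
                rK = ST[k] - eK
                gk += hp.lambda_sim * ((4.0 * rK * eK) @ dK)

                loss += hp.lambda_sim * (
                    float(rD @ rD) + float(rJ @ rJ) + float(rK @ rK)
                )

            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, triple index {int(row)}"
                )
            F_D[i] = fi - lr * gi
            F_T[j] = fj - lr * gj
            F_T[k] = fk - lr * gk
            total += loss
        trace[epoch] = total / len(ts)

    model = FactorModel(F_D=F_D, F_T=F_T, drug_ids=drug_ids, target_ids=target_ids)
    return TrainResult(model=model, loss_trace=trace)


def predict_ranking(
    model: FactorModel,
    drug: int,
    candidates,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> list[tuple[int, float]]:
    """Rank candidate targets for one drug, descending by score.

    Ties break by ascending target index (deterministic); excluded targets
    (e.g. the drug's training positives) are dropped first.
    """
    cand = np.asarray([c for c in candidates if c not in exclude], dtype=np.int64)
    if cand.size == 0:
        raise ValueError("no candidates left after exclusion")
    scores = model.F_D[drug] @ model.F_T[cand].T
    order = np.lexsort((cand, -scores))
    return [(int(cand[q]), float(scores[q])) for q in order]


def top_fraction(
    ranked_pairs: list[tuple[int, int, float]],
    fraction: float,
    known_positives: set[tuple[int, int]] | frozenset = frozenset(),
) -> list[tuple[int, int, float]]:
    """Keep the top fraction of a ranked all-pairs list as predicted edges.

    Known interactions are removed first; the cut keeps
    ceil(fraction * remaining) pairs.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    kept = [p for p in ranked_pairs if (p[0], p[1]) not in known_positives]
    n_keep = int(np.ceil(fraction * len(kept)))
    return kept[:n_keep]
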