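"""Planted-factor synthetic data: desk-scale datasets with known structure.

The generator plants low-rank drug and target factors, thresholds the
planted score matrix into positive interactions among true targets, and
embeds the factors into a high-dimensional expression-profile space through
a shared orthonormal linear map plus Gaussian noise. Profile similarity
therefore correlates with planted-factor similarity, emulating the premise
that drug-perturbation profiles correlate with knockout profiles of their
targets. A large nontarget pool carries no positives and supplies candidate
negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import InteractionMatrix, ProfileMatrix

__all__ = ["SyntheticConfig", "generate", "permute_labels"]


@dataclass
class SyntheticConfig:
    """Shapes, noise and sparsity of the planted dataset.

    Defaults are a scaled-down version of a realistic cell-line dataset:
    60 drugs, 40 true targets, 300 nontargets, ~2 positives per drug.
    """

    m_drugs: int = 60
    n_targets: int = 40
    n_nontargets: int = 300
    f_true: int = 5
    f_dim: int = 978
    signal_noise: float = 0.02
    interaction_rate: float = 0.05
    seed: int = 0
    positive_rule: str = "top"  # 'top' (thresholded) or 'logistic' (sampled)

    def __post_init__(self) -> None:
        for name in ("m_drugs", "n_targets", "n_nontargets", "f_true", "f_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.interaction_rate < 1.0:
            raise ValueError("interaction_rate must be in (0, 1)")
        if self.signal_noise < 0:
            raise ValueError("signal_noise must be >= 0")
        if self.positive_rule not in ("top", "logistic"):
            raise ValueError(f"unknown positive_rule {self.positive_rule!r}")


def _orthonormal_map(rng: np.random.Generator, f: int, d: int) -> np.ndarray:
    """(f, d) matrix with orthonormal rows: an isometric embedding R^f -> R^d."""
    q, _ = np.linalg.qr(rng.standard_normal((d, f)))
    return q.T


def generate(
    cfg: SyntheticConfig,
) -> tuple[ProfileMatrix, ProfileMatrix, InteractionMatrix, tuple[np.ndarray, np.ndarray]]:
    """Draw a planted dataset: profiles, interactions and ground-truth factors.

    Positives are the top interaction_rate fraction of planted scores
    G_D G_T' restricted to true-target columns ('top' rule), or Bernoulli
    draws through a logistic link calibrated to the same expected count
    ('logistic'). Nontarget columns never receive positives. With
    signal_noise=0 the profiles are an exact isometric embedding of the
    planted factors, so profile cosine similarity equals factor cosine
    similarity.
    """
    rng = np.random.default_rng(cfg.seed)
    m, nt, nn = cfg.m_drugs, cfg.n_targets, cfg.n_nontargets
    n_all = nt + nn
    G_D = rng.standard_normal((m, cfg.f_true))
    G_T = rng.standard_normal((n_all, cfg.f_true))

    planted = G_D @ G_T[:nt].T  # scores against true targets only
    n_pos = int(round(cfg.interaction_rate * m * nt))
    if n_pos < 1:
        raise ValueError("interaction_rate yields zero positives")
    y = np.zeros((m, n_all), dtype=np.int8)
    if cfg.positive_rule == "top":
        flat = np.argpartition(planted.ravel(), -n_pos)[-n_pos:]
        ii, jj = np.unravel_index(flat, planted.shape)
        y[ii, jj] = 1
    else:
        z = (planted - planted.mean()) / planted.std()
        thresh = np.quantile(z, 1.0 - cfg.interaction_rate)
        prob = 1.0 / (1.0 + np.exp(-(z - thresh) * 4.0))
        prob *= n_pos / prob.sum()  # calibrate expected count
        draws = rng.random(planted.shape) < np.clip(prob, 0.0, 1.0)
        if not draws.any():
            raise ValueError("logistic rule produced zero positives")
        y[:, :nt][draws] = 1

    Q = _orthonormal_map(rng, cfg.f_true, cfg.f_dim)
    drug_feats = G_D @ Q
    target_feats = G_T @ Q
    if cfg.signal_noise > 0:
        drug_feats = drug_feats + rng.normal(0.0, cfg.signal_noise, drug_feats.shape)
        target_feats = target_feats + rng.normal(
            0.0, cfg.signal_noise, target_feats.shape
        )

    drug_ids = [f"drug{i:03d}" for i in range(m)]
    target_ids = [f"tgt{j:03d}" for j in range(nt)] + [
        f"non{j:03d}" for j in range(nn)
    ]
    drugs = ProfileMatrix(entity_ids=drug_ids, features=drug_feats)
    targets = ProfileMatrix(entity_ids=target_ids, features=target_feats)
    im = InteractionMatrix(
        drug_ids=drug_ids,
        target_ids=target_ids,
        y=y,
        nontarget_flags=y.sum(axis=0) == 0,
        cell_line="synthetic",
    )
    return drugs, targets, im, (G_D, G_T)


def permute_labels(im: InteractionMatrix, seed: int) -> InteractionMatrix:
    """Negative control: scatter the positives uniformly over true-target cells.

    The positive count and the nontarget flags are preserved; only cells in
    non-flagged (true target) columns can receive positives.
    """
    rng = np.random.default_rng(seed)
    true_cols = np.nonzero(~im.nontarget_flags)[0]
    if true_cols.size == 0:
        raise ValueError("no true-target columns to permute into")
    n_pos = im.n_positives
    pool = im.n_drugs * true_cols.size
    if pool < n_pos:
        raise ValueError("true-target cell pool smaller than positive count")
    flat = rng.choice(pool, size=n_pos, replace=False)
    di, ci = np.divmod(flat, true_cols.size)
    y = np.zeros_like(im.y)
    y[di, true_cols[ci]] = 1
    return InteractionMatrix(
        drug_ids=list(im.drug_ids),
        target_ids=list(im.target_ids),
        y=y,
        nontarget_flags=im.nontarget_flags.copy(),
        cell_line=im.cell_line,
    )
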