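"""Dataset containers, negative sampling, triple generation and CV splitting.

The learning problem is posed per cell line: a set of drugs with expression
profiles, a set of targets and nontargets with expression profiles, and a
sparse binary interaction matrix. Training consumes partial-order triples
(d_i, t_j, t_k) asserting that the positive pair (d_i, t_j) should outrank
the negative pair (d_i, t_k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "InteractionMatrix",
    "TripleSet",
    "CVSplit",
    "build_interaction_matrix",
    "sample_negatives",
    "generate_triples",
    "split_cv",
    "inner_split",
    "read_edges",
    "write_edges",
]


@dataclass
class ProfileMatrix:
    """Entity-by-feature matrix of expression scores.

    One row per drug (or per target/nontarget), one column per measured
    feature (978 for L1000-style landmark-gene profiles).
    """

    entity_ids: list[str]
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if len(self.entity_ids) != self.features.shape[0]:
            raise ValueError(
                f"{len(self.entity_ids)} ids for {self.features.shape[0]} feature rows"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("entity_ids must be unique")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def n_entities(self) -> int:
        return self.features.shape[0]

    @property
    def f_dim(self) -> int:
        return self.features.shape[1]

    def index(self, entity_id: str) -> int:
        try:
            return self._index[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity id: {entity_id!r}") from None

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.features,
            index=pd.Index(self.entity_ids, name="id"),
            columns=[f"f{c}" for c in range(self.f_dim)],
        )
        df.to_csv(path, sep=_sep_for(path))

    @classmethod
    def from_tsv(cls, path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        return cls(entity_ids=[str(i) for i in df.index], features=df.to_numpy(float))


@dataclass
class InteractionMatrix:
    """Binary drug x target interaction matrix with nontarget annotation.

    A target column is a *nontarget* when it has no recorded positive with
    any drug; drug x nontarget cells form the candidate negative pool.
    """

    drug_ids: list[str]
    target_ids: list[str]
    y: np.ndarray
    nontarget_flags: np.ndarray
    cell_line: str | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.nontarget_flags = np.asarray(self.nontarget_flags, dtype=bool)
        m, n = self.y.shape
        if m != len(self.drug_ids) or n != len(self.target_ids):
            raise ValueError("y shape inconsistent with id lists")
        if self.nontarget_flags.shape != (n,):
            raise ValueError("nontarget_flags length must match target count")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y entries must be 0 or 1")
        if self.y[:, self.nontarget_flags].any():
            raise ValueError("a column flagged nontarget has a positive entry")

    @property
    def n_drugs(self) -> int:
        return self.y.shape[0]

    @property
    def n_targets(self) -> int:
        return self.y.shape[1]

    @property
    def n_positives(self) -> int:
        return int(self.y.sum())

    @property
    def n_candidate_negatives(self) -> int:
        """Size of the drug x nontarget candidate negative pool."""
        return self.n_drugs * int(self.nontarget_flags.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(self.y)
        return list(zip(ii.tolist(), jj.tolist()))


@dataclass
class TripleSet:
    """Partial-order triples (drug i, positive target j, negative target k)."""

    triples: np.ndarray  # (n, 3) int

    def __post_init__(self) -> None:
        self.triples = np.asarray(self.triples, dtype=np.int64).reshape(-1, 3)

    def __len__(self) -> int:
        return self.triples.shape[0]

    def per_drug(self) -> dict[int, np.ndarray]:
        """Group triple row-indices by drug (the per-drug sets H_i)."""
        out: dict[int, list[int]] = {}
        for row, i in enumerate(self.triples[:, 0].tolist()):
            out.setdefault(i, []).append(row)
        return {i: np.asarray(rows) for i, rows in out.items()}

    def validate(self, im: InteractionMatrix) -> None:
        i, j, k = self.triples.T
        if not (im.y[i, j] == 1).all():
            raise ValueError("triple with y[i,j] != 1")
        if not (im.y[i, k] == 0).all():
            raise ValueError("triple with y[i,k] != 0")
        if (j == k).any():
            raise ValueError("triple with j == k")
        if len(np.unique(self.triples, axis=0)) != len(self):
            raise ValueError("duplicate triples")

    def subset(self, rows: np.ndarray) -> "TripleSet":
        return TripleSet(self.triples[np.asarray(rows)])


@dataclass
class CVSplit:
    """Fold assignment over a triple set, stratified by drug."""

    n_folds: int
    assignment: np.ndarray  # fold index per triple
    seed: int

    def fold_rows(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment == fold)[0]

    def train_test(self, ts: TripleSet, fold: int) -> tuple[TripleSet, TripleSet]:
        test = self.assignment == fold
        return ts.subset(np.nonzero(~test)[0]), ts.subset(np.nonzero(test)[0])


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def build_interaction_matrix(
    drug_profiles: ProfileMatrix,
    target_profiles: ProfileMatrix,
    positive_edges: list[tuple[str, str]],
    cell_line: str | None = None,
) -> InteractionMatrix:
    """Assemble the binary interaction matrix from a positive edge list.

    Unknown identifiers raise; duplicate edges are collapsed with a warning.
    Columns that end up all-zero are flagged as nontargets (candidate
    negative pool).
    """
    m, n = drug_profiles.n_entities, target_profiles.n_entities
    y = np.zeros((m, n), dtype=np.int8)
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for d, t in positive_edges:
        if (d, t) in seen:
            n_dup += 1
            continue
        seen.add((d, t))
        y[drug_profiles.index(d), target_profiles.index(t)] = 1
    if n_dup:
        warnings.warn(f"deduplicated {n_dup} repeated positive edge(s)")
    flags = y.sum(axis=0) == 0
    return InteractionMatrix(
        drug_ids=list(drug_profiles.entity_ids),
        target_ids=list(target_profiles.entity_ids),
        y=y,
        nontarget_flags=flags,
        cell_line=cell_line,
    )


def sample_negatives(
    im: InteractionMatrix, seed: int, n_samples: int | None = None
) -> list[tuple[int, int]]:
    """Uniformly sample drug x nontarget pairs without replacement.

    By default the sample size matches the positive count, so positives and
    negatives are balanced within the cell line.
    """
    nontarget_cols = np.nonzero(im.nontarget_flags)[0]
    pool = im.n_drugs * nontarget_cols.size
    if pool == 0:
        raise ValueError("nontarget pool is empty")
    count = im.n_positives if n_samples is None else int(n_samples)
    if pool < count:
        raise ValueError(
            f"candidate negative pool ({pool}) smaller than requested sample ({count})"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(pool, size=count, replace=False)
    di, ci = np.divmod(flat, nontarget_cols.size)
    ki = nontarget_cols[ci]
    order = np.lexsort((ki, di))  # deterministic presentation order
    return list(zip(di[order].tolist(), ki[order].tolist()))


def generate_triples(
    positives: list[tuple[int, int]],
    negatives: list[tuple[int, int]],
    mode: str = "cross",
) -> TripleSet:
    """Combine each drug's positives and sampled negatives into triples.

    mode='cross' forms, per drug, the full Cartesian product of its positive
    targets and its sampled negative targets (the set definition of H_i);
    mode='paired' pairs the q-th positive with the (q mod #negatives)-th
    negative after sorting both by target index, so each positive appears in
    exactly one triple. Drugs lacking positives or negatives contribute
    nothing.
    """
    if mode not in ("cross", "paired"):
        raise ValueError(f"unknown triple mode: {mode!r}")
    pos_by_drug: dict[int, list[int]] = {}
    for i, j in positives:
        pos_by_drug.setdefault(i, []).append(j)
    neg_by_drug: dict[int, list[int]] = {}
    for i, k in negatives:
        neg_by_drug.setdefault(i, []).append(k)
    rows: list[tuple[int, int, int]] = []
    for i in sorted(pos_by_drug):
        if i not in neg_by_drug:
            continue
        ps = sorted(set(pos_by_drug[i]))
        ns = sorted(set(neg_by_drug[i]))
        if mode == "cross":
            rows.extend((i, j, k) for j in ps for k in ns if j != k)
        else:
            rows.extend((i, j, ns[q % len(ns)]) for q, j in enumerate(ps) if j != ns[q % len(ns)])
    return TripleSet(np.asarray(rows, dtype=np.int64).reshape(-1, 3))


def split_cv(ts: TripleSet, n_folds: int, seed: int, unit: str = "triple") -> CVSplit:
    """Drug-stratified k-fold assignment of triples.

    With unit='triple', each drug's triples are shuffled and dealt
    round-robin starting at a random fold offset, so per-drug fold sizes
    differ by at most one and the folds partition the triple set exactly.
    A positive pair may then appear in triples of different folds, which
    leaks memorized pairs into the test fold. unit='pair' is the strict
    mode: positive pairs (i, j) are assigned to folds the same way and every
    triple follows its pair, so no test positive was seen in training.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(ts) == 0:
        raise ValueError("cannot split an empty triple set")
    if n_folds > len(ts):
        raise ValueError(f"n_folds ({n_folds}) exceeds triple count ({len(ts)})")
    if unit not in ("triple", "pair"):
        raise ValueError(f"unknown split unit {unit!r}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(ts), dtype=np.int64)
    if unit == "triple":
        for _, rows in sorted(ts.per_drug().items()):
            perm = rng.permutation(rows)
            start = int(rng.integers(n_folds))
            assignment[perm] = (start + np.arange(perm.size)) % n_folds
    else:
        tri = ts.triples
        pair_fold: dict[tuple[int, int], int] = {}
        pairs_by_drug: dict[int, list[tuple[int, int]]] = {}
        for i, j in {(int(a), int(b)) for a, b in tri[:, :2]}:
            pairs_by_drug.setdefault(i, []).append((i, j))
        for i in sorted(pairs_by_drug):
            pairs = sorted(pairs_by_drug[i])
            perm = rng.permutation(len(pairs))
            start = int(rng.integers(n_folds))
            for pos, idx in enumerate(perm):
                pair_fold[pairs[idx]] = (start + pos) % n_folds
        for row in range(len(ts)):
            assignment[row] = pair_fold[(int(tri[row, 0]), int(tri[row, 1]))]
    return CVSplit(n_folds=n_folds, assignment=assignment, seed=seed)


def inner_split(
    train_ts: TripleSet, seed: int, val_fraction: float = 0.2
) -> tuple[TripleSet, TripleSet]:
    """Split an outer-fold training set into inner train/validation parts.

    Used for hyperparameter selection inside nested cross-validation; the
    default 4:1 split mirrors a 5-fold inner loop.
    """
    n_folds = max(2, round(1.0 / val_fraction))
    inner = split_cv(train_ts, n_folds=n_folds, seed=seed)
    return inner.train_test(train_ts, fold=0)


def read_edges(path) -> list[tuple[str, str]]:
    """Read a two-column edge list (drug_id, target_id); extra columns ignored."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"edge file {path} needs at least two columns")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_edges(path, edges: list[tuple[str, str]]) -> None:
    pd.DataFrame(edges, columns=["drug_id", "target_id"]).to_csv(
        path, sep=_sep_for(path), index=False
    )
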