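"""Cross-validation designs and the generic CV runner.

Two designs:

* ``genomic_tenfold`` — k folds of near-equal size built from the
  genomic distance matrix (Ward clustering, then greedy balancing), so
  close relatives tend to stay inside one fold and the dependence
  between training and validation sets is reduced;
* ``batch_out`` — whole herd/date batches held out: per repeat,
  floor(train_frac * B) batches train, the rest validate, and repeats
  prefer disjoint validation batch sets until the pool is exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import clone

__all__ = ["FoldAssignment", "genomic_folds", "batch_out_splits", "run_cv"]


@dataclass
class FoldAssignment:
    """Fold label per sample for one CV design (one repeat)."""

    sample_ids: np.ndarray
    fold: np.ndarray
    design: str
    repeat: int = 0
    seed: int = 0
    validation_folds: tuple = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.fold = np.asarray(self.fold, dtype=int)
        if len(self.sample_ids) != len(self.fold):
            raise ValueError("sample_ids and fold must have equal length")
        if self.validation_folds is None:
            self.validation_folds = tuple(np.unique(self.fold))

    def fold_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.fold, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def split(self, v: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, validation_idx) with fold ``v`` held out."""
        val = self.fold == v
        return np.flatnonzero(~val), np.flatnonzero(val)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "design": self.design,
                "repeat": self.repeat,
                "fold": self.fold,
            }
        )


def genomic_folds(
    dist: np.ndarray, sample_ids, k: int = 10, seed: int = 0
) -> FoldAssignment:
    """k near-equal folds from a genomic distance matrix.

    Ward hierarchical clustering cut at k groups, then balanced to
    sizes floor(n/k)/ceil(n/k): over-full folds greedily hand the
    member with the smallest average distance to an under-full fold.
    Deterministic given (dist, k, seed).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")

    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    # fcluster may return fewer groups on degenerate input; split largest
    rng = np.random.default_rng(seed)
    while len(np.unique(labels)) < k:
        big = np.bincount(labels, minlength=k).argmax()
        members = np.flatnonzero(labels == big)
        free = np.setdiff1d(np.arange(k), np.unique(labels))[0]
        labels[rng.choice(members, size=len(members) // 2, replace=False)] = free

    # capacities: n % k folds of size ceil, assigned to the largest clusters
    base, extra = divmod(n, k)
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-(sizes + rng.uniform(0, 0.5, size=k)))  # seeded tie-break
    capacity = np.full(k, base)
    capacity[order[:extra]] = base + 1

    # S[i, f] = total distance from i to current members of fold f
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    S = dist @ onehot
    sizes = sizes.astype(float)
    while True:
        over = np.flatnonzero(np.bincount(labels, minlength=k) > capacity)
        if len(over) == 0:
            break
        under = np.flatnonzero(np.bincount(labels, minlength=k) < capacity)
        best = None
        for f in over:
            members = np.flatnonzero(labels == f)
            avg = S[np.ix_(members, under)] / np.maximum(sizes[under], 1.0)
            i, j = np.unravel_index(np.argmin(avg), avg.shape)
            cand = (avg[i, j], members[i], under[j])
            if best is None or cand < best:
                best = cand
        _, who, dest = best
        src = labels[who]
        labels[who] = dest
        S[:, src] -= dist[:, who]
        S[:, dest] += dist[:, who]
        sizes[src] -= 1
        sizes[dest] += 1

    return FoldAssignment(np.asarray(sample_ids), labels, "genomic_tenfold", 0, seed)


def batch_out_splits(
    batch_labels,
    sample_ids,
    train_frac: float = 0.8,
    repeats: int = 5,
    seed: int = 0,
) -> list[FoldAssignment]:
    """Repeated batch-hold-out splits; fold 0 = train, 1 = validation.

    All records of a batch travel together.  Validation batch sets are
    sampled without replacement across repeats while unused batches
    remain; once the pool is exhausted the remainder is topped up with
    already-used batches (logged via a warning).
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    batch_labels = np.asarray(batch_labels)
    sample_ids = np.asarray(sample_ids, dtype=object)
    batches = np.unique(batch_labels)
    B = len(batches)
    if B < 2:
        raise ValueError("need at least 2 distinct batches")
    n_train = int(np.floor(train_frac * B))
    n_val = B - n_train
    rng = np.random.default_rng(seed)
    pool = list(rng.permutation(batches))
    out = []
    for rep in range(repeats):
        if len(pool) >= n_val:
            val_batches = [pool.pop() for _ in range(n_val)]
        else:
            val_batches = list(pool)
            pool = []
            used = np.setdiff1d(batches, val_batches)
            top_up = rng.choice(used, size=n_val - len(val_batches), replace=False)
            val_batches.extend(top_up.tolist())
            warnings.warn(
                f"repeat {rep}: validation pool exhausted; reusing {len(top_up)} batch(es)"
            )
        fold = np.isin(batch_labels, val_batches).astype(int)
        out.append(
            FoldAssignment(sample_ids, fold, "batch_out", rep, seed, validation_folds=(1,))
        )
    return out


def run_cv(estimator, X, y, folds, sample_ids=None) -> pd.DataFrame:
    """Fit/predict an estimator over one or several FoldAssignments.

    Returns the prediction table (one row per validation individual per
    design repeat) with columns ``sample_id, design, repeat, fold,
    y_true, y_pred, failed``.  A failing fold is recorded and the run
    continues.
    """
    if isinstance(folds, FoldAssignment):
        folds = [folds]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if sample_ids is None:
        sample_ids = folds[0].sample_ids
    sample_ids = np.asarray(sample_ids, dtype=object)

    records = []
    for fa in folds:
        if len(fa.sample_ids) != len(y):
            raise ValueError("fold assignment does not match data length")
        for v in fa.validation_folds:
            tr, va = fa.split(v)
            if len(tr) == 0 or len(va) == 0:
                continue
            try:
                model = clone(estimator).fit(X[tr], y[tr])
                pred = model.predict(X[va])
                failed = False
            except Exception as err:
                warnings.warn(f"fold {v} (repeat {fa.repeat}) failed: {err}")
                pred = np.full(len(va), np.nan)
                failed = True
            for i, yhat in zip(va, pred):
                records.append(
                    (sample_ids[i], fa.design, fa.repeat, int(v), y[i], yhat, failed)
                )
    return pd.DataFrame(
        records,
        columns=["sample_id", "design", "repeat", "fold", "y_true", "y_pred", "failed"],
    )
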