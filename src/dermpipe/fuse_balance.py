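"""Feature fusion, entropy-based selection, and SMOTE-Tomek rebalancing.

The handcrafted HOG descriptor (3780 values) and the deep tap descriptor
(4096 values) are concatenated into one 7876-wide fused vector per
image.  Features are then ranked by the Shannon entropy of their value
distribution over the training samples (a high-entropy feature spreads
over many intensity levels and is informative in the maximum-entropy
sense), and the top 1186 are retained.  Finally the training partition
is rebalanced: SMOTE grows every minority class to the majority count by
convex interpolation between same-class nearest neighbors, and Tomek
links (mutual nearest-neighbor pairs with different labels) are removed
to clean the class boundary.

Selection and rebalancing are fit on training rows only and applied
unchanged elsewhere, so no information leaks from validation or test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .exceptions import DomainError

HOG_DIM = 3780
DEEP_DIM = 4096
FUSED_DIM = HOG_DIM + DEEP_DIM  # 7876
N_SELECT = 1186


@dataclass
class FusedFeatures:
    matrix: np.ndarray  # (n, 7876)
    blocks: dict = field(default_factory=lambda: {"hog": (0, HOG_DIM), "deep": (HOG_DIM, FUSED_DIM)})


@dataclass
class EntropySelection:
    scores: np.ndarray  # (n_features,) bits
    selected_idx: np.ndarray  # (k,) ordered ascending
    bins: int
    n_train: int

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix)[:, self.selected_idx]


@dataclass
class RebalancedSet:
    X: np.ndarray
    y: np.ndarray
    synthetic_flag: np.ndarray  # bool per row
    removed_pairs: list[tuple[int, int]] = field(default_factory=list)


def fuse(hog_vector: np.ndarray, deep_vector: np.ndarray) -> np.ndarray:
    """Concatenate one HOG and one deep descriptor (HOG block first)."""
    hog_vector = np.asarray(hog_vector, dtype=np.float64).ravel()
    deep_vector = np.asarray(deep_vector, dtype=np.float64).ravel()
    if hog_vector.size != HOG_DIM or deep_vector.size != DEEP_DIM:
        raise DomainError(f"expected lengths {HOG_DIM} and {DEEP_DIM}, got {hog_vector.size} and {deep_vector.size}")
    return np.concatenate([hog_vector, deep_vector])


def fuse_matrix(hog_rows: np.ndarray, deep_rows: np.ndarray) -> FusedFeatures:
    """Row-wise fusion of matching HOG and deep descriptor matrices."""
    hog_rows = np.atleast_2d(np.asarray(hog_rows, dtype=np.float64))
    deep_rows = np.atleast_2d(np.asarray(deep_rows, dtype=np.float64))
    if hog_rows.shape[0] != deep_rows.shape[0]:
        raise DomainError("row counts differ")
    if hog_rows.shape[1] != HOG_DIM or deep_rows.shape[1] != DEEP_DIM:
        raise DomainError("descriptor widths differ from the fixed geometry")
    return FusedFeatures(matrix=np.hstack([hog_rows, deep_rows]))


def entropy_scores(train_matrix: np.ndarray, bins: int = 256) -> np.ndarray:
    """Per-feature Shannon entropy (bits) of the training value histogram.

    Each feature's training values are histogrammed into ``bins``
    equal-width bins spanning that feature's own training range;
    constant features score 0.
    """
    x = np.atleast_2d(np.asarray(train_matrix, dtype=np.float64))
    if x.size == 0 or x.shape[0] < 2:
        raise DomainError("need at least two training samples")
    n, _ = x.shape
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    scores = np.zeros(x.shape[1])
    nonconst = span > 0
    if np.any(nonconst):
        xs = (x[:, nonconst] - lo[nonconst]) / span[nonconst]
        b = np.minimum((xs * bins).astype(np.int64), bins - 1)
        # per-feature histogram via offset bincount
        offsets = np.arange(b.shape[1]) * bins
        counts = np.bincount((b + offsets).ravel(), minlength=b.shape[1] * bins)
        counts = counts.reshape(b.shape[1], bins).astype(np.float64)
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        scores[nonconst] = ent
    return scores


def select_top_k(scores: np.ndarray, k: int = N_SELECT, bins: int = 256, n_train: int = 0) -> EntropySelection:
    """Indices of the k highest-entropy features; ties go to the lower index."""
    scores = np.asarray(scores, dtype=np.float64)
    if k > scores.size:
        raise DomainError(f"k={k} exceeds the {scores.size} available features")
    # stable: sort by (-score, index)
    order = np.lexsort((np.arange(scores.size), -scores))
    idx = np.sort(order[:k])
    return EntropySelection(scores=scores, selected_idx=idx, bins=bins, n_train=n_train)


def _check_smote_input(X: np.ndarray, y: np.ndarray, k_neighbors: int) -> dict:
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < 2:
            raise DomainError(f"class {c!r} has a single sample; SMOTE undefined")
    if k_neighbors >= counts.min():
        raise DomainError("k_neighbors must be smaller than the smallest class")
    return dict(zip(classes.tolist(), counts.tolist()))


def smote(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0) -> RebalancedSet:
    """Grow every minority class to the majority count by interpolation.

    A synthetic sample is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``,
    ``x`` a random member of the minority class and ``x_nn`` one of its
    ``k_neighbors`` within-class nearest neighbors.  Deterministic given
    the seed; an already balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    counts = _check_smote_input(X, y, k_neighbors)
    target = max(counts.values())
    rng = np.random.default_rng(seed)

    new_X = [X]
    new_y = [y]
    flags = [np.zeros(len(y), dtype=bool)]
    for c in counts:
        members = np.flatnonzero(y == c)
        deficit = target - counts[c]
        if deficit == 0:
            continue
        Xc = X[members]
        nn = NearestNeighbors(n_neighbors=min(k_neighbors + 1, len(members))).fit(Xc)
        _, nbr = nn.kneighbors(Xc)
        nbr = nbr[:, 1:]  # drop self
        base = rng.integers(0, len(members), size=deficit)
        pick = rng.integers(0, nbr.shape[1], size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        x0 = Xc[base]
        x1 = Xc[nbr[base, pick]]
        synth = x0 + u[:, None] * (x1 - x0)
        new_X.append(synth)
        new_y.append(np.full(deficit, c, dtype=y.dtype))
        flags.append(np.ones(deficit, dtype=bool))

    return RebalancedSet(
        X=np.vstack(new_X),
        y=np.concatenate(new_y),
        synthetic_flag=np.concatenate(flags),
    )


def tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """All mutual-1-NN pairs with different labels (Euclidean), i < j."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2 or len(y) < 2:
        return []
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    _, nbr = nn.kneighbors(X)
    nearest = nbr[:, 1]
    links = []
    for i in range(len(y)):
        j = int(nearest[i])
        if j > i and int(nearest[j]) == i and y[i] != y[j]:
            links.append((i, j))
    return links


def smote_tomek(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0) -> RebalancedSet:
    """SMOTE to the majority count, then drop both members of every Tomek link."""
    over = smote(X, y, k_neighbors=k_neighbors, seed=seed)
    links = tomek_links(over.X, over.y)
    drop = np.zeros(len(over.y), dtype=bool)
    for i, j in links:
        drop[i] = drop[j] = True
    keep = ~drop
    return RebalancedSet(
        X=over.X[keep],
        y=over.y[keep],
        synthetic_flag=over.synthetic_flag[keep],
        removed_pairs=links,
    )
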