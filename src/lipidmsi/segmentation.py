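"""Unsupervised spatial segmentation by bisecting k-means under a
correlation-based spectral distance, and cluster-versus-histology scoring.

The distance between two pixel spectra is ``1 - Pearson r``, which is
insensitive to per-pixel intensity scale — the property that lets clusters
track lipid *composition* rather than overall signal.  2-means under this
metric is run on row-standardized spectra (so Euclidean distance equals
2x the correlation distance), and the leaf with the largest total
within-cluster dispersion is bisected until the requested leaf count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io import TissueMask
from .preprocess import FeatureTable

__all__ = [
    "ClusterMap",
    "OverlapReport",
    "correlation_distance",
    "bisecting_kmeans",
    "score_overlap",
    "select_adipose_cluster",
]


def correlation_distance(u, v) -> float:
    """``1 - Pearson r`` in [0, 2].

    Zero-variance vectors are uncorrelatable: they sit at distance 1 from
    everything except an identical zero-variance vector (distance 0).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    if u.size < 2:
        raise ValueError("need at least 2 elements")
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        if su == 0 and sv == 0 and np.array_equal(u, v):
            return 0.0
        return 1.0
    r = float(np.dot(u - u.mean(), v - v.mean()) / (u.size * su * sv))
    return 1.0 - r


def _standardize(X: np.ndarray) -> np.ndarray:
    """Row-wise z-score scaled to unit norm, so ``zi . zj = Pearson r``."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1, keepdims=True)
    Z = np.divide(Xc, sd * np.sqrt(X.shape[1]), out=np.zeros_like(Xc),
                  where=sd > 0)
    return Z


@dataclass
class BisectionNode:
    node_id: int
    pixels: np.ndarray
    dispersion: float
    children: tuple[int, int] | None = None


@dataclass
class ClusterMap:
    """Leaf assignment per pixel plus the bisection tree that produced it."""

    labels: np.ndarray  # per-pixel leaf id; -1 for excluded/background pixels
    tree: list[BisectionNode] = field(default_factory=list)
    leaf_ids: list[int] = field(default_factory=list)
    grid_shape: tuple[int, int] | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_pixels(self, leaf_id: int) -> np.ndarray:
        return np.nonzero(self.labels == leaf_id)[0]

    def as_image(self) -> np.ndarray:
        if self.grid_shape is None:
            raise ValueError("no grid shape recorded")
        return self.labels.reshape(self.grid_shape)


@dataclass
class OverlapReport:
    """Cluster-to-tissue agreement: per-leaf Dice/Jaccard, global ARI."""

    per_leaf: dict  # leaf id -> (best label, dice, jaccard)
    ari: float


def _two_means(Z: np.ndarray, rng: np.random.Generator, n_restarts: int,
               max_iter: int = 100) -> tuple[np.ndarray, float] | None:
    """Best-of-restarts 2-means on standardized rows.

    Restart 0 seeds from (parent centroid, farthest point), which guarantees
    the split objective never exceeds the parent dispersion; the rest use
    random pixel pairs.  Returns (boolean assignment, objective) or None if
    no proper split exists.
    """
    n = Z.shape[0]
    parent_c = _standardize(Z.mean(axis=0, keepdims=True))[0]
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            d = 1.0 - Z @ parent_c
            c = np.stack([parent_c, Z[int(np.argmax(d))]])
        else:
            i, j = rng.choice(n, size=2, replace=False)
            c = np.stack([Z[i], Z[j]])
        assign = None
        for _ in range(max_iter):
            sim = Z @ c.T  # correlation with each centroid
            new_assign = sim[:, 1] > sim[:, 0]
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for k in (0, 1):
                sel = assign == bool(k)
                if sel.any():
                    c[k] = _standardize(Z[sel].mean(axis=0, keepdims=True))[0]
        if assign is None or assign.all() or not assign.any():
            continue
        obj = 0.0
        for k in (0, 1):
            sel = assign == bool(k)
            obj += float(np.sum(1.0 - Z[sel] @ c[k]))
        if best is None or obj < best[1]:
            best = (assign.copy(), obj)
    return best


def _dispersion(Z: np.ndarray) -> float:
    c = _standardize(Z.mean(axis=0, keepdims=True))[0]
    return float(np.sum(1.0 - Z @ c))


def bisecting_kmeans(
    table: FeatureTable,
    n_leaves: int = 8,
    seed: int = 1,
    n_restarts: int = 10,
    background_tic_fraction: float = 0.05,
) -> ClusterMap:
    """Divisive 2-means segmentation of a feature table's pixels.

    Pixels whose raw TIC falls below ``background_tic_fraction`` of the
    median are excluded as background (label -1).  The leaf with the largest
    total correlation-distance dispersion is split first; splitting stops
    early if no leaf contains two distinct spectra.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    X = table.matrix.T  # pixels x features
    include = np.ones(X.shape[0], dtype=bool)
    if table.pixel_tic is not None:
        tic = np.asarray(table.pixel_tic, dtype=float)
        med = np.median(tic[tic > 0]) if np.any(tic > 0) else 0.0
        include = tic >= background_tic_fraction * med
    idx = np.nonzero(include)[0]
    Z = _standardize(X[idx])
    rng = np.random.default_rng([seed, 0xB15EC7])

    labels = np.full(X.shape[0], -1, dtype=int)
    labels[idx] = 0
    tree = [BisectionNode(0, idx.copy(), _dispersion(Z))]
    leaves = {0: np.arange(len(idx))}  # node id -> positions within idx/Z
    unsplittable: set[int] = set()
    next_id = 1
    while len(leaves) < n_leaves:
        candidates = [nid for nid in leaves if nid not in unsplittable]
        if not candidates:
            break
        nid = max(candidates, key=lambda n: (tree[n].dispersion, -n))
        pos = leaves[nid]
        Zs = Z[pos]
        if len(pos) < 2 or np.allclose(Zs, Zs[0]):
            unsplittable.add(nid)
            continue
        split = _two_means(Zs, rng, n_restarts)
        if split is None:
            unsplittable.add(nid)
            continue
        assign, _ = split
        kids = []
        for k in (False, True):
            sub = pos[assign == k]
            node = BisectionNode(next_id, idx[sub], _dispersion(Z[sub]))
            tree.append(node)
            leaves[next_id] = sub
            kids.append(next_id)
            next_id += 1
        tree[nid].children = (kids[0], kids[1])
        del leaves[nid]
    leaf_ids = sorted(leaves)
    for new, nid in enumerate(leaf_ids):
        labels[idx[leaves[nid]]] = new
    # renumber leaves 0..k-1 in tree-id order
    return ClusterMap(labels=labels, tree=tree,
                      leaf_ids=list(range(len(leaf_ids))),
                      grid_shape=table.grid_shape)


def _dice_jaccard(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    inter = np.intersect1d(a, b).size
    if a.size + b.size == 0:
        return 0.0, 0.0
    dice = 2.0 * inter / (a.size + b.size)
    union = a.size + b.size - inter
    jac = inter / union if union else 0.0
    return dice, jac


def score_overlap(clusters: ClusterMap, mask: TissueMask) -> OverlapReport:
    """Per-leaf best-matching tissue label (by Dice) and global ARI.

    Scores are computed over tissue pixels only (background excluded on
    both sides).
    """
    flat = mask.flat()
    if len(flat) != len(clusters.labels):
        raise ValueError("cluster map and mask dimensions differ")
    tissue = (flat != "background") & (clusters.labels >= 0)
    per_leaf = {}
    tissue_labels = [l for l in np.unique(flat) if l != "background"]
    for leaf in clusters.leaf_ids:
        leaf_px = np.nonzero((clusters.labels == leaf) & tissue)[0]
        best = ("", -1.0, 0.0)
        for lab in tissue_labels:
            lab_px = np.nonzero((flat == lab) & tissue)[0]
            dice, jac = _dice_jaccard(leaf_px, lab_px)
            if dice > best[1]:
                best = (lab, dice, jac)
        per_leaf[leaf] = best
    ari = float(adjusted_rand_score(flat[tissue], clusters.labels[tissue]))
    return OverlapReport(per_leaf=per_leaf, ari=ari)


def select_adipose_cluster(
    clusters: ClusterMap, mask: TissueMask,
) -> tuple[int, np.ndarray]:
    """The leaf best matching adipose (max Dice, ties to the lower id),
    plus all remaining tissue pixels merged into one non-adipose set."""
    flat = mask.flat()
    tissue = (flat != "background") & (clusters.labels >= 0)
    adipose_px = np.nonzero((flat == "adipose") & tissue)[0]
    best_leaf, best_dice = None, 0.0
    for leaf in clusters.leaf_ids:  # ascending: ties keep the lower id
        leaf_px = np.nonzero((clusters.labels == leaf) & tissue)[0]
        dice, _ = _dice_jaccard(leaf_px, adipose_px)
        if dice > best_dice:
            best_leaf, best_dice = leaf, dice
    if best_leaf is None:
        raise ValueError(
            f"no cluster overlaps the adipose label (best Dice {best_dice:.3f})")
    nonadipose = np.nonzero(tissue & (clusters.labels != best_leaf))[0]
    return best_leaf, nonadipose
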