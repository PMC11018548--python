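"""Evidential decision trees, bagged into a forest, predicting through the
co-leaf kernel.

Each training sample carries a mass function over the class frame (crisp
labels become categorical masses). A node's impurity is the mean pairwise
conflict C(m_a, m_b) over its ordered sample pairs,

    Info(s) = sum_{a,b in s} C(m_a, m_b) / (|s|^2 - |s|),

and splits maximize Gain = Info(s) - sum_v |s_v|/|s| * Info(s_v). When every
mass is categorical, C is 1 iff the labels differ, so Info reduces to the
fraction of discordant ordered pairs — a closed form the implementation uses
as a fast path (it equals the O(|s|^2) pairwise computation exactly; tests
assert this). Features are continuous, so splits are binary thresholds over
quantile-spaced candidate midpoints; ties at the threshold go left.

Prediction does not vote the trees. Instead the co-leaf kernel

    K(x, x_i) = (1/W) * #{w : x and x_i reach the same leaf of tree w}

weights every training label, F(x) = sum_i y_i K(x, x_i) / sum_l K(x, x_l),
and the label is sgn(F) with sgn(0) = +1. The ablation variant without the
kernel (plain evidential forest) averages the W leaf masses reached by x and
takes the class with maximal pignistic probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .belief_core import (
    Frame,
    JaccardMatrix,
    MassFunction,
    average_masses,
    binary_frame,
    categorical_mass,
    conflict,
    jaccard_matrix,
    pignistic,
)


class ForestError(ValueError):
    pass


@dataclass
class ForestParams:
    """Knobs of the forest. mtry=None means floor(sqrt(n_features))."""

    W: int = 100
    min_leaf_samples: int = 5
    max_depth: Optional[int] = None
    n_thresholds: int = 32
    mtry: Optional[int] = None
    gain_tol: float = 1e-12
    bootstrap: bool = True
    exhaustive_thresholds: bool = False  # all midpoints; for oracle tests
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "W": self.W,
            "min_leaf_samples": self.min_leaf_samples,
            "max_depth": self.max_depth,
            "n_thresholds": self.n_thresholds,
            "mtry": self.mtry,
            "gain_tol": self.gain_tol,
            "bootstrap": self.bootstrap,
            "exhaustive_thresholds": self.exhaustive_thresholds,
            "seed": self.seed,
        }


@dataclass
class TreeNode:
    """Internal node (attr/thr/left/right; <= goes left) or leaf
    (average in-bag mass, in-bag training ids, dense leaf id)."""

    attr: Optional[int] = None
    thr: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    leaf_mass: Optional[MassFunction] = None
    inbag_ids: Optional[list[int]] = None
    leaf_id: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_mass is not None


def _crisp_labels(masses: Sequence[MassFunction]) -> Optional[np.ndarray]:
    """Subset bitmasks of the singletons if every mass is categorical, else None."""
    out = np.empty(len(masses), dtype=np.int64)
    for i, m in enumerate(masses):
        if not m.is_categorical():
            return None
        out[i] = int(m.focal_indices()[0])
    return out


def _crisp_info(codes: np.ndarray) -> float:
    """Fraction of discordant ordered pairs: (s^2 - sum n_c^2)/(s^2 - s)."""
    s = len(codes)
    if s <= 1:
        return 0.0
    _, counts = np.unique(codes, return_counts=True)
    return float((s * s - (counts**2).sum()) / (s * s - s))


def node_info(masses: Sequence[MassFunction], D: Optional[JaccardMatrix] = None) -> float:
    """Mean pairwise conflict over ordered pairs; 0 for |s| <= 1.

    All-categorical nodes use the discordant-pair closed form; mixed masses
    fall back to the O(|s|^2) pairwise conflict sum.
    """
    s = len(masses)
    if s <= 1:
        return 0.0
    codes = _crisp_labels(masses)
    if codes is not None:
        return _crisp_info(codes)
    if D is None:
        D = jaccard_matrix(masses[0].frame)
    total = 0.0
    for i in range(s):
        for j in range(i + 1, s):
            total += 2.0 * conflict(masses[i], masses[j], D)
    return total / (s * s - s)


def _candidate_thresholds(
    values: np.ndarray, params: ForestParams
) -> np.ndarray:
    """Midpoints between consecutive unique values, thinned to at most
    ``n_thresholds`` quantile-spaced candidates unless exhaustive."""
    uvals = np.unique(values)
    if len(uvals) < 2:
        return np.empty(0)
    if not params.exhaustive_thresholds and len(uvals) > params.n_thresholds + 1:
        idx = np.unique(
            np.round(np.linspace(0, len(uvals) - 1, params.n_thresholds + 1)).astype(int)
        )
        uvals = uvals[idx]
    return (uvals[:-1] + uvals[1:]) / 2.0


def _split_crisp(
    X_node: np.ndarray,
    codes: np.ndarray,
    candidate_attrs: Sequence[int],
    params: ForestParams,
) -> Optional[tuple[int, float, float]]:
    m = len(codes)
    info_s = _crisp_info(codes)
    best: Optional[tuple[int, float, float]] = None
    classes = np.unique(codes)
    onehot = (codes[:, None] == classes[None, :]).astype(float)
    for j in candidate_attrs:
        v = X_node[:, j]
        thrs = _candidate_thresholds(v, params)
        if len(thrs) == 0:
            continue
        order = np.argsort(v, kind="stable")
        vs = v[order]
        cum = np.cumsum(onehot[order], axis=0)  # m x n_classes
        n_l = np.searchsorted(vs, thrs, side="right")
        valid = (n_l >= params.min_leaf_samples) & (m - n_l >= params.min_leaf_samples)
        if not valid.any():
            continue
        thrs, n_l = thrs[valid], n_l[valid]
        cl = cum[n_l - 1]  # class counts left of each threshold
        cr = cum[-1] - cl
        nl = n_l.astype(float)
        nr = m - nl
        with np.errstate(invalid="ignore", divide="ignore"):
            info_l = np.where(nl > 1, (nl**2 - (cl**2).sum(axis=1)) / (nl**2 - nl), 0.0)
            info_r = np.where(nr > 1, (nr**2 - (cr**2).sum(axis=1)) / (nr**2 - nr), 0.0)
        gains = info_s - (nl * info_l + nr * info_r) / m
        k = int(np.argmax(gains))  # thresholds ascend -> first max = lowest thr
        if best is None or gains[k] > best[2]:
            best = (int(j), float(thrs[k]), float(gains[k]))
    if best is None or best[2] <= params.gain_tol:
        return None
    return best


def _split_general(
    X_node: np.ndarray,
    masses: Sequence[MassFunction],
    candidate_attrs: Sequence[int],
    params: ForestParams,
) -> Optional[tuple[int, float, float]]:
    m = len(masses)
    D = jaccard_matrix(masses[0].frame)
    C = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            C[i, j] = C[j, i] = conflict(masses[i], masses[j], D)
    info_s = C.sum() / (m * m - m) if m > 1 else 0.0

    def sub_info(mask: np.ndarray) -> float:
        k = int(mask.sum())
        if k <= 1:
            return 0.0
        return float(C[np.ix_(mask, mask)].sum() / (k * k - k))

    best: Optional[tuple[int, float, float]] = None
    for j in candidate_attrs:
        for thr in _candidate_thresholds(X_node[:, j], params):
            left = X_node[:, j] <= thr
            nl = int(left.sum())
            if nl < params.min_leaf_samples or m - nl < params.min_leaf_samples:
                continue
            gain = info_s - (nl * sub_info(left) + (m - nl) * sub_info(~left)) / m
            if best is None or gain > best[2]:
                best = (int(j), float(thr), float(gain))
    if best is None or best[2] <= params.gain_tol:
        return None
    return best


def best_split(
    X_node: np.ndarray,
    masses: Sequence[MassFunction],
    candidate_attrs: Sequence[int],
    params: ForestParams,
) -> Optional[tuple[int, float, float]]:
    """Maximize the conflict-information gain over (attribute, threshold).

    Returns (attribute, threshold, gain) or None when no split clears
    ``gain_tol`` or satisfies the minimum leaf size. Gain ties break toward
    the lower attribute index, then the lower threshold.
    """
    attrs = sorted(int(a) for a in candidate_attrs)
    codes = _crisp_labels(masses)
    if codes is not None:
        return _split_crisp(np.asarray(X_node, float), codes, attrs, params)
    return _split_general(np.asarray(X_node, float), masses, attrs, params)


class _TreeBuilder:
    def __init__(
        self,
        X: np.ndarray,
        masses: Sequence[MassFunction],
        ids: np.ndarray,
        params: ForestParams,
        rng: np.random.Generator,
    ):
        self.X = X
        self.masses = list(masses)
        self.ids = ids  # original training indices per row
        self.params = params
        self.rng = rng
        self.n = X.shape[1]
        self.mtry = params.mtry or max(1, int(math.floor(math.sqrt(self.n))))
        self.codes = _crisp_labels(self.masses)
        self.next_leaf = 0

    def build(self, idx: np.ndarray, depth: int) -> TreeNode:
        p = self.params
        if (
            len(idx) < 2 * p.min_leaf_samples
            or (p.max_depth is not None and depth >= p.max_depth)
            or self._pure(idx)
        ):
            return self._leaf(idx)
        attrs = self.rng.choice(self.n, size=min(self.mtry, self.n), replace=False)
        node_masses = [self.masses[i] for i in idx]
        found = best_split(self.X[idx], node_masses, attrs, p)
        if found is None:
            return self._leaf(idx)
        attr, thr, _ = found
        left = idx[self.X[idx, attr] <= thr]
        right = idx[self.X[idx, attr] > thr]
        return TreeNode(
            attr=attr,
            thr=thr,
            left=self.build(left, depth + 1),
            right=self.build(right, depth + 1),
        )

    def _pure(self, idx: np.ndarray) -> bool:
        if self.codes is not None:
            return len(np.unique(self.codes[idx])) <= 1
        return node_info([self.masses[i] for i in idx]) <= 0.0

    def _leaf(self, idx: np.ndarray) -> TreeNode:
        node = TreeNode(
            leaf_mass=average_masses([self.masses[i] for i in idx]),
            inbag_ids=[int(self.ids[i]) for i in idx],
            leaf_id=self.next_leaf,
        )
        self.next_leaf += 1
        return node


def build_tree(
    X: np.ndarray,
    masses: Sequence[MassFunction],
    params: ForestParams,
    rng: np.random.Generator,
    ids: Optional[np.ndarray] = None,
) -> TreeNode:
    """Grow one evidential tree by recursive conflict-gain splitting."""
    X = np.asarray(X, dtype=float)
    if len(X) != len(masses) or len(X) == 0:
        raise ForestError("X and masses must align and be nonempty")
    if ids is None:
        ids = np.arange(len(X))
    return _TreeBuilder(X, masses, ids, params, rng).build(np.arange(len(X)), 0)


def tree_route(tree: TreeNode, x: np.ndarray) -> TreeNode:
    """Deterministic root-to-leaf descent; value == threshold goes left."""
    node = tree
    while not node.is_leaf:
        node = node.left if x[node.attr] <= node.thr else node.right
    return node


def route_batch(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Leaf ids for every row of X."""
    X = np.asarray(X, dtype=float)
    out = np.empty(len(X), dtype=np.int64)

    def descend(node: TreeNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.leaf_id
            return
        mask = X[idx, node.attr] <= node.thr
        if mask.any():
            descend(node.left, idx[mask])
        if (~mask).any():
            descend(node.right, idx[~mask])

    descend(tree, np.arange(len(X)))
    return out


def collect_leaves(tree: TreeNode) -> list[TreeNode]:
    """Leaves ordered by leaf_id."""
    leaves: list[TreeNode] = []

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            leaves.append(node)
        else:
            walk(node.left)
            walk(node.right)

    walk(tree)
    return sorted(leaves, key=lambda n: n.leaf_id)


@dataclass
class EvidentialForest:
    """Bagged evidential trees plus everything the co-leaf kernel needs."""

    trees: list[TreeNode]
    bootstrap_ids: list[np.ndarray]
    train_leaf_ids: np.ndarray  # W x m: leaf of every training sample per tree
    X_train: np.ndarray
    y: np.ndarray  # +1/-1
    frame: Frame
    params: ForestParams

    @property
    def W(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]


def fit_forest(X: np.ndarray, y: np.ndarray, params: ForestParams) -> EvidentialForest:
    """Fit W trees on bootstrap resamples (size m, with replacement).

    Per-tree generators are derived from (seed, tree index), so the forest is
    a pure function of (X, y, params). Crisp labels enter as categorical
    masses. After each tree is grown, *every* training sample — in-bag or
    not — is routed through it once; those leaf assignments back the kernel.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    m = len(X)
    if m < 2:
        raise ForestError("need at least two samples")
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ForestError("both classes must be present")
    frame = binary_frame()
    by_label = {lab: categorical_mass(frame, lab) for lab in (1, -1)}
    trees, boots, leaf_rows = [], [], []
    for w in range(params.W):
        rng = np.random.default_rng([params.seed, w])
        ids = rng.integers(0, m, size=m) if params.bootstrap else np.arange(m)
        masses = [by_label[int(y[i])] for i in ids]
        tree = build_tree(X[ids], masses, params, rng, ids=ids)
        trees.append(tree)
        boots.append(ids)
        leaf_rows.append(route_batch(tree, X))
    return EvidentialForest(
        trees=trees,
        bootstrap_ids=boots,
        train_leaf_ids=np.stack(leaf_rows),
        X_train=X.copy(),
        y=y.copy(),
        frame=frame,
        params=params,
    )


def _train_leaves(forest: EvidentialForest, X_train: Optional[np.ndarray]) -> np.ndarray:
    if X_train is None or X_train is forest.X_train:
        return forest.train_leaf_ids
    return np.stack([route_batch(t, np.asarray(X_train, float)) for t in forest.trees])


def kernel_matrix(
    forest: EvidentialForest,
    X: np.ndarray,
    X_train: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Co-leaf kernel between every row of X and every training sample."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    train_leaves = _train_leaves(forest, X_train)
    m_train = train_leaves.shape[1]
    K = np.zeros((len(X), m_train))
    for w, tree in enumerate(forest.trees):
        test_leaf = route_batch(tree, X)
        K += test_leaf[:, None] == train_leaves[w][None, :]
    return K / forest.W


def kernel_vector(
    forest: EvidentialForest,
    x: np.ndarray,
    X_train: Optional[np.ndarray] = None,
) -> np.ndarray:
    """K(x, x_i) for one sample x; entries in [0, 1]."""
    return kernel_matrix(forest, np.asarray(x, float)[None, :], X_train)[0]


def predict_value(
    forest: EvidentialForest,
    x: np.ndarray,
    X_train: Optional[np.ndarray] = None,
    y: Optional[np.ndarray] = None,
) -> float:
    """Kernel-weighted mean label F in [-1, 1]."""
    K = kernel_vector(forest, x, X_train)
    yy = forest.y if y is None else np.asarray(y)
    denom = K.sum()
    assert denom > 0, "co-leaf kernel degenerate: no training sample shares a leaf"
    return float((yy * K).sum() / denom)


def predict_label(
    forest: EvidentialForest,
    x: np.ndarray,
    X_train: Optional[np.ndarray] = None,
    y: Optional[np.ndarray] = None,
) -> int:
    """sgn(F) with the tie sgn(0) = +1."""
    return 1 if predict_value(forest, x, X_train, y) >= 0 else -1


def predict_value_batch(forest: EvidentialForest, X: np.ndarray) -> np.ndarray:
    K = kernel_matrix(forest, X)
    denom = K.sum(axis=1)
    assert np.all(denom > 0)
    return (K @ forest.y) / denom


def predict_label_batch(forest: EvidentialForest, X: np.ndarray) -> np.ndarray:
    return np.where(predict_value_batch(forest, X) >= 0, 1, -1)


def predict_mass_erf(forest: EvidentialForest, x: np.ndarray) -> MassFunction:
    """Kernel-free ablation: average the W leaf masses x reaches."""
    return average_masses(
        [tree_route(t, np.asarray(x, float)).leaf_mass for t in forest.trees]
    )


def erf_predict_batch(forest: EvidentialForest, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, BetP(positive)) for the kernel-free variant.

    Class = argmax pignistic; an exact tie goes to the first class of the
    frame (the positive class).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_sub = forest.frame.n_subsets
    acc = np.zeros((len(X), n_sub))
    for tree in forest.trees:
        leaves = collect_leaves(tree)
        leaf_masses = np.stack([lf.leaf_mass.masses for lf in leaves])
        acc += leaf_masses[route_batch(tree, X)]
    acc /= forest.W
    labels = np.empty(len(X), dtype=int)
    scores = np.empty(len(X))
    for i in range(len(X)):
        bet = pignistic(MassFunction(forest.frame, acc[i]))
        labels[i] = forest.frame.classes[int(np.argmax(bet))]
        scores[i] = bet[0]  # frame order: positive first
    return labels, scores


# ---------------------------------------------------------------------------
# serialization (nested dicts, JSON-ready)

def tree_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {
            "mass": node.leaf_mass.to_dict(),
            "inbag": node.inbag_ids,
            "leaf_id": node.leaf_id,
        }
    return {
        "attr": node.attr,
        "thr": node.thr,
        "left": tree_to_dict(node.left),
        "right": tree_to_dict(node.right),
    }


def tree_from_dict(d: dict, frame: Frame) -> TreeNode:
    if "mass" in d:
        return TreeNode(
            leaf_mass=MassFunction.from_dict(frame, d["mass"]),
            inbag_ids=list(d["inbag"]),
            leaf_id=int(d["leaf_id"]),
        )
    return TreeNode(
        attr=int(d["attr"]),
        thr=float(d["thr"]),
        left=tree_from_dict(d["left"], frame),
        right=tree_from_dict(d["right"], frame),
    )


def forest_to_dict(forest: EvidentialForest) -> dict:
    return {
        "trees": [tree_to_dict(t) for t in forest.trees],
        "bootstrap_ids": [ids.tolist() for ids in forest.bootstrap_ids],
        "train_leaf_ids": forest.train_leaf_ids.tolist(),
        "X_train": forest.X_train.tolist(),
        "y": forest.y.tolist(),
        "classes": list(forest.frame.classes),
        "params": forest.params.to_dict(),
    }


def forest_from_dict(d: dict) -> EvidentialForest:
    frame = Frame(tuple(d["classes"]))
    return EvidentialForest(
        trees=[tree_from_dict(t, frame) for t in d["trees"]],
        bootstrap_ids=[np.asarray(ids) for ids in d["bootstrap_ids"]],
        train_leaf_ids=np.asarray(d["train_leaf_ids"]),
        X_train=np.asarray(d["X_train"], dtype=float),
        y=np.asarray(d["y"], dtype=int),
        frame=frame,
        params=ForestParams(**d["params"]),
    )
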