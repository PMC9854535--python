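"""Second-order gradient-boosted regression trees for binary classification.

Each boosting round fits a regression tree to the first and second
derivatives (g_i, h_i) of the logistic loss at the current margins — the
second-order Taylor approximation of the training objective

    Obj = sum_i l(y_i, margin_i) + sum_trees [ gamma * T + (lambda/2) * sum w^2 ]

where T is the leaf count and w the leaf weights.  Dropping constants, the
per-leaf optimum is w* = -G/(H + lambda) with G, H the leaf's gradient and
hessian sums, and the gain of a split is

    1/2 [ G_L^2/(H_L+lam) + G_R^2/(H_R+lam) - (G_L+G_R)^2/(H_L+H_R+lam) ] - gamma.

Split finding is exact greedy: candidate thresholds are midpoints between
consecutive distinct feature values.  Per-feature sample orderings ("sorted
blocks") are computed once from X and reused by every round; the hot loop is
numba-compiled.  ``build_tree_naive`` is a slow, per-node re-sorting
reference implementation used as a correctness oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import expit


@dataclass(frozen=True)
class GradHess:
    g: np.ndarray
    h: np.ndarray


@dataclass(frozen=True)
class BoostConfig:
    num_rounds: int = 50
    max_depth: int = 3
    shrinkage: float = 0.1
    lam: float = 1.0  # L2 penalty on leaf weights
    gamma: float = 0.0  # per-leaf complexity penalty
    min_child_hessian: float = 0.0

    def __post_init__(self) -> None:
        if self.num_rounds < 1:
            raise ValueError("num_rounds must be >= 1")
        for name in ("max_depth", "shrinkage", "lam", "gamma", "min_child_hessian"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def logistic_grad_hess(y, margins) -> GradHess:
    """g = p - y, h = p(1-p) with p = sigmoid(margin)."""
    margins = np.asarray(margins, dtype=float)
    if not np.all(np.isfinite(margins)):
        raise ValueError("non-finite margins")
    p = expit(margins)
    y = np.asarray(y, dtype=float)
    return GradHess(g=p - y, h=p * (1.0 - p))


def leaf_weight(G: float, H: float, lam: float) -> float:
    """Minimizer of G*w + (H+lam)/2 * w^2."""
    if H + lam <= 0:
        raise ValueError("H + lambda must be positive")
    return -G / (H + lam)


def split_gain(G_L, H_L, G_R, H_R, lam, gamma) -> float:
    if H_L + lam <= 0 or H_R + lam <= 0:
        return -math.inf
    G, H = G_L + G_R, H_L + H_R
    return 0.5 * (G_L**2 / (H_L + lam) + G_R**2 / (H_R + lam) - G**2 / (H + lam)) - gamma


# ---------------------------------------------------------------------------
# Tree growth (numba hot path)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _grow(X, g, h, sorted_idx, max_depth, lam, gamma, min_child_h):  # pragma: no cover
    n, p = X.shape
    max_nodes = 2 ** (max_depth + 1) + 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes)
    pred = np.zeros(n)

    order = np.arange(n)
    member = np.zeros(n, np.bool_)

    # explicit DFS stack: (node, start, end, depth)
    st_node = np.empty(max_nodes, np.int64)
    st_lo = np.empty(max_nodes, np.int64)
    st_hi = np.empty(max_nodes, np.int64)
    st_dep = np.empty(max_nodes, np.int64)
    sp = 0
    st_node[0], st_lo[0], st_hi[0], st_dep[0] = 0, 0, n, 0
    sp = 1
    next_node = 1

    while sp > 0:
        sp -= 1
        node, lo, hi, dep = st_node[sp], st_lo[sp], st_hi[sp], st_dep[sp]
        m = hi - lo
        Gs = 0.0
        Hs = 0.0
        for k in range(lo, hi):
            Gs += g[order[k]]
            Hs += h[order[k]]

        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        if dep < max_depth and m >= 2 and Hs + lam > 0.0:
            for k in range(lo, hi):
                member[order[k]] = True
            parent = Gs * Gs / (Hs + lam)
            for f in range(p):
                Gl = 0.0
                Hl = 0.0
                prev_x = 0.0
                have_prev = False
                for k in range(n):
                    s = sorted_idx[k, f]
                    if not member[s]:
                        continue
                    xv = X[s, f]
                    if have_prev and xv > prev_x:
                        Gr = Gs - Gl
                        Hr = Hs - Hl
                        if (Hl >= min_child_h and Hr >= min_child_h
                                and Hl + lam > 0.0 and Hr + lam > 0.0):
                            gain = (
                                0.5 * (Gl * Gl / (Hl + lam) + Gr * Gr / (Hr + lam) - parent)
                                - gamma
                            )
                            if gain > best_gain:
                                best_gain = gain
                                best_f = f
                                best_thr = 0.5 * (prev_x + xv)
                    Gl += g[s]
                    Hl += h[s]
                    prev_x = xv
                    have_prev = True
            for k in range(lo, hi):
                member[order[k]] = False

        if best_f < 0:
            # a saturated node can underflow to Hs == 0; its pull is then nil
            value[node] = -Gs / (Hs + lam) if Hs + lam > 0.0 else 0.0
            for k in range(lo, hi):
                pred[order[k]] = value[node]
            continue

        feat[node] = best_f
        thr[node] = best_thr
        idx = order[lo:hi].copy()
        li = lo
        for s in idx:
            if X[s, best_f] <= best_thr:
                order[li] = s
                li += 1
        mid = li
        for s in idx:
            if X[s, best_f] > best_thr:
                order[li] = s
                li += 1
        lc, rc = next_node, next_node + 1
        next_node += 2
        left[node], right[node] = lc, rc
        st_node[sp], st_lo[sp], st_hi[sp], st_dep[sp] = lc, lo, mid, dep + 1
        sp += 1
        st_node[sp], st_lo[sp], st_hi[sp], st_dep[sp] = rc, mid, hi, dep + 1
        sp += 1

    return feat[:next_node], thr[:next_node], left[:next_node], right[:next_node], value[:next_node], pred


@njit(cache=True)
def _tree_margin(feat, thr, left, right, value, X, out):  # pragma: no cover
    for r in range(X.shape[0]):
        node = 0
        while feat[node] >= 0:
            if X[r, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[r] += value[node]


@dataclass
class RegressionTree:
    """Flat array representation: feature[i] == -1 marks a leaf."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature < 0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros(X.shape[0])
        _tree_margin(self.feature, self.threshold, self.left, self.right, self.value,
                     np.ascontiguousarray(X, dtype=np.float64), out)
        return out

    def to_dict(self, node: int = 0) -> dict:
        if self.feature[node] < 0:
            return {"leaf": float(self.value[node])}
        return {
            "feature": int(self.feature[node]),
            "threshold": float(self.threshold[node]),
            "left": self.to_dict(int(self.left[node])),
            "right": self.to_dict(int(self.right[node])),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        feature, threshold, left, right, value = [], [], [], [], []

        def walk(nd: dict) -> int:
            i = len(feature)
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(0.0)
            if "leaf" in nd:
                value[i] = float(nd["leaf"])
            else:
                feature[i] = int(nd["feature"])
                threshold[i] = float(nd["threshold"])
                left[i] = walk(nd["left"])
                right[i] = walk(nd["right"])
            return i

        walk(d)
        return cls(np.array(feature, np.int64), np.array(threshold),
                   np.array(left, np.int64), np.array(right, np.int64), np.array(value))


def sorted_blocks(X: np.ndarray) -> np.ndarray:
    """Per-feature stable sample orderings, computed once and reused."""
    return np.argsort(X, axis=0, kind="stable").astype(np.int64)


def build_tree(X, gh: GradHess, config: BoostConfig, blocks: np.ndarray | None = None):
    """Exact greedy depth-bounded tree on the given gradient statistics."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if blocks is None:
        blocks = sorted_blocks(X)
    feat, thr, left, right, value, pred = _grow(
        X, np.asarray(gh.g, float), np.asarray(gh.h, float), blocks,
        config.max_depth, config.lam, config.gamma, config.min_child_hessian,
    )
    return RegressionTree(feat, thr, left, right, value), pred


def build_tree_naive(X, gh: GradHess, config: BoostConfig) -> RegressionTree:
    """Reference builder: re-sorts node-local data at every node.

    Same arithmetic and tie-breaking as the block-based builder; used to
    check that pre-sorted blocks are a pure optimization.
    """
    X = np.asarray(X, dtype=float)
    g, h = np.asarray(gh.g, float), np.asarray(gh.h, float)
    feature, threshold, left, right, value = [], [], [], [], []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        return len(feature) - 1

    def grow(idx: np.ndarray, depth: int) -> int:
        node = new_node()
        Gs = 0.0
        Hs = 0.0
        for s in idx:
            Gs += g[s]
            Hs += h[s]
        best_gain, best_f, best_thr = 0.0, -1, 0.0
        if depth < config.max_depth and idx.size >= 2 and Hs + config.lam > 0.0:
            parent = Gs * Gs / (Hs + config.lam)
            for f in range(X.shape[1]):
                local = idx[np.argsort(X[idx, f], kind="stable")]
                Gl = 0.0
                Hl = 0.0
                prev_x, have_prev = 0.0, False
                for s in local:
                    xv = X[s, f]
                    if have_prev and xv > prev_x:
                        Gr, Hr = Gs - Gl, Hs - Hl
                        if (Hl >= config.min_child_hessian and Hr >= config.min_child_hessian
                                and Hl + config.lam > 0.0 and Hr + config.lam > 0.0):
                            gain = 0.5 * (Gl * Gl / (Hl + config.lam)
                                          + Gr * Gr / (Hr + config.lam) - parent) - config.gamma
                            if gain > best_gain:
                                best_gain, best_f, best_thr = gain, f, 0.5 * (prev_x + xv)
                    Gl += g[s]
                    Hl += h[s]
                    prev_x, have_prev = xv, True
        if best_f < 0:
            value[node] = -Gs / (Hs + config.lam) if Hs + config.lam > 0.0 else 0.0
            return node
        feature[node] = best_f
        threshold[node] = best_thr
        mask = X[idx, best_f] <= best_thr
        left[node] = grow(idx[mask], depth + 1)
        right[node] = grow(idx[~mask], depth + 1)
        return node

    grow(np.arange(X.shape[0]), 0)
    return RegressionTree(np.array(feature, np.int64), np.array(threshold),
                          np.array(left, np.int64), np.array(right, np.int64),
                          np.array(value))


# ---------------------------------------------------------------------------
# Boosting
# ---------------------------------------------------------------------------


@dataclass
class BoostedEnsemble:
    trees: list
    shrinkage: float
    base_margin: float
    n_features: int

    def predict_margin(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got shape {X.shape}")
        out = np.full(X.shape[0], self.base_margin)
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            _tree_margin(tree.feature, tree.threshold, tree.left, tree.right,
                         tree.value, X, acc)
        return out + self.shrinkage * acc

    def predict_proba(self, X) -> np.ndarray:
        return expit(self.predict_margin(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def to_json(self) -> str:
        return json.dumps({
            "shrinkage": self.shrinkage,
            "base_margin": self.base_margin,
            "n_features": self.n_features,
            "trees": [t.to_dict() for t in self.trees],
        })

    @classmethod
    def from_json(cls, text: str) -> "BoostedEnsemble":
        d = json.loads(text)
        return cls(trees=[RegressionTree.from_dict(t) for t in d["trees"]],
                   shrinkage=d["shrinkage"], base_margin=d["base_margin"],
                   n_features=d["n_features"])


def validate_table(X, y):
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains missing/non-finite values")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary {0,1}")
    return X, y.astype(float)


def fit(X, y, config: BoostConfig = BoostConfig(), seed: int = 0) -> BoostedEnsemble:
    """Train num_rounds trees on refreshed gradient statistics.

    Sorted blocks are computed once from X and reused in every round.  The
    initial margin is the log-odds of the class prior.  ``seed`` is accepted
    for interface uniformity; training itself is deterministic.
    """
    X, y = validate_table(X, y)
    ybar = float(np.mean(y))
    if ybar in (0.0, 1.0):
        raise ValueError("training table must contain both classes")
    base = math.log(ybar / (1.0 - ybar))
    blocks = sorted_blocks(X)
    margins = np.full(X.shape[0], base)
    trees = []
    for _ in range(config.num_rounds):
        gh = logistic_grad_hess(y, margins)
        tree, pred = build_tree(X, gh, config, blocks)
        margins += config.shrinkage * pred
        trees.append(tree)
    return BoostedEnsemble(trees=trees, shrinkage=config.shrinkage,
                           base_margin=base, n_features=X.shape[1])


def regularized_objective(ens: BoostedEnsemble, X, y, lam: float, gamma: float) -> float:
    """Training objective: total logloss + gamma*T + (lam/2)*sum(w^2) per tree."""
    margins = ens.predict_margin(X)
    y = np.asarray(y, float)
    # numerically stable logloss: log(1+exp(-|m|)) + max(m,0) - y*m
    loss = float(np.sum(np.logaddexp(0.0, margins) - y * margins))
    penalty = 0.0
    for t in ens.trees:
        leaves = t.value[t.feature < 0]
        penalty += gamma * leaves.size + 0.5 * lam * float(np.sum(leaves**2))
    return loss + penalty
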