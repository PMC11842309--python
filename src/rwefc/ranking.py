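"""C4.5-style decision-tree induction used as a feature-ranking method.

A binary tree over continuous features is grown top-down: at every node the
split (feature, threshold) maximizing the normalized information gain ratio
is chosen among all midpoints between consecutive distinct sorted values;
growth stops when a node is pure or no candidate has positive gain.  The tree
is then pruned with pessimistic (confidence-bound) error estimates, the C4.5
default confidence 0.25: a subtree collapses to a leaf whenever the parent's
estimated risk does not exceed its children's combined estimate.

Because features enter the tree in order of importance, the depth at which a
feature is first used ranks it: rank value = 1 / (1 + first-use depth),
min-max normalized so the root feature scores 1 and unused features 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

#: one-sided z for the C4.5 default pruning confidence CF = 0.25
_PRUNE_Z = float(norm.ppf(0.75))


@dataclass(frozen=True)
class SplitCandidate:
    feature: int
    threshold: float
    gain: float
    split_info: float
    gain_ratio: float


@dataclass
class TreeNode:
    prediction: str
    n: int
    n_errors: int
    depth: int
    feature: int | None = None
    threshold: float | None = None
    gain: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass(frozen=True)
class C45Config:
    prune: bool = True
    confidence: float = 0.25
    min_gain: float = 1e-12


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy (base 2) of a label sample."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def best_split(values: np.ndarray, labels: np.ndarray, feature: int = 0) -> SplitCandidate:
    """Best threshold for one continuous feature by exhaustive midpoint search.

    Ties in gain ratio resolve to the lower threshold.  A constant feature
    yields a zero-gain candidate with a NaN threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.size
    order = np.argsort(values, kind="stable")
    xs, ys = values[order], labels[order]
    boundaries = np.nonzero(xs[:-1] < xs[1:])[0]
    if boundaries.size == 0:
        return SplitCandidate(feature, float("nan"), 0.0, 0.0, 0.0)

    classes, y_idx = np.unique(ys, return_inverse=True)
    onehot = np.zeros((n, classes.size))
    onehot[np.arange(n), y_idx] = 1.0
    cum = np.cumsum(onehot, axis=0)

    n_left = (boundaries + 1).astype(float)
    n_right = n - n_left
    left_counts = cum[boundaries]
    right_counts = cum[-1] - left_counts

    def _h(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
        p = counts / totals[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return -terms.sum(axis=1)

    h_total = entropy(ys)
    gain = h_total - (n_left / n) * _h(left_counts, n_left) - (n_right / n) * _h(right_counts, n_right)
    pl, pr = n_left / n, n_right / n
    split_info = -(pl * np.log2(pl) + pr * np.log2(pr))
    ratio = np.where(split_info > 0, gain / np.maximum(split_info, 1e-300), 0.0)

    best = int(np.argmax(ratio))  # boundaries ascend, argmax takes the first -> lower threshold
    i = boundaries[best]
    return SplitCandidate(
        feature,
        float((xs[i] + xs[i + 1]) / 2.0),
        float(max(gain[best], 0.0)),
        float(split_info[best]),
        float(ratio[best]),
    )


def _majority(labels: np.ndarray) -> tuple[str, int]:
    classes, counts = np.unique(labels, return_counts=True)
    winner = int(np.argmax(counts))  # np.unique sorts -> canonical tie-break
    return str(classes[winner]), int(labels.size - counts[winner])


def _grow(X: np.ndarray, y: np.ndarray, depth: int, config: C45Config) -> TreeNode:
    prediction, n_errors = _majority(y)
    node = TreeNode(prediction=prediction, n=int(y.size), n_errors=n_errors, depth=depth)
    if n_errors == 0:
        return node
    candidates = [best_split(X[:, j], y, feature=j) for j in range(X.shape[1])]
    best = max(
        candidates, key=lambda c: (c.gain_ratio, -c.feature)
    )  # tie across features -> lower index
    if best.gain <= config.min_gain or not np.isfinite(best.threshold):
        return node
    mask = X[:, best.feature] <= best.threshold
    node.feature = best.feature
    node.threshold = best.threshold
    node.gain = best.gain
    node.left = _grow(X[mask], y[mask], depth + 1, config)
    node.right = _grow(X[~mask], y[~mask], depth + 1, config)
    return node


def _pessimistic_errors(n_errors: int, n: int, z: float = _PRUNE_Z) -> float:
    """Upper confidence bound on the error count of a leaf covering n samples."""
    if n == 0:
        return 0.0
    f = n_errors / n
    bound = (f + z * z / (2 * n) + z * np.sqrt(f * (1 - f) / n + z * z / (4 * n * n))) / (
        1 + z * z / n
    )
    return float(bound * n)


def _prune(node: TreeNode) -> float:
    """Bottom-up pessimistic pruning; returns the subtree's estimated errors."""
    if node.is_leaf:
        return _pessimistic_errors(node.n_errors, node.n)
    subtree = _prune(node.left) + _prune(node.right)
    as_leaf = _pessimistic_errors(node.n_errors, node.n)
    if as_leaf <= subtree:
        node.feature = None
        node.threshold = None
        node.left = node.right = None
        return as_leaf
    return subtree


def build_tree(
    X: np.ndarray | pd.DataFrame, labels: np.ndarray, config: C45Config | None = None
) -> TreeNode:
    """Grow (and optionally prune) a C4.5 gain-ratio tree; deterministic."""
    config = config or C45Config()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) matching labels")
    tree = _grow(X, y, depth=0, config=config)
    if config.prune:
        _prune(tree)
    return tree


@dataclass(frozen=True)
class RankedFeatures:
    """Descending (feature index, normalized rank value) pairs; features never
    used by the tree carry rank 0 and are omitted from ``entries``."""

    entries: tuple[tuple[int, float], ...]
    n_features: int

    @property
    def values(self) -> np.ndarray:
        out = np.zeros(self.n_features)
        for idx, val in self.entries:
            out[idx] = val
        return out


def rank_features(tree: TreeNode, n_features: int) -> RankedFeatures:
    """Rank features by first-use depth (root = 1 after normalization), ties
    broken by total sample-weighted gain contribution."""
    first_depth: dict[int, int] = {}
    total_gain: dict[int, float] = {}

    def walk(node: TreeNode | None) -> None:
        if node is None or node.is_leaf:
            return
        f = node.feature
        first_depth[f] = min(first_depth.get(f, node.depth), node.depth)
        total_gain[f] = total_gain.get(f, 0.0) + node.gain * node.n
        walk(node.left)
        walk(node.right)

    walk(tree)
    if not first_depth:
        return RankedFeatures(entries=(), n_features=n_features)
    raw = {f: 1.0 / (1.0 + d) for f, d in first_depth.items()}
    top = max(raw.values())  # min over all features is 0 (unused), so divide by max
    ordered = sorted(raw, key=lambda f: (-raw[f] / top, -total_gain[f], f))
    return RankedFeatures(
        entries=tuple((f, raw[f] / top) for f in ordered), n_features=n_features
    )


def ranking_table(ranked: RankedFeatures, feature_names: list[str]) -> pd.DataFrame:
    """Ranking as a DataFrame (feature id, name, rank value), descending."""
    rows = [
        {"feature_id": f"f{idx + 1:03d}", "name": feature_names[idx], "rank_value": val}
        for idx, val in ranked.entries
    ]
    return pd.DataFrame(rows, columns=["feature_id", "name", "rank_value"])


def plot_ranking(table: pd.DataFrame, path, title: str = "") -> None:
    """Horizontal bar plot of ranked features (matplotlib, optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(table))))
    ax.barh(table["name"][::-1], table["rank_value"][::-1])
    ax.set_xlabel("normalized rank value")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
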