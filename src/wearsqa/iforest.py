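"""Isolation forest, implemented from scratch.

The quality axis of the pipeline is the isolation-forest anomaly score:
an ensemble of randomly grown binary trees, each built on a small
subsample, isolates anomalous feature vectors in few splits.  The score
of a probe x is

    s(x) = 2 ** (-E[h(x)] / c(psi))

where h(x) is the path length to the external node reached in a tree
(plus the average-path adjustment c(m) for the m points terminating
there), E[.] averages over trees, and c(psi) = 2 H(psi-1) - 2(psi-1)/psi
is the expected unsuccessful-search path length of a binary search tree
on psi points.  Scores near 1 indicate anomalies (poor quality), scores
well below 0.5 indicate normal signal.

Tree-growth contract (relied on by the equivalence tests): at each node
a split feature is drawn uniformly at random among features whose values
in the node are not all equal (``rng.integers(n_valid)`` indexing the
ascending list of valid feature indices), then a split value uniformly
in that feature's open node range (``rng.uniform(min, max)``).  Nodes
terminate when the height limit ceil(log2 psi) is reached, at size <= 1,
or when no feature admits a valid split.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "average_path_normalizer_c",
    "IsolationTree",
    "IsolationForestModel",
    "fit",
    "path_length",
    "anomaly_score",
]

_EULER_GAMMA = 0.5772156649015329


def average_path_normalizer_c(n: int) -> float:
    """Expected unsuccessful-search path length c(n) of a BST on n points.

    c(0) = c(1) = 0; for n >= 2, c(n) = 2 H(n-1) - 2 (n-1)/n, with exact
    harmonic numbers up to n = 1000 and the ln + gamma approximation
    above.
    """
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    if n <= 1:
        return 0.0
    if n <= 1000:
        h = float(np.sum(1.0 / np.arange(1, n)))
    else:
        h = math.log(n - 1) + _EULER_GAMMA
    return 2.0 * h - 2.0 * (n - 1) / n


@dataclass
class IsolationTree:
    """One isolation tree in flat-array form.

    ``feature[i] < 0`` marks node i external; ``size[i]`` is the number
    of subsample points that terminated there.
    """

    feature: np.ndarray   # int, -1 for external nodes
    threshold: np.ndarray
    left: np.ndarray      # child indices, -1 for external
    right: np.ndarray
    size: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)


def _grow_tree(X: np.ndarray, rng: np.random.Generator, height_limit: int) -> IsolationTree:
    feature, threshold, left, right, size = [], [], [], [], []

    def build(rows: np.ndarray, depth: int) -> int:
        idx = len(feature)
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        size.append(len(rows))
        if depth >= height_limit or len(rows) <= 1:
            return idx
        sub = X[rows]
        mins = sub.min(axis=0)
        maxs = sub.max(axis=0)
        valid = np.flatnonzero(maxs > mins)
        if len(valid) == 0:
            return idx
        f = int(valid[rng.integers(len(valid))])
        split = float(rng.uniform(mins[f], maxs[f]))
        mask = sub[:, f] < split
        feature[idx] = f
        threshold[idx] = split
        left[idx] = build(rows[mask], depth + 1)
        right[idx] = build(rows[~mask], depth + 1)
        return idx

    build(np.arange(len(X)), 0)
    return IsolationTree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        size=np.asarray(size, dtype=np.int64),
    )


@dataclass
class IsolationForestModel:
    """Fitted ensemble plus metadata.

    ``contamination`` is stored as metadata only: grades come from the
    calibrated score thresholds, never from a native score offset.
    ``calibration`` optionally holds the fitted thresholds so one JSON
    artifact carries everything scoring needs.
    """

    trees: list
    psi: int
    n_trees: int
    contamination: float = 0.05
    feature_names: tuple = ()
    seed: int = 0
    calibration: dict | None = None
    schema_version: int = 1
    _c_psi: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        self._c_psi = average_path_normalizer_c(self.psi)

    @property
    def n_features(self) -> int:
        return len(self.feature_names) if self.feature_names else -1

    # -- scoring -----------------------------------------------------------

    def mean_path_length(self, X) -> np.ndarray:
        """E[h(x)] over the ensemble for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not self.trees:
            raise RuntimeError("model has no trees (unfitted)")
        total = np.zeros(len(X))
        for tree in self.trees:
            _accumulate_paths(tree, X, total)
        return total / len(self.trees)

    def score(self, X) -> np.ndarray:
        """Anomaly scores in (0, 1); higher = more anomalous."""
        eh = self.mean_path_length(X)
        return 2.0 ** (-eh / self._c_psi)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "schema_version": self.schema_version,
            "params": {
                "psi": self.psi,
                "n_trees": self.n_trees,
                "contamination": self.contamination,
                "seed": self.seed,
            },
            "feature_names": list(self.feature_names),
            "calibration": self.calibration,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "size": t.size.tolist(),
                }
                for t in self.trees
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "IsolationForestModel":
        payload = json.loads(text)
        if payload.get("schema_version") != 1:
            raise ValueError(f"unsupported model schema {payload.get('schema_version')!r}")
        trees = [
            IsolationTree(
                feature=np.asarray(t["feature"], dtype=np.int32),
                threshold=np.asarray(t["threshold"], dtype=float),
                left=np.asarray(t["left"], dtype=np.int32),
                right=np.asarray(t["right"], dtype=np.int32),
                size=np.asarray(t["size"], dtype=np.int64),
            )
            for t in payload["trees"]
        ]
        params = payload["params"]
        return cls(
            trees=trees,
            psi=params["psi"],
            n_trees=params["n_trees"],
            contamination=params["contamination"],
            seed=params["seed"],
            feature_names=tuple(payload["feature_names"]),
            calibration=payload.get("calibration"),
        )


def _accumulate_paths(tree: IsolationTree, X: np.ndarray, out: np.ndarray) -> None:
    """Add every probe's path length in one tree to ``out`` (vectorized
    breadth-first routing of index sets through the node arrays)."""
    c_cache = {}
    stack = [(0, np.arange(len(X)), 0)]
    while stack:
        node, idx, depth = stack.pop()
        f = tree.feature[node]
        if f < 0:
            m = int(tree.size[node])
            if m not in c_cache:
                c_cache[m] = average_path_normalizer_c(m)
            out[idx] += depth + c_cache[m]
            continue
        mask = X[idx, f] < tree.threshold[node]
        l_idx, r_idx = idx[mask], idx[~mask]
        if len(l_idx):
            stack.append((int(tree.left[node]), l_idx, depth + 1))
        if len(r_idx):
            stack.append((int(tree.right[node]), r_idx, depth + 1))


def fit(
    X,
    n_trees: int = 2000,
    psi: int = 256,
    contamination: float = 0.05,
    seed: int = 0,
    feature_names: tuple = (),
) -> IsolationForestModel:
    """Grow the ensemble: each tree on an independent uniform subsample
    of ``psi`` rows with height limit ceil(log2 psi)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    n = len(X)
    if n < psi:
        warnings.warn(f"only {n} rows available; shrinking psi from {psi}")
        psi = n
    if psi < 1:
        raise ValueError("need at least one row")
    height_limit = max(1, math.ceil(math.log2(max(psi, 2))))
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        rows = rng.choice(n, size=psi, replace=False)
        trees.append(_grow_tree(X[rows], rng, height_limit))
    return IsolationForestModel(
        trees=trees, psi=psi, n_trees=n_trees, contamination=contamination,
        seed=seed, feature_names=tuple(feature_names),
    )


def path_length(tree: IsolationTree, x) -> float:
    """Path length of a single probe in a single tree: edges traversed
    plus c(size) at the reached external node."""
    x = np.asarray(x, dtype=float)
    node, depth = 0, 0
    while True:
        f = tree.feature[node]
        if f < 0:
            return depth + average_path_normalizer_c(int(tree.size[node]))
        if f >= len(x):
            raise ValueError("probe arity smaller than tree's split feature index")
        node = int(tree.left[node] if x[f] < tree.threshold[node] else tree.right[node])
        depth += 1


def anomaly_score(model: IsolationForestModel, x) -> float:
    """Anomaly score of a single probe."""
    return float(model.score(np.atleast_2d(x))[0])
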