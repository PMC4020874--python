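"""Per-eye response pattern, dynamic features w(1)-w(3) and CART classification.

Each eye gets an individual response *pattern*

    L_V(n, i) = L_TO(N/2, i) + opening(L_TR)(n, i),

i.e. the centre-line eyeball displacement plus the slow part of the
corneal deflection.  The *pattern error* L_Δ = L_T - L_V then contains
exactly what the pattern does not explain: the fast corneal oscillation
and the across-image residue of the eyeball motion.  Three scalar
features summarise the dynamics of one eye:

w(1)  maximum of L_Δ over (n, i), px -- how far the observed response
      departs from its own pattern, dominated by the eyeball deflection;
w(2)  maximum FFT magnitude of the border signals over harmonics 7-15
      (216-464 Hz at 140 frames / 231 µs), the amplitude of the rapid
      corneal oscillation;
w(3)  duration of the rapid oscillation: the frame span over which the
      envelope of the region-II component stays above 80 % of its peak.

Deformation classes 1-4 are assigned by an unpruned CART decision tree
(greedy binary splits minimising Gini impurity) trained on labelled
feature vectors; with only a handful of training eyes per class, pruning
would discard real structure, so the tree grows until its leaves are pure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_sequences import DimensionError, Map2D
from .fast_dynamics import SE2_DEFAULT, grayscale_opening

__all__ = [
    "W2_HARMONIC_RANGE",
    "REFERENCE_EYES",
    "reference_feature_table",
    "FeatureVector",
    "build_pattern",
    "pattern_error",
    "feature_w1",
    "feature_w2",
    "feature_w3",
    "gini",
    "TreeNode",
    "DecisionTree",
    "train_cart",
    "classify",
]

#: Inclusive harmonic-number window of the w(2) spectral maximum.  At 140
#: frames and 231 µs per frame, harmonics 7..15 cover 216.5-463.8 Hz, the
#: measured band of rapid corneal oscillation (nominally 150-500 Hz, with
#: the region-II content sitting above 200 Hz).
W2_HARMONIC_RANGE = (7, 15)

#: Reference feature vectors (w1, w2, w3) of ten measured right eyes and
#: their deformation classes, as published for this feature set.  They are
#: the canonical small training set for the default 4-class tree.
REFERENCE_EYES: tuple[tuple[float, float, float, int], ...] = (
    (37.2, 2.5, 17.0, 1),
    (15.0, 3.2, 16.8, 2),
    (13.1, 4.3, 22.0, 2),
    (25.6, 5.0, 19.5, 2),
    (20.2, 28.6, 28.6, 3),
    (13.9, 16.3, 30.6, 3),
    (38.2, 3.2, 24.2, 1),
    (48.4, 20.3, 25.1, 4),
    (21.0, 25.5, 25.6, 3),
    (20.7, 5.2, 23.9, 2),
)


def reference_feature_table() -> pd.DataFrame:
    """The ten reference eyes as a DataFrame (columns w1, w2, w3, class)."""
    return pd.DataFrame(list(REFERENCE_EYES), columns=["w1", "w2", "w3", "class"])


@dataclass
class FeatureVector:
    """Dynamic features of one eye: w1/w2 amplitudes and the w3 duration.

    ``w1`` and ``w3`` are in pixels and frames respectively; ``w2`` is in
    raw FFT-magnitude units (pixel·frames).  ``w3_ms(dt)`` converts the
    duration to milliseconds for a given frame interval.
    """

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        if self.w2 < 0 or self.w3 < 0:
            raise ValueError("w2 and w3 are magnitudes/durations and cannot be negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3], dtype=float)

    def w3_ms(self, frame_interval_s: float) -> float:
        return self.w3 * frame_interval_s * 1e3


# ---------------------------------------------------------------------------
# pattern and features
# ---------------------------------------------------------------------------


def build_pattern(L_TO: Map2D, L_TR: Map2D, se: tuple[int, int] = SE2_DEFAULT) -> Map2D:
    """Per-eye response pattern: centre-line eyeball motion + slow deflection."""
    if L_TO.shape != L_TR.shape:
        raise DimensionError("L_TO and L_TR must share one shape")
    centre = L_TO.values[L_TO.shape[0] // 2, :]
    slow = grayscale_opening(L_TR, se).values
    return Map2D(centre[None, :] + slow, "pattern")


def pattern_error(L_T: Map2D, L_V: Map2D) -> Map2D:
    """Elementwise deviation of the observed response from the pattern."""
    if L_T.shape != L_V.shape:
        raise DimensionError(f"shape mismatch: {L_T.shape} vs {L_V.shape}")
    return Map2D(L_T.values - L_V.values, "error")


def feature_w1(L_delta: Map2D) -> float:
    """Maximum amplitude of the pattern error over (n, i), px."""
    return float(np.nanmax(L_delta.values))


def feature_w2(
    F_QL: np.ndarray,
    F_QR: np.ndarray,
    harmonics: tuple[int, int] = W2_HARMONIC_RANGE,
) -> float:
    """Maximum of both border spectra over the rapid-oscillation window.

    ``harmonics`` is an inclusive harmonic-number range (DC = harmonic 0);
    spectra must extend at least that far.
    """
    lo, hi = harmonics
    F_QL = np.asarray(F_QL, dtype=float)
    F_QR = np.asarray(F_QR, dtype=float)
    if min(F_QL.size, F_QR.size) <= hi:
        raise DimensionError(f"spectra must have more than {hi} harmonics")
    return float(max(F_QL[lo : hi + 1].max(), F_QR[lo : hi + 1].max()))


def feature_w3(
    comp_ii_left: np.ndarray,
    comp_ii_right: np.ndarray,
    threshold: float = 0.8,
) -> float:
    """Duration of the rapid oscillation, frames.

    The envelope e(i) = max(|comp_II_L(i)|, |comp_II_R(i)|) is thresholded
    at ``threshold`` times its peak; w3 counts the frames from the first
    to the last super-threshold sample inclusive.  An all-zero envelope
    yields 0.
    """
    env = np.maximum(np.abs(np.asarray(comp_ii_left)), np.abs(np.asarray(comp_ii_right)))
    peak = env.max() if env.size else 0.0
    if peak <= 0:
        return 0.0
    above = np.flatnonzero(env >= threshold * peak)
    return float(above[-1] - above[0] + 1)


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("w1", "w2", "w3")


def gini(labels: np.ndarray) -> float:
    """Gini impurity 1 - sum p^2 of a label multiset."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - (p**2).sum())


@dataclass
class TreeNode:
    """One node of the decision tree.

    Internal nodes route a sample left when ``x[feature] <= threshold``;
    leaves carry the assigned label and the training class counts from
    which their purity follows.
    """

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: int | None = None
    counts: dict[int, int] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def purity(self) -> float:
        total = sum(self.counts.values()) if self.counts else 0
        if not total:
            return 1.0
        return max(self.counts.values()) / total  # type: ignore[union-attr]


@dataclass
class DecisionTree:
    """Unpruned binary CART over (w1, w2, w3)."""

    root: TreeNode
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict(self, x: np.ndarray | FeatureVector) -> int:
        if isinstance(x, FeatureVector):
            x = x.as_array()
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return int(node.label)  # type: ignore[arg-type]

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def n_leaves(self) -> int:
        def _n(node: TreeNode) -> int:
            if node.is_leaf:
                return 1
            return _n(node.left) + _n(node.right)

        return _n(self.root)

    # -- JSON serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        def _node(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"label": node.label, "counts": {str(k): v for k, v in node.counts.items()}}
            return {
                "feature": node.feature,
                "feature_name": self.feature_names[node.feature],
                "threshold": node.threshold,
                "left": _node(node.left),
                "right": _node(node.right),
            }

        return {"feature_names": list(self.feature_names), "root": _node(self.root)}

    @classmethod
    def from_dict(cls, payload: dict) -> "DecisionTree":
        def _node(d: dict) -> TreeNode:
            if "label" in d:
                return TreeNode(label=int(d["label"]), counts={int(k): v for k, v in d["counts"].items()})
            return TreeNode(
                feature=int(d["feature"]),
                threshold=float(d["threshold"]),
                left=_node(d["left"]),
                right=_node(d["right"]),
            )

        return cls(root=_node(payload["root"]), feature_names=tuple(payload["feature_names"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecisionTree":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _leaf(labels: np.ndarray) -> TreeNode:
    values, counts = np.unique(labels, return_counts=True)
    # majority label; ties break toward the lowest label
    label = int(values[np.argmax(counts)])
    return TreeNode(label=label, counts={int(v): int(c) for v, c in zip(values, counts)})


def _best_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float] | None:
    """Best (feature, threshold) by weighted Gini; None if nothing splits.

    Candidate thresholds are midpoints between consecutive sorted unique
    values of each feature.  Ties break toward the lowest feature index,
    then the lowest threshold.
    """
    n = y.size
    best: tuple[float, int, float] | None = None  # (impurity, feature, threshold)
    for f in range(X.shape[1]):
        uniques = np.unique(X[:, f])
        if uniques.size < 2:
            continue
        for thr in (uniques[:-1] + uniques[1:]) / 2.0:
            mask = X[:, f] <= thr
            n_left = int(mask.sum())
            impurity = (n_left * gini(y[mask]) + (n - n_left) * gini(y[~mask])) / n
            key = (impurity, f, float(thr))
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[1], best[2]


def _grow(X: np.ndarray, y: np.ndarray) -> TreeNode:
    if np.unique(y).size == 1:
        return _leaf(y)
    split = _best_split(X, y)
    if split is None:
        # conflicting duplicates: identical feature vectors, different labels
        return _leaf(y)
    f, thr = split
    mask = X[:, f] <= thr
    return TreeNode(feature=f, threshold=thr, left=_grow(X[mask], y[mask]), right=_grow(X[~mask], y[~mask]))


def _as_matrix(features: Sequence[FeatureVector] | np.ndarray | pd.DataFrame) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    if len(features) and isinstance(features[0], FeatureVector):  # type: ignore[index]
        return np.array([fv.as_array() for fv in features])
    return np.asarray(features, dtype=float)


def train_cart(
    features: Sequence[FeatureVector] | np.ndarray | pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
) -> DecisionTree:
    """Grow an unpruned Gini CART on labelled feature vectors.

    Recursion continues until every leaf is pure or holds only conflicting
    duplicate vectors (such leaves keep the majority label and their
    impurity is visible in ``counts``).  No minimum node size is imposed.
    Entirely deterministic: split ties break toward the lowest feature
    index, then the lowest threshold.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise DimensionError("features must form a 2-D matrix")
    if X.shape[0] != y.size:
        raise DimensionError(f"{X.shape[0]} feature rows vs {y.size} labels")
    if X.shape[0] < 1:
        raise ValueError("training needs at least one sample")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    return DecisionTree(root=_grow(X, y))


def classify(tree: DecisionTree, fv: FeatureVector | np.ndarray) -> int:
    """Route one feature vector through the tree and return its class label."""
    return tree.predict(fv)
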