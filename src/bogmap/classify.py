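"""Random-forest land-use classification of the 12-band feature stack.

Training pixels are sampled from labelled polygons by pixel-centre
containment; a bagged ensemble of Gini decision trees (20 trees, 3 of the 12
features considered per split by default) is fitted with scikit-learn; the
map prediction is an explicit majority vote over the trees with ties broken
by the lowest class code.  Trees are exported to plain arrays at training
time so the model serialises to documented JSON and prediction is identical
whether the model came from training or from disk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from sklearn.ensemble import RandomForestClassifier

from .compositing import CompositeImage
from .lucip import FEATURE_NAMES, N_FEATURES, NODATA, class_name
from .synthetic import ClassMap, TrainingPolygons


@dataclass
class TrainingSet:
    """Feature matrix (rows = pixels, columns = the 12 stack features) + labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one label per row")
        if np.isnan(self.X).any():
            raise ValueError("training features must not contain nodata")

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.y, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}


@dataclass
class _Tree:
    """Flat array encoding of one decision tree (sklearn node layout)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int64)
        while True:
            feat = self.feature[node]
            leaf = feat < 0
            if leaf.all():
                return self.leaf_class[node]
            col = np.where(leaf, 0, feat)
            left = X[np.arange(len(X)), col] <= self.threshold[node]
            nxt = np.where(left, self.children_left[node], self.children_right[node])
            node = np.where(leaf, node, nxt)


@dataclass
class ForestModel:
    """Trained ensemble: flat tree arrays + metadata, JSON-serialisable."""

    n_trees: int
    variables_per_split: int
    seed: int
    classes: np.ndarray
    trees: list[_Tree]
    feature_importances: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def vote(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) vote counts; rows sum to n_trees."""
        code_to_col = {int(c): i for i, c in enumerate(self.classes)}
        votes = np.zeros((len(X), len(self.classes)), dtype=np.int32)
        for tree in self.trees:
            pred = tree.predict(X)
            cols = np.vectorize(code_to_col.__getitem__, otypes=[np.int64])(pred)
            votes[np.arange(len(X)), cols] += 1
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote class per row; ties go to the lowest class code."""
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature count mismatch: model expects {self.n_features}, "
                f"got {X.shape[1]}"
            )
        votes = self.vote(X)
        # classes are stored sorted ascending, so argmax's first-wins rule
        # breaks ties toward the lowest class code
        return self.classes[np.argmax(votes, axis=1)]

    def to_json(self) -> str:
        obj = {
            "format": "bogmap-forest-v1",
            "n_trees": self.n_trees,
            "variables_per_split": self.variables_per_split,
            "seed": self.seed,
            "classes": [int(c) for c in self.classes],
            "feature_names": self.feature_names,
            "feature_importances": [float(v) for v in self.feature_importances],
            "trees": [
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "leaf_class": t.leaf_class.tolist(),
                }
                for t in self.trees
            ],
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        obj = json.loads(text)
        if obj.get("format") != "bogmap-forest-v1":
            raise ValueError("not a bogmap forest model JSON")
        trees = [
            _Tree(
                np.asarray(t["children_left"], dtype=np.int64),
                np.asarray(t["children_right"], dtype=np.int64),
                np.asarray(t["feature"], dtype=np.int64),
                np.asarray(t["threshold"], dtype=np.float64),
                np.asarray(t["leaf_class"], dtype=np.int64),
            )
            for t in obj["trees"]
        ]
        return cls(
            n_trees=int(obj["n_trees"]),
            variables_per_split=int(obj["variables_per_split"]),
            seed=int(obj["seed"]),
            classes=np.asarray(obj["classes"], dtype=np.int64),
            trees=trees,
            feature_importances=np.asarray(obj["feature_importances"], dtype=float),
            feature_names=list(obj["feature_names"]),
        )


@dataclass
class ImportanceRanking:
    """Normalised per-feature importance scores with rank order."""

    feature_names: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("importance scores must be non-negative")

    @property
    def ranking(self) -> list[str]:
        """Feature names from most to least important (stable tie order)."""
        order = np.argsort(-self.scores, kind="stable")
        return [self.feature_names[i] for i in order]


def extract_training_pixels(
    stack: CompositeImage, polygons: TrainingPolygons
) -> TrainingSet:
    """One training row per non-nodata pixel whose centre lies in a polygon.

    Pixel (r, c) has its centre at (x, y) = (c + 0.5, r + 0.5).  Rows with
    any nodata feature are dropped; a class left with zero rows raises a
    training error naming the class.
    """
    feats = stack.features
    h, w = stack.shape
    rows_out: list[np.ndarray] = []
    labels_out: list[np.ndarray] = []
    requested = set()
    for poly, code in polygons.items:
        requested.add(code)
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(0, int(math.floor(minx))), min(w, int(math.ceil(maxx)))
        r0, r1 = max(0, int(math.floor(miny))), min(h, int(math.ceil(maxy)))
        if c1 <= c0 or r1 <= r0:
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = shapely.contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
        if not inside.any():
            continue
        r_in, c_in = rr.ravel()[inside], cc.ravel()[inside]
        block = feats[:, r_in, c_in].T  # (n, 12)
        ok = ~np.isnan(block).any(axis=1)
        if ok.any():
            rows_out.append(block[ok])
            labels_out.append(np.full(int(ok.sum()), code, dtype=np.int64))
    if not rows_out:
        raise ValueError("no training pixels extracted from any polygon")
    X = np.vstack(rows_out)
    y = np.concatenate(labels_out)
    present = set(np.unique(y).tolist())
    missing = sorted(requested - present)
    if missing:
        names = ", ".join(class_name(c) for c in missing)
        raise ValueError(f"no training pixels extracted for class(es): {names}")
    return TrainingSet(X, y)


def resolve_variables_per_split(spec: int | str, n_features: int) -> int:
    """Resolve the per-split feature budget; ``"sqrt"`` -> floor(sqrt(n))."""
    if spec == "sqrt":
        return max(1, int(math.floor(math.sqrt(n_features))))
    m = int(spec)
    if not 1 <= m <= n_features:
        raise ValueError(f"variables_per_split must lie in [1, {n_features}]")
    return m


def train_forest(
    data: TrainingSet,
    n_trees: int = 20,
    variables_per_split: int | str = "sqrt",
    seed: int = 0,
) -> ForestModel:
    """Fit the bagged tree ensemble and export it to flat arrays.

    Each tree is grown on a bootstrap resample of the rows (sample size =
    training size), splitting on the best of ``variables_per_split``
    randomly drawn features by Gini impurity, to unlimited depth with
    minimum leaf size 1.  Identical data + seed give an identical model.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    classes = np.unique(data.y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    m = resolve_variables_per_split(variables_per_split, data.X.shape[1])
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=m,
        criterion="gini",
        bootstrap=True,
        min_samples_leaf=1,
        max_depth=None,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(data.X, data.y)
    trees = []
    for est in rf.estimators_:
        t = est.tree_
        leaf_class = rf.classes_[np.argmax(t.value[:, 0, :], axis=1)]
        trees.append(
            _Tree(
                t.children_left.astype(np.int64).copy(),
                t.children_right.astype(np.int64).copy(),
                t.feature.astype(np.int64).copy(),
                t.threshold.astype(np.float64).copy(),
                leaf_class.astype(np.int64),
            )
        )
    return ForestModel(
        n_trees=n_trees,
        variables_per_split=m,
        seed=seed,
        classes=classes.astype(np.int64),
        trees=trees,
        feature_importances=rf.feature_importances_.copy(),
        feature_names=list(data.feature_names),
    )


def predict_map(model: ForestModel, stack: CompositeImage) -> ClassMap:
    """Majority-vote prediction over the stack; nodata pixels stay nodata."""
    feats = stack.features
    if feats.shape[0] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features}, "
            f"stack has {feats.shape[0]}"
        )
    h, w = stack.shape
    flat = feats.reshape(model.n_features, -1).T
    valid = ~np.isnan(flat).any(axis=1)
    out = np.full(h * w, NODATA, dtype=np.int16)
    if valid.any():
        out[valid] = model.predict(flat[valid])
    return ClassMap(out.reshape(h, w), pixel_size_ha=stack.pixel_size_ha)


def variable_importance(
    model: ForestModel, data: TrainingSet | None = None
) -> ImportanceRanking:
    """Mean-decrease-in-impurity importances, normalised to sum to 1.

    MDI is accumulated over the training splits and stored on the model, so
    ``data`` is not consulted; it is accepted so callers can keep the
    training set alongside the model in one call signature.
    """
    scores = np.asarray(model.feature_importances, dtype=float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    return ImportanceRanking(list(model.feature_names), scores)
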