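"""Random-forest voxel classifier over multi-scale multimodal features.

A forest of decision trees is fit on annotated feature rows and applied
voxel-wise to dense feature stacks.  Label decisions use hard per-tree votes
with ties broken toward the lower class code, so the fraction maps returned by
:func:`predict_class_fractions` are exactly consistent with
:func:`predict_labels`.  Row order never matters: tables are canonically
sorted (specimen, z, y, x, label) before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureStack, SampleTable
from .phantom import BACKGROUND, CLASS_NAMES


@dataclass(frozen=True)
class Hyperparams:
    """Forest hyperparameters (Weka-era trainable-segmentation defaults)."""

    n_trees: int = 200
    max_features: object = "sqrt"   # features considered per split
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class TrainedModel:
    """A fitted forest with its channel schema and training provenance."""

    forest: RandomForestClassifier
    channels: list[str]
    classes: np.ndarray           # sorted class codes seen in training
    hyperparams: Hyperparams
    seed: int
    metadata: dict = field(default_factory=dict)

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Serialize to a single portable file (schema + hyperparameters)."""
        import joblib

        joblib.dump({"format_version": self.FORMAT_VERSION, "forest": self.forest,
                     "channels": self.channels, "classes": self.classes,
                     "hyperparams": self.hyperparams, "seed": self.seed,
                     "metadata": self.metadata}, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import joblib

        payload = joblib.load(path)
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model file version {payload.get('format_version')}")
        return cls(forest=payload["forest"], channels=payload["channels"],
                   classes=payload["classes"], hyperparams=payload["hyperparams"],
                   seed=payload["seed"], metadata=payload["metadata"])

    def check_schema(self, channels: Sequence[str]) -> None:
        if list(channels) != list(self.channels):
            missing = [c for c in self.channels if c not in channels]
            extra = [c for c in channels if c not in self.channels]
            raise ValueError(
                f"feature schema mismatch: missing channels {missing}, extra channels {extra}"
            )

    # -- vote machinery ----------------------------------------------------

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) per-class fractions of hard tree votes."""
        n = X.shape[0]
        counts = np.zeros((n, len(self.classes)), dtype=np.float64)
        rows = np.arange(n)
        for tree in self.forest.estimators_:
            # forest sub-trees emit indices into forest.classes_ (== self.classes)
            counts[rows, np.asarray(tree.predict(X), dtype=int)] += 1.0
        return counts / len(self.forest.estimators_)

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote class codes; ties broken toward the lower code."""
        fractions = self.vote_fractions(X)
        return self.classes[np.argmax(fractions, axis=1)]


def _canonical_order(samples: SampleTable) -> np.ndarray:
    keys = (samples.y,
            samples.coords[:, 0], samples.coords[:, 1], samples.coords[:, 2],
            samples.specimens.astype(str))
    return np.lexsort(keys)


def train(samples: SampleTable, hyperparams: Optional[Hyperparams] = None,
          seed: int = 0) -> TrainedModel:
    """Fit a random forest on annotated feature rows.

    The table is canonically sorted before fitting so that permuting the row
    order of the input never changes the model.
    """
    hyperparams = hyperparams or Hyperparams()
    if samples.channels is None or not samples.channels:
        raise ValueError("sample table has no channel schema")
    present = np.unique(samples.y)
    if present.size < 2:
        raise ValueError("training requires samples from at least two classes")

    order = _canonical_order(samples)
    X, y = samples.X[order], samples.y[order]
    forest = RandomForestClassifier(
        n_estimators=hyperparams.n_trees,
        max_features=hyperparams.max_features,
        max_depth=hyperparams.max_depth,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y)

    specimens = sorted(set(samples.specimens.astype(str)))
    per_class = {CLASS_NAMES[c]: int((samples.y == c).sum()) for c in present}
    metadata = {"specimens": specimens, "n_samples": len(samples), "per_class": per_class}
    return TrainedModel(forest=forest, channels=list(samples.channels),
                        classes=np.asarray(forest.classes_, dtype=int),
                        hyperparams=hyperparams, seed=int(seed), metadata=metadata)


def predict_labels(model: TrainedModel, stack: FeatureStack,
                   mask: Optional[np.ndarray] = None):
    """Dense voxel-wise classification of a feature stack.

    Out-of-mask voxels are labeled background.  Returns a
    :class:`~trunkphenix.phantom.LabelVolume`.
    """
    from .phantom import LabelVolume

    model.check_schema(stack.channels)
    shape = stack.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask grid must be congruent with the feature stack")
    out = np.full(shape, BACKGROUND, dtype=np.uint8)
    idx = np.nonzero(mask)
    if idx[0].size:
        X = stack.data[:, idx[0], idx[1], idx[2]].T
        out[idx] = model.predict_codes(X).astype(np.uint8)
    return LabelVolume(data=out, spacing=stack.spacing)


def predict_class_fractions(model: TrainedModel, stack: FeatureStack,
                            mask: Optional[np.ndarray] = None) -> dict[str, np.ndarray]:
    """Per-voxel per-class tree-vote fractions (summing to 1 in-mask).

    Out-of-mask voxels get fraction 1 for background.  Returns a dict mapping
    class name to a float grid; classes unseen in training map to zeros.
    """
    model.check_schema(stack.channels)
    shape = stack.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    maps = {name: np.zeros(shape, dtype=np.float64) for name in CLASS_NAMES}
    maps["background"][~mask] = 1.0
    idx = np.nonzero(mask)
    if idx[0].size:
        X = stack.data[:, idx[0], idx[1], idx[2]].T
        fractions = model.vote_fractions(X)
        for col, code in enumerate(model.classes):
            maps[CLASS_NAMES[int(code)]][idx] = fractions[:, col]
    return maps
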