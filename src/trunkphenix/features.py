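"""Per-voxel multi-scale feature vectors for the trainable voxel classifier.

Each modality volume is expanded into a bank of smoothed/derivative/rank
filters parameterized by an integer scale (in voxels), following the trainable
segmentation convention: the raw intensity is always included as a channel,
and the remaining channels are ``operator x scale`` products.  All filters act
isotropically in index space on the full 3D neighborhood, with edge
replication at borders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import MODALITIES, AnnotationSet, MultimodalVolume, CLASS_CODES

OPERATORS: tuple[str, ...] = (
    "local_mean", "local_variance", "local_min", "local_max",
    "local_median", "edge", "dog",
)

#: Powers of two spanning the 1..64-voxel scale range.
DEFAULT_SCALES: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64)

_BORDER_MODE = "nearest"  # edge replication, for bit-reproducibility


@dataclass(frozen=True)
class FilterSpec:
    """One filter-bank member: an operator and its scale in voxels."""

    operator: str
    scale: int = 1

    def __post_init__(self) -> None:
        if self.operator != "raw" and self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.operator != "raw" and self.scale < 1:
            raise ValueError("scale must be >= 1")

    @property
    def name(self) -> str:
        return "raw" if self.operator == "raw" else f"{self.operator}_s{self.scale}"


def compute_filter(volume: np.ndarray, filt: FilterSpec) -> np.ndarray:
    """Apply one filter to a 3D intensity grid.

    Local rank/moment operators use a cubic neighborhood of half-width
    ``scale``; ``edge`` is the Gaussian gradient magnitude at sigma = scale;
    ``dog`` is the difference of Gaussian blurs at sigmas (scale, 2*scale).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(volume).all():
        raise ValueError("volume must be finite-valued")
    op, scale = filt.operator, filt.scale
    if op == "raw":
        return volume.copy()
    if scale > min(volume.shape):
        raise ValueError(f"scale {scale} exceeds the grid extent {volume.shape}")
    size = 2 * scale + 1
    if op == "local_mean":
        return ndimage.uniform_filter(volume, size=size, mode=_BORDER_MODE)
    if op == "local_variance":
        # center first: the variance is shift-invariant and centring avoids
        # catastrophic cancellation in E[v^2] - E[v]^2
        v0 = volume - volume.mean()
        m = ndimage.uniform_filter(v0, size=size, mode=_BORDER_MODE)
        m2 = ndimage.uniform_filter(v0 * v0, size=size, mode=_BORDER_MODE)
        return np.maximum(m2 - m * m, 0.0)
    if op == "local_min":
        return ndimage.minimum_filter(volume, size=size, mode=_BORDER_MODE)
    if op == "local_max":
        return ndimage.maximum_filter(volume, size=size, mode=_BORDER_MODE)
    if op == "local_median":
        return ndimage.median_filter(volume, size=size, mode=_BORDER_MODE)
    if op == "edge":
        return ndimage.gaussian_gradient_magnitude(volume, sigma=scale, mode=_BORDER_MODE)
    if op == "dog":
        return (ndimage.gaussian_filter(volume, sigma=scale, mode=_BORDER_MODE)
                - ndimage.gaussian_filter(volume, sigma=2 * scale, mode=_BORDER_MODE))
    raise ValueError(f"unknown operator {op!r}")  # pragma: no cover


def channel_specs(modalities: Sequence[str], operators: Sequence[str],
                  scales: Sequence[int]) -> list[tuple[str, FilterSpec]]:
    """Canonical (modality, FilterSpec) channel order.

    Modalities follow the global modality order; per modality the raw channel
    comes first, then operators in canonical order crossed with ascending
    scales.
    """
    mods = [m for m in MODALITIES if m in modalities]
    unknown = set(modalities) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities {sorted(unknown)}")
    if not mods:
        raise ValueError("modalities must be a non-empty subset")
    ops = [o for o in OPERATORS if o in operators]
    unknown_ops = set(operators) - set(OPERATORS)
    if unknown_ops:
        raise ValueError(f"unknown operators {sorted(unknown_ops)}")
    scales = sorted(set(int(s) for s in scales))
    specs: list[tuple[str, FilterSpec]] = []
    for m in mods:
        specs.append((m, FilterSpec("raw")))
        for op in ops:
            for s in scales:
                specs.append((m, FilterSpec(op, s)))
    return specs


@dataclass
class FeatureStack:
    """Stack of per-voxel feature channels over one specimen grid.

    ``data`` has shape (n_channels, nx, ny, nz); ``channels`` holds the unique
    canonical channel names ``<modality>__<operator>[_s<scale>]``.
    """

    channels: list[str]
    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel list and data are inconsistent")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def values_at(self, coords: np.ndarray) -> np.ndarray:
        """(n, n_channels) feature rows at integer voxel coordinates."""
        coords = np.asarray(coords, dtype=int)
        return self.data[:, coords[:, 0], coords[:, 1], coords[:, 2]].T


def build_feature_stack(volume: MultimodalVolume,
                        modalities: Optional[Sequence[str]] = None,
                        operators: Sequence[str] = OPERATORS,
                        scales: Sequence[int] = DEFAULT_SCALES) -> FeatureStack:
    """Compute the full filter bank over a subset of modalities."""
    modalities = volume.modalities if modalities is None else modalities
    specs = channel_specs(modalities, operators, scales)
    names, planes = [], []
    for modality, filt in specs:
        names.append(f"{modality}__{filt.name}")
        planes.append(compute_filter(volume.get(modality), filt))
    return FeatureStack(channels=names, data=np.stack(planes), spacing=volume.spacing)


@dataclass
class SampleTable:
    """Annotated feature rows ready for classifier training.

    ``X`` is (n_samples, n_channels); ``y`` holds integer class codes;
    ``specimens`` and voxel ``coords`` keep provenance for canonical sorting
    and leakage audits.
    """

    X: np.ndarray
    y: np.ndarray
    specimens: np.ndarray
    coords: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("feature and label row counts differ")
        if np.isnan(self.X).any():
            raise ValueError("feature rows must not contain missing values")

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.channels)
        for i, col in enumerate(("x", "y", "z")):
            frame.insert(i, col, self.coords[:, i] if len(self.coords) else [])
        frame.insert(0, "specimen", self.specimens)
        frame["label"] = self.y
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleTable":
        meta = ("specimen", "x", "y", "z", "label")
        channels = [c for c in frame.columns if c not in meta]
        return cls(X=frame[channels].to_numpy(dtype=float),
                   y=frame["label"].to_numpy(dtype=int),
                   specimens=frame["specimen"].to_numpy(dtype=object),
                   coords=frame[["x", "y", "z"]].to_numpy(dtype=int),
                   channels=channels)

    def subset_channels(self, channels: Sequence[str]) -> "SampleTable":
        idx = [self.channels.index(c) for c in channels]
        return SampleTable(X=self.X[:, idx], y=self.y, specimens=self.specimens,
                           coords=self.coords, channels=list(channels))

    @staticmethod
    def concatenate(tables: Sequence["SampleTable"]) -> "SampleTable":
        if not tables:
            raise ValueError("cannot concatenate zero tables")
        channels = tables[0].channels
        for t in tables[1:]:
            if t.channels != channels:
                raise ValueError("tables have inconsistent channel schemas")
        return SampleTable(
            X=np.concatenate([t.X for t in tables]),
            y=np.concatenate([t.y for t in tables]),
            specimens=np.concatenate([t.specimens for t in tables]),
            coords=np.concatenate([t.coords for t in tables]),
            channels=channels,
        )


def extract_samples(stack: FeatureStack, annotations: AnnotationSet) -> SampleTable:
    """One feature row per annotated voxel, in annotation order."""
    table = annotations.table
    coords = table[["x", "y", "z"]].to_numpy(dtype=int) if len(table) else np.zeros((0, 3), int)
    shape = stack.grid_shape
    for i, (x, y, z) in enumerate(coords):
        if not (0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]):
            raise ValueError(f"annotation row {i} at ({x},{y},{z}) lies outside the grid {shape}")
    X = stack.values_at(coords) if len(coords) else np.zeros((0, len(stack.channels)))
    y = table["class"].map(CLASS_CODES).to_numpy(dtype=int) if len(table) else np.zeros(0, int)
    specimens = table["specimen"].to_numpy(dtype=object) if len(table) else np.zeros(0, object)
    return SampleTable(X=X, y=y, specimens=specimens, coords=coords, channels=list(stack.channels))
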