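"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: filters are
re-implemented as explicit neighborhood loops and separable kernel sums,
geodesics via scipy's sparse-graph Dijkstra, and block votes via per-block
Python loops.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

import trunkphenix as tp


# ---------------------------------------------------------------------------
# Small phantom fixtures (fast; used across test modules)
# ---------------------------------------------------------------------------

SMALL_SPEC = tp.PhantomSpec(
    grid_shape=(32, 32, 48), trunk_radius=8.0, trunk_length=22.0,
    tortuosity_amplitude=1.5, bark_thickness=1.6, branch_radius=3.5,
    lesion_center_offset=5.0, lesion_fraction_degraded=0.18,
    lesion_fraction_white_rot=0.08,
)

#: raw-only feature configuration (fast, exact on noiseless phantoms)
RAW_CONFIG = tp.FeatureConfig(operators=(), scales=())
#: small multi-operator configuration for unit-scale experiments
SMALL_CONFIG = tp.FeatureConfig(scales=(1,))


@pytest.fixture(scope="session")
def small_record():
    return tp.generate_specimen(SMALL_SPEC, seed=11, specimen_id="unit-0")


@pytest.fixture(scope="session")
def noiseless_record():
    spec = dataclasses.replace(SMALL_SPEC, noise_sd=0.0)
    return tp.generate_specimen(spec, seed=11, specimen_id="unit-quiet")


@pytest.fixture(scope="session")
def small_cohort():
    return tp.generate_cohort(4, SMALL_SPEC, seed=3)


@pytest.fixture(scope="session")
def small_annotations(small_cohort):
    return {r.specimen_id: tp.sample_annotations(r, n_sections=10, per_class_cap=120, seed=5)
            for r in small_cohort}


# ---------------------------------------------------------------------------
# Brute-force filter oracles
# ---------------------------------------------------------------------------

def _windows(volume: np.ndarray, scale: int):
    """Yield (index, flat neighborhood) with edge replication."""
    padded = np.pad(volume, scale, mode="edge")
    size = 2 * scale + 1
    for i in range(volume.shape[0]):
        for j in range(volume.shape[1]):
            for k in range(volume.shape[2]):
                yield (i, j, k), padded[i:i + size, j:j + size, k:k + size].ravel()


def _gauss_kernel_1d(sigma: float, order: int = 0) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 1:
        phi = phi * (-x / sigma ** 2)
    return phi


def _separable_correlate(volume: np.ndarray, kernels) -> np.ndarray:
    """Apply one 1D kernel per axis with edge replication, via explicit sums."""
    out = volume.astype(float)
    for axis, kernel in enumerate(kernels):
        radius = (len(kernel) - 1) // 2
        pad = [(0, 0)] * 3
        pad[axis] = (radius, radius)
        padded = np.pad(out, pad, mode="edge")
        acc = np.zeros_like(out)
        for t, w in enumerate(kernel):
            sl = [slice(None)] * 3
            sl[axis] = slice(t, t + out.shape[axis])
            acc += w * padded[tuple(sl)]
        out = acc
    return out


def oracle_filter(volume: np.ndarray, operator: str, scale: int) -> np.ndarray:
    """Loop/kernel-sum reference implementation of every filter operator."""
    volume = np.asarray(volume, dtype=float)
    if operator == "raw":
        return volume.copy()
    if operator in ("local_mean", "local_variance", "local_min", "local_max", "local_median"):
        out = np.empty(volume.shape)
        for idx, w in _windows(volume, scale):
            if operator == "local_mean":
                out[idx] = w.mean()
            elif operator == "local_variance":
                out[idx] = ((w - w.mean()) ** 2).mean()
            elif operator == "local_min":
                out[idx] = w.min()
            elif operator == "local_max":
                out[idx] = w.max()
            else:
                out[idx] = np.median(w)
        return out
    g0 = _gauss_kernel_1d(scale, 0)
    if operator == "edge":
        g1 = _gauss_kernel_1d(scale, 1)
        sq = np.zeros(volume.shape)
        for axis in range(3):
            kernels = [g1 if a == axis else g0 for a in range(3)]
            sq += _separable_correlate(volume, kernels) ** 2
        return np.sqrt(sq)
    if operator == "dog":
        wide = _gauss_kernel_1d(2 * scale, 0)
        return (_separable_correlate(volume, [g0] * 3)
                - _separable_correlate(volume, [wide] * 3))
    raise ValueError(operator)


# ---------------------------------------------------------------------------
# Geodesic and block-vote oracles
# ---------------------------------------------------------------------------

def oracle_geodesic(mask: np.ndarray, reference, spacing,
                    connectivity: int = 26) -> np.ndarray:
    """Dijkstra over an explicit sparse voxel graph with physical edge lengths."""
    mask = np.asarray(mask, bool)
    idx = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    idx[tuple(coords.T)] = np.arange(len(coords))
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)
               and (connectivity == 26 or abs(dx) + abs(dy) + abs(dz) == 1)]
    rows, cols, weights = [], [], []
    sp = np.asarray(spacing, float)
    for (dx, dy, dz) in offsets:
        shifted = coords + np.array([dx, dy, dz])
        valid = np.zeros(len(coords), bool)
        inside = np.all((shifted >= 0) & (shifted < mask.shape), axis=1)
        valid[inside] = mask[tuple(shifted[inside].T)]
        rows.extend(idx[tuple(coords[valid].T)])
        cols.extend(idx[tuple(shifted[valid].T)])
        weights.extend([float(np.linalg.norm(np.array([dx, dy, dz]) * sp))] * int(valid.sum()))
    n = len(coords)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n))
    source = idx[tuple(reference)]
    dist = csgraph_dijkstra(graph.tocsr(), directed=False, indices=source)
    out = np.full(mask.shape, np.inf)
    out[tuple(coords.T)] = dist
    return out


def oracle_block_majority(labels: np.ndarray, factors) -> np.ndarray:
    """Per-block vote with ties toward the lower class code."""
    fx, fy, fz = factors
    nx, ny, nz = labels.shape
    shape = (-(-nx // fx), -(-ny // fy), -(-nz // fz))
    out = np.zeros(shape, dtype=np.uint8)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                block = labels[i * fx:(i + 1) * fx, j * fy:(j + 1) * fy, k * fz:(k + 1) * fz]
                counts = np.bincount(block.ravel(), minlength=5)
                out[i, j, k] = int(np.argmax(counts))
    return out


def oracle_block_mean(volume: np.ndarray, factors) -> np.ndarray:
    fx, fy, fz = factors
    nx, ny, nz = volume.shape
    shape = (-(-nx // fx), -(-ny // fy), -(-nz // fz))
    out = np.zeros(shape, dtype=float)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                block = volume[i * fx:(i + 1) * fx, j * fy:(j + 1) * fy, k * fz:(k + 1) * fz]
                out[i, j, k] = block.mean()
    return out
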