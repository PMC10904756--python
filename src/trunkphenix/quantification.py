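"""Tissue quantification and geodesic positioning along the trunk.

Tissue compartments are counted and converted to physical volumes; their
location is expressed as a geodesic distance from a reference point placed on
the trunk axis (by convention 20 cm below the trunk head), computed as the
shortest in-mask path so that tortuous trunks are measured along their own
anatomy rather than through space.  The signed position (distance minus the
reference depth, in cm) is ~0 at the trunk head, negative inside the trunk
and positive in the branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.graph import MCP_Geometric

from .phantom import (CLASS_CODES, CLASS_NAMES, TISSUE_CLASSES, TISSUE_CODES,
                      INTACT, LabelVolume, MultimodalVolume)

#: Default depth of the reference point below the trunk head, in mm.
DEFAULT_REFERENCE_DEPTH_MM = 200.0


# ---------------------------------------------------------------------------
# Tissue quantification
# ---------------------------------------------------------------------------

@dataclass
class TissueSummary:
    """Per-class counts, physical volumes and tissue fractions in a region.

    Fractions are computed over the three tissue classes only and are NaN
    ("undefined") when the region holds no tissue voxel.
    """

    table: pd.DataFrame          # index: class names; columns: count, volume_cm3, tissue_fraction
    region: str = "whole volume"

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.table.loc[list(TISSUE_CLASSES), "tissue_fraction"]).all())

    def fraction_pct(self, name: str) -> float:
        return float(self.table.loc[name, "tissue_fraction"] * 100.0)

    def count(self, name: str) -> int:
        return int(self.table.loc[name, "count"])


def quantify_tissues(labels: LabelVolume, spacing: Optional[Sequence[float]] = None,
                     region_mask: Optional[np.ndarray] = None,
                     region: str = "whole volume") -> TissueSummary:
    """Count voxels per class and convert to cm^3 within an optional region."""
    data = labels.data
    spacing = labels.spacing if spacing is None else tuple(spacing)
    if region_mask is not None:
        if region_mask.shape != data.shape:
            raise ValueError("region mask must be congruent with the label grid")
        values = data[region_mask]
    else:
        values = data.ravel()
    counts = np.bincount(values, minlength=len(CLASS_NAMES))[:len(CLASS_NAMES)]
    voxel_cm3 = float(np.prod(spacing)) / 1000.0  # mm^3 -> cm^3
    tissue_total = counts[list(TISSUE_CODES)].sum()
    fractions = np.full(len(CLASS_NAMES), np.nan)
    if tissue_total > 0:
        for code in TISSUE_CODES:
            fractions[code] = counts[code] / tissue_total
    table = pd.DataFrame({
        "count": counts.astype(int),
        "volume_cm3": counts * voxel_cm3,
        "tissue_fraction": fractions,
    }, index=list(CLASS_NAMES))
    return TissueSummary(table=table, region=region)


# ---------------------------------------------------------------------------
# Geodesic distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceMap:
    """Geodesic distance (mm) from the reference point within a mask."""

    distance_mm: np.ndarray       # +inf outside the mask / unreachable
    reachable: np.ndarray         # boolean
    reference: tuple[int, int, int]
    spacing: tuple[float, float, float]
    reference_depth_mm: float = DEFAULT_REFERENCE_DEPTH_MM

    def signed_position_cm(self) -> np.ndarray:
        """(distance - reference depth) / 10: ~0 at the trunk head."""
        return (self.distance_mm - self.reference_depth_mm) / 10.0

    def band_mask(self, lo_cm: float, hi_cm: float) -> np.ndarray:
        pos = self.signed_position_cm()
        return self.reachable & (pos >= lo_cm) & (pos < hi_cm)


def geodesic_map(mask: np.ndarray, reference: Sequence[int],
                 spacing: Sequence[float],
                 reference_depth_mm: float = DEFAULT_REFERENCE_DEPTH_MM,
                 connectivity: int = 26) -> DistanceMap:
    """Shortest-path distance over in-mask neighbors with physical edge lengths.

    Steps connect 26-neighborhoods by default (6 by flag); each edge costs its
    Euclidean length in mm given the voxel spacing.
    """
    mask = np.asarray(mask, dtype=bool)
    reference = tuple(int(c) for c in reference)
    if not mask[reference]:
        raise ValueError(f"reference point {reference} lies outside the mask")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    costs = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=(connectivity == 26),
                        sampling=tuple(float(s) for s in spacing))
    cumulative, _ = mcp.find_costs([reference])
    distance = np.where(np.isfinite(cumulative), cumulative, np.inf)
    distance[~mask] = np.inf
    reachable = np.isfinite(distance)
    return DistanceMap(distance_mm=distance, reachable=reachable, reference=reference,
                       spacing=tuple(float(s) for s in spacing),
                       reference_depth_mm=float(reference_depth_mm))


# ---------------------------------------------------------------------------
# Distance profiles and region restrictions
# ---------------------------------------------------------------------------

@dataclass
class DistanceProfile:
    """Per-bin tissue-class composition along the signed geodesic position."""

    bin_edges_cm: np.ndarray
    counts: pd.DataFrame        # index: bin centers; columns: tissue classes
    totals: np.ndarray

    def fractions(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts.div(self.totals, axis=0)


def distance_profile(labels: LabelVolume, dmap: DistanceMap,
                     bin_width_cm: float = 1.0,
                     position_range_cm: tuple[float, float] = (-20.0, 5.0)) -> DistanceProfile:
    """Tissue composition in geodesic-position bins over [lo, hi) cm."""
    if bin_width_cm <= 0:
        raise ValueError("bin width must be strictly positive")
    if labels.shape != dmap.distance_mm.shape:
        raise ValueError("label grid and distance map must be congruent")
    lo, hi = position_range_cm
    edges = np.arange(lo, hi + bin_width_cm * 0.5, bin_width_cm)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    pos = dmap.signed_position_cm()
    sel = dmap.reachable & (labels.data >= INTACT) & (pos >= lo) & (pos < edges[-1])
    which = np.digitize(pos[sel], edges) - 1
    tissue = labels.data[sel]

    n_bins = len(edges) - 1
    counts = np.zeros((n_bins, len(TISSUE_CLASSES)), dtype=np.int64)
    for j, code in enumerate(TISSUE_CODES):
        counts[:, j] = np.bincount(which[tissue == code], minlength=n_bins)[:n_bins]
    centers = (edges[:-1] + edges[1:]) / 2.0
    frame = pd.DataFrame(counts, index=centers, columns=list(TISSUE_CLASSES))
    return DistanceProfile(bin_edges_cm=edges, counts=frame, totals=counts.sum(axis=1))


def region_fractions(labels: LabelVolume, dmap: DistanceMap,
                     lo_cm: float = -2.0, hi_cm: float = 2.0) -> TissueSummary:
    """Tissue summary restricted to a signed-position band [lo, hi) in cm."""
    if lo_cm >= hi_cm:
        raise ValueError("lo_cm must be strictly below hi_cm")
    band = dmap.band_mask(lo_cm, hi_cm)
    return quantify_tissues(labels, region_mask=band,
                            region=f"geodesic position [{lo_cm:g}, {hi_cm:g}) cm")


# ---------------------------------------------------------------------------
# Class-wise signal summary
# ---------------------------------------------------------------------------

@dataclass
class SignalSummary:
    """Class x modality intensity moments and ordered relative changes."""

    moments: pd.DataFrame          # MultiIndex (class, modality): mean, sd, n
    relative_change: pd.DataFrame  # index: transition; columns: modalities (fractional change)

    def change_pct(self, transition: str, modality: str) -> float:
        return float(self.relative_change.loc[transition, modality] * 100.0)


def summarize_signals(volume: MultimodalVolume, labels: LabelVolume) -> SignalSummary:
    """Exact per-class intensity moments and inter-class relative changes.

    The relative-change table holds (mean_b - mean_a) / mean_a for the ordered
    degradation transitions intact->degraded and degraded->white_rot; cells
    involving an absent class are NaN.
    """
    if volume.shape != labels.shape:
        raise ValueError("intensity and label grids must be congruent")
    rows = []
    means: dict[tuple[str, str], float] = {}
    flat_labels = labels.data.ravel()
    for name in CLASS_NAMES:
        code = CLASS_CODES[name]
        sel = flat_labels == code
        n = int(sel.sum())
        for m in volume.modalities:
            vals = volume.get(m).ravel()[sel]
            mean = float(vals.mean()) if n else float("nan")
            sd = float(vals.std(ddof=0)) if n else float("nan")
            means[(name, m)] = mean
            rows.append({"class": name, "modality": m, "mean": mean, "sd": sd, "n": n})
    moments = pd.DataFrame(rows).set_index(["class", "modality"])

    transitions = [("intact", "degraded"), ("degraded", "white_rot")]
    change = pd.DataFrame(index=[f"{a}->{b}" for a, b in transitions],
                          columns=list(volume.modalities), dtype=float)
    for a, b in transitions:
        for m in volume.modalities:
            ma, mb = means[(a, m)], means[(b, m)]
            if np.isfinite(ma) and np.isfinite(mb) and ma != 0:
                change.loc[f"{a}->{b}", m] = (mb - ma) / ma
    return SignalSummary(moments=moments, relative_change=change)
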