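"""Synthetic vine-trunk phantoms: labeled multimodal volumes with known geometry.

No imaging dataset of diseased grapevine trunks is publicly deposited, so this
module generates seeded synthetic specimens that carry the statistical structure
the downstream classifier and diagnostics assume: a tortuous woody cylinder with
a bark shell, a degraded lesion with a nested white-rot core concentrated near
the trunk head, four co-registered intensity channels (MRI T1-w, T2-w, PD-w and
X-ray CT absorbance) whose class means follow the relative signal declines
measured on real vines, and a twenty-year foliar-symptom history per specimen.

Intensities are expressed on a relative scale where the *intact* class mean is
100 in every modality; only relative inter-class changes are meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

# ---------------------------------------------------------------------------
# Class and modality codebooks (canonical order, fixed integer codes)
# ---------------------------------------------------------------------------

MODALITIES: tuple[str, ...] = ("T1w", "T2w", "PDw", "Xray")

CLASS_NAMES: tuple[str, ...] = ("background", "bark", "intact", "degraded", "white_rot")
CLASS_CODES: dict[str, int] = {name: code for code, name in enumerate(CLASS_NAMES)}
BACKGROUND, BARK, INTACT, DEGRADED, WHITE_ROT = range(5)
TISSUE_CLASSES: tuple[str, ...] = ("intact", "degraded", "white_rot")
TISSUE_CODES: tuple[int, ...] = (INTACT, DEGRADED, WHITE_ROT)

#: Relative mean declines between ordered tissue classes, per modality
#: (fractions of the preceding class mean; measured on whole classified vines).
DECLINE_INTACT_TO_DEGRADED: dict[str, float] = {
    "T1w": 0.573, "T2w": 0.863, "PDw": 0.713, "Xray": 0.193,
}
DECLINE_DEGRADED_TO_WHITE_ROT: dict[str, float] = {
    "T1w": 0.368, "T2w": 0.768, "PDw": 0.642, "Xray": 0.560,
}

#: Bark means relative to intact: 0.60 for the MRI channels, 0.90 for X-ray.
#: No bark statistics are reported for real vines; these values merely make the
#: bark shell separable and are exposed for configuration.
BARK_RELATIVE_MEAN: dict[str, float] = {"T1w": 0.60, "T2w": 0.60, "PDw": 0.60, "Xray": 0.90}

#: Default per-class intensity spread (10% of the intact mean).
DEFAULT_SD = 10.0

#: Axial elongation of the lesion distance metric (lesions stretch along the
#: trunk axis rather than forming spheres).
LESION_AXIAL_ELONGATION = 2.0

# Cohort history model: lesion burden grows with the number of symptomatic
# years.  Fractions of wood volume: degraded = 0.05 + 0.045*c, white rot =
# 0.015 + 0.021*c (c = cumulative symptomatic years), jittered by +/-15% per
# specimen.  Category -> cumulative-year ranges (inclusive).
HISTORY_CATEGORIES: tuple[str, ...] = (
    "asymptomatic_always",
    "asymptomatic_resilient",
    "symptomatic_neo",
    "symptomatic_apoplectic",
)
CATEGORY_CUMULATIVE_YEARS: dict[str, tuple[int, int]] = {
    "asymptomatic_always": (0, 0),
    "asymptomatic_resilient": (2, 3),
    "symptomatic_neo": (1, 1),
    "symptomatic_apoplectic": (4, 6),
}
BURDEN_DEGRADED_BASE, BURDEN_DEGRADED_SLOPE = 0.05, 0.045
BURDEN_WHITE_ROT_BASE, BURDEN_WHITE_ROT_SLOPE = 0.015, 0.021
BURDEN_JITTER = 0.15

DEFAULT_PLANTING_YEAR = 1999
DEFAULT_OBSERVATION_YEAR = 2019


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of one synthetic trunk.

    Axes are indexed (x, y, z) with the trunk axis along z.  All physical
    quantities are in millimetres.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 160)
    voxel_spacing: tuple[float, float, float] = (0.68, 0.68, 0.60)
    trunk_radius: float = 16.0
    trunk_length: float = 78.0
    tortuosity_amplitude: float = 3.0
    bark_thickness: float = 2.0
    lesion_fraction_degraded: float = 0.18
    lesion_fraction_white_rot: float = 0.08
    lesion_center_offset: float = 10.0
    #: depth of the geodesic reference point below the trunk head; ``None``
    #: resolves to min(200 mm, 0.8 * trunk_length) at generation time.
    reference_depth: Optional[float] = None
    branch_radius: float = 6.0
    n_branches: int = 2
    noise_sd: float = 10.0
    texture_smoothing: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be strictly positive, got {self.grid_shape}")
        for name in ("trunk_radius", "trunk_length", "bark_thickness", "branch_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive")
        fd, fw = self.lesion_fraction_degraded, self.lesion_fraction_white_rot
        if not (0 <= fd < 1 and 0 <= fw < 1 and fd + fw < 1):
            raise ValueError("lesion fractions must lie in [0,1) and sum below 1")
        if self.noise_sd < 0 or self.tortuosity_amplitude < 0:
            raise ValueError("noise_sd and tortuosity_amplitude must be non-negative")

    def resolved_reference_depth(self) -> float:
        if self.reference_depth is not None:
            return float(self.reference_depth)
        return min(200.0, 0.8 * self.trunk_length)


@dataclass(frozen=True)
class SignalModel:
    """Per-class, per-modality intensity means and spreads.

    Both tables are indexed by :data:`CLASS_NAMES` rows and :data:`MODALITIES`
    columns.  Intact means are normalized to 100 per modality; only relative
    changes between classes are physically meaningful.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame

    def __post_init__(self) -> None:
        for table in (self.mean, self.sd):
            if list(table.index) != list(CLASS_NAMES) or list(table.columns) != list(MODALITIES):
                raise ValueError("signal tables must be indexed by the canonical class/modality order")
        if (self.mean.values < 0).any():
            raise ValueError("class means must be non-negative")
        for m in MODALITIES:
            if not (self.mean.loc["white_rot", m] < self.mean.loc["degraded", m]
                    < self.mean.loc["intact", m]):
                raise ValueError(f"means must decline intact > degraded > white_rot in {m}")

    def mean_lut(self) -> np.ndarray:
        """(n_classes, n_modalities) float lookup table in code order."""
        return self.mean.to_numpy(dtype=float)

    def sd_lut(self) -> np.ndarray:
        return self.sd.to_numpy(dtype=float)


@dataclass
class SymptomHistory:
    """Yearly foliar-symptom record of one vine."""

    vine_id: str
    flags: dict[int, bool]
    apoplexy_year: Optional[int] = None

    def __post_init__(self) -> None:
        self.flags = {int(y): bool(v) for y, v in sorted(self.flags.items())}
        if self.apoplexy_year is not None and self.apoplexy_year not in self.flags:
            raise ValueError("apoplexy_year must lie inside the recorded year range")

    @property
    def years(self) -> list[int]:
        return sorted(self.flags)

    def flag(self, year: int) -> bool:
        if year not in self.flags:
            raise ValueError(f"year {year} outside the recorded history of {self.vine_id}")
        return self.flags[year]

    def cumulative_symptomatic_years(self, through_year: Optional[int] = None) -> int:
        return sum(v for y, v in self.flags.items()
                   if through_year is None or y <= through_year)

    def first_symptom_year(self) -> Optional[int]:
        for y in self.years:
            if self.flags[y]:
                return y
        return None


@dataclass
class MultimodalVolume:
    """Co-registered 3D intensity grids, one per imaging modality."""

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("modality grids must be congruent")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITIES if m in self.channels)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def get(self, modality: str) -> np.ndarray:
        return self.channels[modality]


@dataclass
class LabelVolume:
    """3D grid of tissue-class codes (see :data:`CLASS_CODES`)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.data.ravel(), minlength=len(CLASS_NAMES))
        return {name: int(counts[CLASS_CODES[name]]) for name in CLASS_NAMES}

    def wood_mask(self) -> np.ndarray:
        """Boolean mask of the three tissue classes (intact/degraded/white rot)."""
        return self.data >= INTACT


@dataclass
class SpecimenRecord:
    """One phantom vine: images, ground-truth labels, history and landmarks."""

    specimen_id: str
    volume: MultimodalVolume
    labels: LabelVolume
    history: SymptomHistory
    trunk_head_position: tuple[int, int, int]
    reference_point: tuple[int, int, int]
    spec: PhantomSpec = field(default=PhantomSpec())

    def __post_init__(self) -> None:
        if self.volume.shape != self.labels.shape:
            raise ValueError("intensity and label grids must be congruent")
        if self.labels.data[self.reference_point] < INTACT:
            raise ValueError("reference point must lie inside the wood mask")


@dataclass
class AnnotationSet:
    """Sparse voxel-level ground-truth labels sampled on transverse sections.

    ``table`` has columns (specimen, x, y, z, class); class values are names
    from :data:`CLASS_NAMES`.
    """

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    COLUMNS = ("specimen", "x", "y", "z", "class")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.table)

    def class_counts(self) -> dict[str, int]:
        vc = self.table["class"].value_counts()
        return {name: int(vc.get(name, 0)) for name in CLASS_NAMES}


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

def default_signal_model(bark_relative: Optional[dict[str, float]] = None,
                         sd: float = DEFAULT_SD) -> SignalModel:
    """Build the default class x modality intensity table.

    Intact means are fixed at 100; degraded and white-rot means are obtained by
    chaining the measured relative declines (intact→degraded, then
    degraded→white rot) per modality.  Bark sits at a configurable fraction of
    intact and background at zero.
    """
    bark_relative = dict(BARK_RELATIVE_MEAN if bark_relative is None else bark_relative)
    mean = pd.DataFrame(0.0, index=list(CLASS_NAMES), columns=list(MODALITIES))
    for m in MODALITIES:
        intact = 100.0
        degraded = intact * (1.0 - DECLINE_INTACT_TO_DEGRADED[m])
        white_rot = degraded * (1.0 - DECLINE_DEGRADED_TO_WHITE_ROT[m])
        mean.loc["background", m] = 0.0
        mean.loc["bark", m] = intact * bark_relative[m]
        mean.loc["intact", m] = intact
        mean.loc["degraded", m] = degraded
        mean.loc["white_rot", m] = white_rot
    sd_table = pd.DataFrame(float(sd), index=list(CLASS_NAMES), columns=list(MODALITIES))
    return SignalModel(mean=mean, sd=sd_table)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _axis_centers(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-z-plane (cx, cy) of the trunk axis in mm, with sinusoidal tortuosity."""
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_spacing
    z_mm = (np.arange(nz) + 0.5) * dz
    cx0, cy0 = nx * dx / 2.0, ny * dy / 2.0
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, size=2)
    wavelength = max(spec.trunk_length, 1.0)
    cx = cx0 + spec.tortuosity_amplitude * np.sin(2 * np.pi * z_mm / wavelength + phase_x)
    cy = cy0 + spec.tortuosity_amplitude * np.sin(2 * np.pi * z_mm / wavelength + phase_y)
    return cx, cy, z_mm


def _build_labels(spec: PhantomSpec, rng: np.random.Generator):
    """Noiseless ground-truth label volume plus landmarks.

    Returns (labels uint8 array, trunk_head voxel, reference voxel,
    axis centers in mm).
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_spacing
    cx, cy, z_mm = _axis_centers(spec, rng)

    x_mm = (np.arange(nx) + 0.5) * dx
    y_mm = (np.arange(ny) + 0.5) * dy
    X = x_mm[:, None]   # (nx, 1)
    Y = y_mm[None, :]   # (1, ny)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    trunk_planes = z_mm < spec.trunk_length
    head_z = int(np.searchsorted(z_mm, spec.trunk_length))
    head_z = min(head_z, nz - 1)

    # Branch centers: offset from the trunk-head axis position so that the
    # branch cross-sections overlap the trunk section at the interface.
    offset = max(spec.trunk_radius - spec.branch_radius - spec.bark_thickness, 0.0)
    angles = rng.uniform(0, 2 * np.pi) + np.arange(max(spec.n_branches, 1)) * (2 * np.pi / max(spec.n_branches, 1))
    branch_centers = [
        (cx[min(head_z, nz - 1)] + offset * np.cos(a), cy[min(head_z, nz - 1)] + offset * np.sin(a))
        for a in angles
    ]

    for k in range(nz):
        if trunk_planes[k]:
            r = np.sqrt((X - cx[k]) ** 2 + (Y - cy[k]) ** 2)
            wood = r < (spec.trunk_radius - spec.bark_thickness)
            bark = (r < spec.trunk_radius) & ~wood
            plane = np.zeros((nx, ny), dtype=np.uint8)
            plane[bark] = BARK
            plane[wood] = INTACT
            labels[:, :, k] = plane
        elif spec.n_branches > 0:
            plane = np.zeros((nx, ny), dtype=np.uint8)
            for (bx, by) in branch_centers:
                r = np.sqrt((X - bx) ** 2 + (Y - by) ** 2)
                wood = r < (spec.branch_radius - min(spec.bark_thickness, spec.branch_radius * 0.4))
                bark = (r < spec.branch_radius) & ~wood
                plane[bark & (plane == BACKGROUND)] = BARK
                plane[wood] = INTACT
            labels[:, :, k] = plane

    trunk_head = (int(round(cx[head_z] / dx - 0.5)), int(round(cy[head_z] / dy - 0.5)), head_z)
    ref_depth = spec.resolved_reference_depth()
    ref_zmm = np.clip(spec.trunk_length - ref_depth, dz, spec.trunk_length - dz)
    ref_k = int(np.clip(np.searchsorted(z_mm, ref_zmm), 0, nz - 1))
    reference = (int(round(cx[ref_k] / dx - 0.5)), int(round(cy[ref_k] / dy - 0.5)), ref_k)
    return labels, trunk_head, reference, (cx, cy, z_mm)


def _carve_lesion(labels: np.ndarray, spec: PhantomSpec, axis) -> None:
    """Place the degraded lesion and its strictly nested white-rot core.

    Wood voxels are ranked by an axially elongated distance from the lesion
    center (on the trunk axis, ``lesion_center_offset`` below the head).  The
    closest voxels form the lesion superset; the white-rot core is restricted
    to the 26-connectivity erosion of that superset, which guarantees every
    white-rot voxel touches only white-rot or degraded voxels.
    """
    fd, fw = spec.lesion_fraction_degraded, spec.lesion_fraction_white_rot
    if fd + fw <= 0:
        return
    cx, cy, z_mm = axis
    dx, dy, dz = spec.voxel_spacing
    nx, ny, nz = labels.shape

    wood = labels >= INTACT
    n_wood = int(wood.sum())
    n_lesion = int(round((fd + fw) * n_wood))
    n_wr = int(round(fw * n_wood))
    if n_lesion > n_wood:
        raise ValueError("requested lesion fractions exceed the available wood volume")

    zc_mm = spec.trunk_length - spec.lesion_center_offset
    kc = int(np.clip(np.searchsorted(z_mm, zc_mm), 0, nz - 1))
    center = np.array([cx[kc], cy[kc], z_mm[kc]])

    xs, ys, zs = np.nonzero(wood)
    pos = np.stack([(xs + 0.5) * dx, (ys + 0.5) * dy, (zs + 0.5) * dz], axis=1)
    delta = pos - center
    delta[:, 2] /= LESION_AXIAL_ELONGATION
    dist = np.sqrt((delta ** 2).sum(axis=1))

    order = np.argsort(dist, kind="stable")
    lesion_sel = order[:n_lesion]
    lesion_mask = np.zeros_like(wood)
    lesion_mask[xs[lesion_sel], ys[lesion_sel], zs[lesion_sel]] = True
    labels[lesion_mask] = DEGRADED

    if n_wr > 0:
        core = ndimage.binary_erosion(lesion_mask, structure=np.ones((3, 3, 3), bool),
                                      border_value=0)
        core_flat = core[xs, ys, zs]
        candidates = order[core_flat[order]]
        if candidates.size < n_wr:
            raise ValueError(
                "white-rot fraction unachievable: the eroded lesion core holds "
                f"{candidates.size} voxels but {n_wr} were requested"
            )
        wr_sel = candidates[:n_wr]
        labels[xs[wr_sel], ys[wr_sel], zs[wr_sel]] = WHITE_ROT


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def _smoothing_gain(sigma: float) -> float:
    """Std-dev shrinkage factor of white noise under 3D Gaussian smoothing."""
    if sigma <= 0:
        return 1.0
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    g1 = float(np.sqrt((k ** 2).sum()))
    return g1 ** 3


def _textured_noise(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="nearest")
    return smooth / _smoothing_gain(sigma)


# ---------------------------------------------------------------------------
# Specimen and cohort generation
# ---------------------------------------------------------------------------

def _default_history(vine_id: str) -> SymptomHistory:
    years = range(DEFAULT_PLANTING_YEAR, DEFAULT_OBSERVATION_YEAR + 1)
    return SymptomHistory(vine_id=vine_id, flags={y: False for y in years})


def generate_specimen(spec: PhantomSpec, model: Optional[SignalModel] = None,
                      seed=None, specimen_id: str = "phantom-0",
                      history: Optional[SymptomHistory] = None) -> SpecimenRecord:
    """Generate one synthetic specimen (labels + multimodal intensities).

    ``seed`` may be an int or a sequence of ints (used verbatim to seed a
    PCG64 generator, so identical spec+seed reproduce bit-identical volumes).
    Each voxel's intensity is its class mean plus spatially smoothed Gaussian
    noise whose standard deviation equals the signal model's spread table
    rescaled by ``spec.noise_sd / 10``.
    """
    spec.validate()
    model = default_signal_model() if model is None else model
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    labels, trunk_head, reference, axis = _build_labels(spec, rng)
    _carve_lesion(labels, spec, axis)

    mean_lut = model.mean_lut()
    sd_lut = model.sd_lut() * (spec.noise_sd / DEFAULT_SD)
    channels: dict[str, np.ndarray] = {}
    for j, m in enumerate(MODALITIES):
        intensity = mean_lut[labels, j]
        if spec.noise_sd > 0:
            noise = _textured_noise(labels.shape, spec.texture_smoothing, rng)
            intensity = intensity + noise * sd_lut[labels, j]
        channels[m] = intensity

    volume = MultimodalVolume(channels=channels, spacing=spec.voxel_spacing)
    label_volume = LabelVolume(data=labels, spacing=spec.voxel_spacing)
    return SpecimenRecord(
        specimen_id=specimen_id,
        volume=volume,
        labels=label_volume,
        history=history if history is not None else _default_history(specimen_id),
        trunk_head_position=trunk_head,
        reference_point=reference,
        spec=spec,
    )


def _make_history(vine_id: str, category: str, rng: np.random.Generator,
                  planting_year: int, observation_year: int) -> tuple[SymptomHistory, int]:
    """History consistent with one of the four sampling categories.

    Returns (history, cumulative symptomatic years).
    """
    years = list(range(planting_year, observation_year + 1))
    flags = {y: False for y in years}
    lo, hi = CATEGORY_CUMULATIVE_YEARS[category]
    cum = int(rng.integers(lo, hi + 1))
    apoplexy_year = None
    # symptoms never occur in the first three seasons after planting
    eligible_past = [y for y in years if planting_year + 3 <= y < observation_year]
    if category == "asymptomatic_always":
        pass
    elif category == "asymptomatic_resilient":
        past = rng.choice(eligible_past, size=min(cum, len(eligible_past)), replace=False)
        for y in past:
            flags[int(y)] = True
    elif category == "symptomatic_neo":
        flags[observation_year] = True
    elif category == "symptomatic_apoplectic":
        flags[observation_year] = True
        past = rng.choice(eligible_past, size=min(cum - 1, len(eligible_past)), replace=False)
        for y in past:
            flags[int(y)] = True
        apoplexy_year = observation_year
    else:  # pragma: no cover - guarded by HISTORY_CATEGORIES
        raise ValueError(f"unknown history category {category!r}")
    hist = SymptomHistory(vine_id=vine_id, flags=flags, apoplexy_year=apoplexy_year)
    return hist, hist.cumulative_symptomatic_years()


def generate_cohort(n_specimens: int, spec: Optional[PhantomSpec] = None,
                    seed: int = 0, model: Optional[SignalModel] = None,
                    planting_year: int = DEFAULT_PLANTING_YEAR,
                    observation_year: int = DEFAULT_OBSERVATION_YEAR) -> list[SpecimenRecord]:
    """Generate a cohort spanning the four foliar-symptom history categories.

    Specimens are assigned round-robin to the categories (n=12 gives three per
    category, matching the sampling design the workflow emulates).  Lesion
    burden grows monotonically with the cumulative number of symptomatic
    years, so always-asymptomatic vines carry the smallest lesions and
    apoplectic vines the largest.  Per-specimen RNG streams are derived from
    the root seed by fixed offsets.
    """
    if n_specimens < 4:
        raise ValueError("a cohort needs at least 4 specimens (one per history category)")
    spec = PhantomSpec() if spec is None else spec
    spec.validate()
    model = default_signal_model() if model is None else model

    records = []
    for i in range(n_specimens):
        category = HISTORY_CATEGORIES[i % len(HISTORY_CATEGORIES)]
        vine_id = f"vine-{i + 1:02d}"
        rng_i = np.random.default_rng([seed, i])
        history, cum = _make_history(vine_id, category, rng_i, planting_year, observation_year)
        jitter = 1.0 + float(rng_i.uniform(-BURDEN_JITTER, BURDEN_JITTER))
        fd = (BURDEN_DEGRADED_BASE + BURDEN_DEGRADED_SLOPE * cum) * jitter
        fw = (BURDEN_WHITE_ROT_BASE + BURDEN_WHITE_ROT_SLOPE * cum) * jitter
        spec_i = dataclasses.replace(spec,
                                     lesion_fraction_degraded=float(np.clip(fd, 0.0, 0.45)),
                                     lesion_fraction_white_rot=float(np.clip(fw, 0.0, 0.25)))
        record = generate_specimen(spec_i, model, seed=[seed, i, 1],
                                   specimen_id=vine_id, history=history)
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# Annotation sampling
# ---------------------------------------------------------------------------

def sample_annotations(specimen: SpecimenRecord, n_sections: int = 13,
                       per_class_cap: int = 1500, seed: int = 0) -> AnnotationSet:
    """Sample sparse ground-truth annotations on transverse sections.

    Emulates the manual labeling protocol: ``n_sections`` distinct z-planes
    containing plant material are selected, and within those planes at most
    ``per_class_cap`` voxels per class are labeled from the ground truth.
    """
    labels = specimen.labels.data
    rng = np.random.default_rng(seed)

    plant_planes = np.flatnonzero((labels > BACKGROUND).any(axis=(0, 1)))
    if plant_planes.size == 0:
        raise ValueError("specimen contains no plant voxels")
    if n_sections > plant_planes.size:
        raise ValueError(
            f"n_sections={n_sections} exceeds the {plant_planes.size} planes containing plant material"
        )
    sections = np.sort(rng.choice(plant_planes, size=n_sections, replace=False))

    rows = []
    notes: list[str] = []
    section_labels = labels[:, :, sections]
    for name in CLASS_NAMES:
        code = CLASS_CODES[name]
        xs, ys, ks = np.nonzero(section_labels == code)
        if xs.size == 0:
            notes.append(f"class {name!r} absent from the sampled sections")
            continue
        n_take = min(per_class_cap, xs.size)
        if n_take == 0:
            continue
        pick = rng.choice(xs.size, size=n_take, replace=False)
        pick.sort()
        for idx in pick:
            rows.append((specimen.specimen_id, int(xs[idx]), int(ys[idx]),
                         int(sections[ks[idx]]), name))

    table = pd.DataFrame(rows, columns=list(AnnotationSet.COLUMNS))
    return AnnotationSet(table=table, warnings=notes)
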