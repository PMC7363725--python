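"""Synthetic CBCT-like phantoms with exact analytic ground truth.

A phantom is a list of geometric primitives (sphere, hemispherical dome,
ellipsoid, cylinder, box), each carrying a material (bone, soft tissue,
styrofoam) and a region label.  Voxels take the HU of the last primitive
covering their center — list primitives outermost first — so the analytic
surface areas, volumes and label grids are exact by construction.  Optional
air bubbles inside soft tissue and additive Gaussian noise emulate the
artifacts the segmentation stage must cope with.

The module also generates the synthetic statistical datasets (rater tables
with controlled variance components, correlated measurement pairs) used to
exercise the reliability statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .anthropometry import LandmarkSet
from .partition import PartitionRules, Plane, Region
from .segmentation import HUVolume
from .stats import MeasurementTable

__all__ = [
    "Material",
    "Sphere",
    "Dome",
    "Ellipsoid",
    "Cylinder",
    "Box",
    "PhantomSpec",
    "PhantomTruth",
    "BubblePlacementError",
    "generate_oral_phantom",
    "oral_cavity_layout",
    "synthetic_head_landmarks",
    "generate_rater_table",
    "generate_correlated_pairs",
    "DEFAULT_HU_TABLE",
]


class Material(IntEnum):
    AIR = 0
    STYROFOAM = 1
    SOFT_TISSUE = 2
    BONE = 3


DEFAULT_HU_TABLE: dict[Material, float] = {
    Material.AIR: -1000.0,
    Material.STYROFOAM: -980.0,
    Material.SOFT_TISSUE: 40.0,
    Material.BONE: 1200.0,
}

#: region code used in the voxel label grid for "no region"
NO_REGION = -1


@dataclass(frozen=True)
class _Primitive:
    center: tuple[float, float, float]
    material: Material = Material.SOFT_TISSUE
    region: Region | None = None

    def _c(self) -> np.ndarray:
        return np.asarray(self.center, dtype=np.float64)


@dataclass(frozen=True)
class Sphere(_Primitive):
    radius: float = 1.0

    def contains(self, x, y, z):
        c = self._c()
        return (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= self.radius**2

    def inner_margin(self, p) -> float:
        return self.radius - float(np.linalg.norm(np.asarray(p) - self._c()))

    @property
    def surface_area_mm2(self) -> float:
        return 4.0 * np.pi * self.radius**2

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def bounds(self):
        c = self._c()
        return c - self.radius, c + self.radius


@dataclass(frozen=True)
class Dome(_Primitive):
    """Solid hemisphere: flat base at z = center_z, dome toward +z."""

    radius: float = 1.0

    def contains(self, x, y, z):
        c = self._c()
        inside_sphere = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= self.radius**2
        return inside_sphere & (z >= c[2])

    def inner_margin(self, p) -> float:
        p = np.asarray(p, dtype=float)
        c = self._c()
        return min(self.radius - float(np.linalg.norm(p - c)), float(p[2] - c[2]))

    @property
    def surface_area_mm2(self) -> float:
        # curved cap 2*pi*r^2 plus flat base pi*r^2
        return 3.0 * np.pi * self.radius**2

    @property
    def volume_mm3(self) -> float:
        return 2.0 / 3.0 * np.pi * self.radius**3

    def bounds(self):
        c = self._c()
        return c - (self.radius, self.radius, 0.0), c + self.radius


@dataclass(frozen=True)
class Ellipsoid(_Primitive):
    semi_axes: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def contains(self, x, y, z):
        c = self._c()
        a, b, cc = self.semi_axes
        return ((x - c[0]) / a) ** 2 + ((y - c[1]) / b) ** 2 + ((z - c[2]) / cc) ** 2 <= 1.0

    def inner_margin(self, p) -> float:
        p = np.asarray(p, dtype=float)
        ax = np.asarray(self.semi_axes)
        q = float(np.sqrt(np.sum(((p - self._c()) / ax) ** 2)))
        return (1.0 - q) * float(ax.min())

    @property
    def surface_area_mm2(self) -> float:
        # Thomsen approximation (p = 1.6075), relative error < 1.1%
        a, b, c = self.semi_axes
        p = 1.6075
        s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
        return 4.0 * np.pi * s ** (1.0 / p)

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def bounds(self):
        c = self._c()
        ax = np.asarray(self.semi_axes)
        return c - ax, c + ax


@dataclass(frozen=True)
class Cylinder(_Primitive):
    """Axis-aligned right circular cylinder."""

    radius: float = 1.0
    height: float = 1.0
    axis: int = 2  # 0=x, 1=y, 2=z

    def contains(self, x, y, z):
        c = self._c()
        coords = [x - c[0], y - c[1], z - c[2]]
        along = coords.pop(self.axis)
        return (coords[0] ** 2 + coords[1] ** 2 <= self.radius**2) & (
            np.abs(along) <= self.height / 2.0
        )

    def inner_margin(self, p) -> float:
        d = np.asarray(p, dtype=float) - self._c()
        along = d[self.axis]
        radial = np.delete(d, self.axis)
        return min(self.radius - float(np.linalg.norm(radial)), self.height / 2.0 - abs(along))

    @property
    def surface_area_mm2(self) -> float:
        return 2.0 * np.pi * self.radius * (self.radius + self.height)

    @property
    def volume_mm3(self) -> float:
        return np.pi * self.radius**2 * self.height

    def bounds(self):
        half = np.full(3, self.radius)
        half[self.axis] = self.height / 2.0
        c = self._c()
        return c - half, c + half


@dataclass(frozen=True)
class Box(_Primitive):
    size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def contains(self, x, y, z):
        c = self._c()
        s = np.asarray(self.size) / 2.0
        return (
            (np.abs(x - c[0]) <= s[0]) & (np.abs(y - c[1]) <= s[1]) & (np.abs(z - c[2]) <= s[2])
        )

    def inner_margin(self, p) -> float:
        d = np.abs(np.asarray(p, dtype=float) - self._c())
        return float((np.asarray(self.size) / 2.0 - d).min())

    @property
    def surface_area_mm2(self) -> float:
        a, b, c = self.size
        return 2.0 * (a * b + b * c + c * a)

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.size))

    def bounds(self):
        c = self._c()
        s = np.asarray(self.size) / 2.0
        return c - s, c + s


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a voxel phantom; see the module docstring for semantics."""

    grid_shape: tuple[int, int, int]
    voxel_spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    primitives: tuple = ()
    hu_table: dict = field(default_factory=lambda: dict(DEFAULT_HU_TABLE))
    bubble_count: int = 0
    bubble_radius_mm: float = 0.5
    noise_sd_hu: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "primitives", tuple(self.primitives))
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if self.bubble_count < 0:
            raise ValueError("bubble_count must be non-negative")
        if self.bubble_radius_mm <= 0:
            raise ValueError("bubble_radius_mm must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        table = {Material(k): float(v) for k, v in self.hu_table.items()}
        object.__setattr__(self, "hu_table", table)
        if table[Material.SOFT_TISSUE] < -300 or table[Material.BONE] < 350:
            raise ValueError(
                "hu_table must keep soft tissue >= -300 HU and bone >= 350 HU so the "
                "segmentation thresholds separate the materials"
            )
        lo = np.asarray(self.origin_mm, dtype=float)
        hi = lo + (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_spacing_mm)
        for i, prim in enumerate(self.primitives):
            p_lo, p_hi = prim.bounds()
            if np.any(p_lo < lo) or np.any(p_hi > hi):
                raise ValueError(
                    f"primitive #{i} ({type(prim).__name__} at {prim.center}) extends "
                    f"outside the grid [{lo.tolist()} .. {hi.tolist()}]"
                )


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth accompanying a generated phantom."""

    region_area_cm2: dict[str, float]
    material_labels: np.ndarray  # uint8 grid of Material codes
    region_labels: np.ndarray  # int8 grid of Region codes, NO_REGION for background
    landmarks: LandmarkSet
    seed: int
    bubble_centers_mm: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))


class BubblePlacementError(RuntimeError):
    pass


def _world_axes(spec: PhantomSpec):
    sp = np.asarray(spec.voxel_spacing_mm)
    org = np.asarray(spec.origin_mm)
    return [org[a] + np.arange(spec.grid_shape[a]) * sp[a] for a in range(3)]


def _paint(spec: PhantomSpec, prim, material_grid, region_grid, axes) -> None:
    sp = np.asarray(spec.voxel_spacing_mm)
    org = np.asarray(spec.origin_mm)
    lo, hi = prim.bounds()
    i0 = np.maximum(np.floor((lo - org) / sp).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - org) / sp).astype(int) + 1, spec.grid_shape)
    if np.any(i0 >= i1):
        return
    sub = tuple(slice(a, b) for a, b in zip(i0, i1))
    x = axes[0][sub[0]][:, None, None]
    y = axes[1][sub[1]][None, :, None]
    z = axes[2][sub[2]][None, None, :]
    hit = prim.contains(x, y, z)
    material_grid[sub][hit] = int(prim.material)
    region_grid[sub][hit] = NO_REGION if prim.region is None else int(prim.region)


def _place_bubbles(spec: PhantomSpec, rng, material_grid, region_grid, axes) -> np.ndarray:
    """Carve air bubbles strictly inside soft-tissue primitives."""
    soft = [p for p in spec.primitives if p.material == Material.SOFT_TISSUE]
    if not soft:
        raise BubblePlacementError("bubbles requested but the spec has no soft-tissue primitive")
    max_sp = float(max(spec.voxel_spacing_mm))
    clearance = spec.bubble_radius_mm + 2.0 * max_sp  # stay clear of the surface
    min_sep = 2.0 * spec.bubble_radius_mm + 2.0 * max_sp  # keep bubbles disjoint
    weights = np.array([p.volume_mm3 for p in soft])
    weights = weights / weights.sum()
    centers: list[np.ndarray] = []
    for _ in range(spec.bubble_count):
        for _attempt in range(1000):
            prim = soft[rng.choice(len(soft), p=weights)]
            lo, hi = prim.bounds()
            cand = rng.uniform(lo, hi)
            if prim.inner_margin(cand) < clearance:
                continue
            if centers and np.min(np.linalg.norm(np.array(centers) - cand, axis=1)) < min_sep:
                continue
            centers.append(cand)
            break
        else:
            raise BubblePlacementError(
                f"could not place bubble {len(centers) + 1}/{spec.bubble_count} "
                "after 1000 attempts"
            )
    bubble = Sphere(center=(0, 0, 0), radius=spec.bubble_radius_mm, material=Material.AIR)
    for c in centers:
        _paint(
            spec,
            Sphere(center=tuple(c), radius=bubble.radius, material=Material.AIR),
            material_grid,
            region_grid,
            axes,
        )
    return np.array(centers) if centers else np.zeros((0, 3))


def generate_oral_phantom(
    spec: PhantomSpec, seed: int, landmarks: LandmarkSet | None = None
) -> tuple[HUVolume, PhantomTruth]:
    """Render a spec to an HU volume plus exact truth.

    Deterministic: identical ``(spec, seed)`` give bit-identical output.
    Voxel membership is by voxel-center inclusion; later primitives
    override earlier ones.
    """
    rng = np.random.default_rng(seed)
    material_grid = np.zeros(spec.grid_shape, dtype=np.uint8)
    region_grid = np.full(spec.grid_shape, NO_REGION, dtype=np.int8)
    axes = _world_axes(spec)
    for prim in spec.primitives:
        _paint(spec, prim, material_grid, region_grid, axes)
    bubble_centers = np.zeros((0, 3))
    if spec.bubble_count > 0:
        bubble_centers = _place_bubbles(spec, rng, material_grid, region_grid, axes)

    hu = np.empty(spec.grid_shape, dtype=np.float32)
    for material, value in spec.hu_table.items():
        hu[material_grid == material] = value
    if spec.noise_sd_hu > 0:
        hu += rng.standard_normal(spec.grid_shape, dtype=np.float32) * np.float32(spec.noise_sd_hu)

    areas = {r.name: 0.0 for r in (Region.PALATE, Region.TONGUE, Region.HARD_TISSUE, Region.MUCOSA)}
    for prim in spec.primitives:
        if prim.region is not None:
            areas[Region(prim.region).name] += prim.surface_area_mm2 / 100.0

    vol = HUVolume(hu, spacing_mm=tuple(spec.voxel_spacing_mm), origin_mm=tuple(spec.origin_mm))
    truth = PhantomTruth(
        region_area_cm2=areas,
        material_labels=material_grid,
        region_labels=region_grid,
        landmarks=landmarks or LandmarkSet({}),
        seed=seed,
        bubble_centers_mm=bubble_centers,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# default oral-cavity layout


def oral_cavity_layout(
    scale: float = 1.0,
    voxel_spacing_mm: float = 0.3,
    bubble_count: int = 20,
    bubble_radius_mm: float = 0.5,
    noise_sd_hu: float = 0.0,
    include_styrofoam: bool = True,
    include_teeth: bool = True,
) -> tuple[PhantomSpec, PartitionRules, LandmarkSet]:
    """A disjoint-solid stand-in for a scanned oral cavity.

    Palate: hemispherical dome above the occlusal plane inside the
    maxillary ridge footprint.  Tongue: sphere below it.  Hard tissue: four
    bone 'teeth' spheres at the seed points.  Mucosa: larger sphere outside
    both ridge footprints, anterior but inside the lip-crease clip.  A
    styrofoam separator bar (near-air HU) floats between tongue and palate.
    All solids are mutually disjoint and clear of each other's capture
    radii, so the analytic truth areas are exact and the partition rules
    reproduce the labels.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    s = scale

    def pt(x, y, z):
        return (x * s, y * s, z * s)

    tooth_centers = [pt(12, 30, 24), pt(48, 30, 24), pt(12, 30, 44), pt(48, 30, 44)]
    primitives = [
        Dome(center=pt(30, 26, 38), radius=12 * s, material=Material.SOFT_TISSUE,
             region=Region.PALATE),
        Sphere(center=pt(30, 30, 15), radius=10 * s, material=Material.SOFT_TISSUE,
               region=Region.TONGUE),
        Sphere(center=pt(30, 62, 30), radius=14 * s, material=Material.SOFT_TISSUE,
               region=Region.MUCOSA),
    ]
    if include_teeth:
        primitives += [
            Sphere(center=c, radius=3 * s, material=Material.BONE, region=Region.HARD_TISSUE)
            for c in tooth_centers
        ]
    if include_styrofoam:
        primitives.append(
            Box(center=pt(30, 30, 31.5), size=(24 * s, 8 * s, 3 * s),
                material=Material.STYROFOAM, region=None)
        )

    extent = np.array([60.0, 78.0, 56.0]) * s
    shape = tuple(int(np.ceil(e / voxel_spacing_mm)) + 1 for e in extent)
    spec = PhantomSpec(
        grid_shape=shape,
        voxel_spacing_mm=(voxel_spacing_mm,) * 3,
        primitives=tuple(primitives),
        bubble_count=bubble_count,
        bubble_radius_mm=bubble_radius_mm * s,
        noise_sd_hu=noise_sd_hu,
    )

    ridge = np.array(
        [pt(14, 10, 30), pt(46, 10, 30), pt(46, 42, 30), pt(14, 42, 30)], dtype=float
    )
    rules = PartitionRules(
        occlusal_plane=Plane(point=pt(30, 30, 30), normal=(0, 0, 1)),
        lip_crease_plane=Plane(point=pt(30, 77.5, 30), normal=(0, 1, 0)),
        hamulus_left=pt(14, 8, 34),
        hamulus_right=pt(46, 8, 34),
        maxillary_ridge_curve=ridge,
        mandibular_ridge_curve=ridge.copy(),
        tooth_seeds=np.array(tooth_centers) if include_teeth else np.zeros((0, 3)),
        tooth_capture_radius_mm=6.0 * s,
    )
    landmarks = LandmarkSet(
        {
            "pterygoid_hamulus_left": pt(14, 8, 34),
            "pterygoid_hamulus_right": pt(46, 8, 34),
        }
    )
    return spec, rules, landmarks


_CANONICAL_HEAD_MM: dict[str, tuple[float, float, float]] = {
    "vertex": (0.0, 0.0, 220.0),
    "glabella": (0.0, 95.0, 160.0),
    "subnasale": (0.0, 100.0, 105.0),
    "upper_lip": (0.0, 102.0, 88.0),
    "lower_lip": (0.0, 100.0, 70.0),
    "gnathion": (0.0, 90.0, 40.0),
    "back_of_head": (0.0, -95.0, 150.0),
    "ext_auditory_meatus_left": (75.0, -10.0, 140.0),
    "ext_auditory_meatus_right": (-75.0, -10.0, 140.0),
    "tragus": (-72.0, -5.0, 138.0),
    "chelion_left": (28.0, 92.0, 88.0),
    "chelion_right": (-28.0, 92.0, 88.0),
    "molar_16": (-21.5, 60.0, 95.0),
    "molar_26": (21.5, 60.0, 95.0),
    "pterygoid_hamulus_left": (18.0, 30.0, 95.0),
    "pterygoid_hamulus_right": (-18.0, 30.0, 95.0),
}


def synthetic_head_landmarks(seed: int | None = None, jitter_mm: float = 0.0) -> LandmarkSet:
    """Plausible full head landmark set, optionally jittered (measurement noise)."""
    points = {k: np.asarray(v, dtype=float) for k, v in _CANONICAL_HEAD_MM.items()}
    if jitter_mm > 0:
        rng = np.random.default_rng(seed)
        points = {k: v + rng.normal(0.0, jitter_mm, 3) for k, v in points.items()}
    return LandmarkSet(points)


# ---------------------------------------------------------------------------
# synthetic statistical datasets


def generate_rater_table(
    n_subjects: int,
    variance_components: tuple[float, float, float],
    n_raters: int = 2,
    seed: int = 0,
    mean: float = 10.0,
) -> MeasurementTable:
    """Two-way crossed design: value[i, j] = mean + subject_i + rater_j + error_ij.

    With variances (s2, r2, e2) the population absolute-agreement
    average-measures ICC over k raters is s2 / (s2 + (r2 + e2) / k).
    """
    s2, r2, e2 = variance_components
    if min(s2, r2, e2) < 0:
        raise ValueError("variance components must be non-negative")
    if s2 <= 0:
        raise ValueError("subject variance must be positive")
    if n_subjects < 2 or n_raters < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, np.sqrt(s2), size=(n_subjects, 1))
    rater = rng.normal(0.0, np.sqrt(r2), size=(1, n_raters))
    err = rng.normal(0.0, np.sqrt(e2), size=(n_subjects, n_raters))
    return MeasurementTable(values=mean + subj + rater + err, column_kind="rater")


def generate_correlated_pairs(
    n: int, r_target: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate standard-normal sample with population correlation ``r_target``."""
    if not -1.0 <= r_target <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r_target}")
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, r_target * z1 + np.sqrt(1.0 - r_target**2) * z2
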