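"""Landmark-driven partition of the intra-oral surface mesh into four regions.

The regions — hard palate, tongue, hard tissue (crowns and alveoli) and
remaining mucosa — are carved out of the triangle mesh by deterministic
geometric rules: side of the occlusal plane, containment in the top-view
polygon of an alveolar ridge curve, the trans-hamular boundary, and
proximity to tooth seed points.  Faces are assigned by centroid with
precedence HARD_TISSUE > PALATE > TONGUE > MUCOSA; remaining faces beyond
the lip-crease plane are EXCLUDED from the intra-oral total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
from matplotlib.path import Path as PolyPath

from .meshing import TriangleMesh, extract_isosurface, flat_fill_holes, mesh_area
from .segmentation import HUVolume, SegmentationConfig, segment_pipeline

__all__ = [
    "Region",
    "Plane",
    "PartitionRules",
    "RegionLabeling",
    "AreaReport",
    "partition_regions",
    "region_areas",
    "run_pipeline",
]


class Region(IntEnum):
    PALATE = 0
    TONGUE = 1
    HARD_TISSUE = 2
    MUCOSA = 3
    EXCLUDED = 4


INTRAORAL_REGIONS = (Region.PALATE, Region.TONGUE, Region.HARD_TISSUE, Region.MUCOSA)


@dataclass(frozen=True)
class Plane:
    """Oriented plane: a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        point = np.asarray(self.point, dtype=np.float64).reshape(3)
        normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(normal)
        if norm == 0:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "normal", normal / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def translated(self, offset) -> "Plane":
        return Plane(self.point + np.asarray(offset, dtype=float), self.normal)


def _as_curve(points) -> np.ndarray:
    arr = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(arr) < 3:
        raise ValueError("ridge curve needs at least 3 points")
    return arr


@dataclass(frozen=True)
class PartitionRules:
    """Geometric inputs of the four-region partition.

    ``occlusal_plane.normal`` points toward the maxilla (superior);
    ``lip_crease_plane.normal`` points anteriorly out of the mouth — faces
    beyond it are excluded.  Ridge curves are ordered point loops whose
    top-view projections bound the palate and tongue; the pterygoid hamuli
    set the posterior limit of both.
    """

    occlusal_plane: Plane
    lip_crease_plane: Plane
    hamulus_left: np.ndarray | None = None
    hamulus_right: np.ndarray | None = None
    maxillary_ridge_curve: np.ndarray | None = None
    mandibular_ridge_curve: np.ndarray | None = None
    tooth_seeds: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    tooth_capture_radius_mm: float = 6.0

    def __post_init__(self) -> None:
        for name in ("hamulus_left", "hamulus_right"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=np.float64).reshape(3))
        if self.hamulus_left is not None and self.hamulus_right is not None:
            if np.allclose(self.hamulus_left, self.hamulus_right):
                raise ValueError("the two hamulus points must be distinct")
        for name in ("maxillary_ridge_curve", "mandibular_ridge_curve"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _as_curve(v))
        seeds = np.asarray(self.tooth_seeds, dtype=np.float64).reshape(-1, 3)
        object.__setattr__(self, "tooth_seeds", seeds)
        if self.tooth_capture_radius_mm <= 0:
            raise ValueError("tooth capture radius must be positive")

    def translated(self, offset) -> "PartitionRules":
        off = np.asarray(offset, dtype=float)
        return replace(
            self,
            occlusal_plane=self.occlusal_plane.translated(off),
            lip_crease_plane=self.lip_crease_plane.translated(off),
            hamulus_left=None if self.hamulus_left is None else self.hamulus_left + off,
            hamulus_right=None if self.hamulus_right is None else self.hamulus_right + off,
            maxillary_ridge_curve=(
                None if self.maxillary_ridge_curve is None else self.maxillary_ridge_curve + off
            ),
            mandibular_ridge_curve=(
                None if self.mandibular_ridge_curve is None else self.mandibular_ridge_curve + off
            ),
            tooth_seeds=self.tooth_seeds + off if len(self.tooth_seeds) else self.tooth_seeds,
        )

    def to_json(self, path: str | Path) -> None:
        def conv(v):
            return None if v is None else np.asarray(v).tolist()

        payload = {
            "occlusal_plane": {
                "point": conv(self.occlusal_plane.point),
                "normal": conv(self.occlusal_plane.normal),
            },
            "lip_crease_plane": {
                "point": conv(self.lip_crease_plane.point),
                "normal": conv(self.lip_crease_plane.normal),
            },
            "hamulus_left": conv(self.hamulus_left),
            "hamulus_right": conv(self.hamulus_right),
            "maxillary_ridge_curve": conv(self.maxillary_ridge_curve),
            "mandibular_ridge_curve": conv(self.mandibular_ridge_curve),
            "tooth_seeds": conv(self.tooth_seeds),
            "tooth_capture_radius_mm": self.tooth_capture_radius_mm,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PartitionRules":
        d = json.loads(Path(path).read_text())
        return cls(
            occlusal_plane=Plane(**d["occlusal_plane"]),
            lip_crease_plane=Plane(**d["lip_crease_plane"]),
            hamulus_left=d.get("hamulus_left"),
            hamulus_right=d.get("hamulus_right"),
            maxillary_ridge_curve=d.get("maxillary_ridge_curve"),
            mandibular_ridge_curve=d.get("mandibular_ridge_curve"),
            tooth_seeds=d.get("tooth_seeds") or np.zeros((0, 3)),
            tooth_capture_radius_mm=d.get("tooth_capture_radius_mm", 6.0),
        )


@dataclass(frozen=True)
class RegionLabeling:
    """One region label per mesh face."""

    face_region: np.ndarray  # (m,) int codes from Region

    def __post_init__(self) -> None:
        arr = np.asarray(self.face_region, dtype=np.int8)
        valid = set(int(r) for r in Region)
        if arr.size and not set(np.unique(arr)).issubset(valid):
            raise ValueError("labels outside the five-region set")
        object.__setattr__(self, "face_region", arr)

    def faces_of(self, region: Region) -> np.ndarray:
        return np.flatnonzero(self.face_region == region)

    def counts(self) -> dict[str, int]:
        return {r.name: int((self.face_region == r).sum()) for r in Region}


def _projection_basis(normal: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane orthogonal to ``normal``."""
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.stack([u, v])


def partition_regions(mesh: TriangleMesh, rules: PartitionRules) -> RegionLabeling:
    """Assign every face to exactly one of the five region labels.

    'Top view' is the orthographic projection along the occlusal-plane
    normal.  The posterior limit of palate and tongue is the top-view line
    through the two hamuli; 'anterior' is the side containing the centroid
    of the corresponding ridge curve.
    """
    if mesh.n_faces == 0:
        raise ValueError("cannot partition an empty mesh")
    want_palate = rules.maxillary_ridge_curve is not None
    want_tongue = rules.mandibular_ridge_curve is not None
    if (want_palate or want_tongue) and (rules.hamulus_left is None or rules.hamulus_right is None):
        raise ValueError("palate/tongue rules require both pterygoid hamulus points")

    centroids = mesh.face_centroids()
    occl = rules.occlusal_plane
    maxillary_side = occl.signed_distance(centroids) > 0
    basis = _projection_basis(occl.normal)
    uv = centroids @ basis.T

    labels = np.full(mesh.n_faces, Region.MUCOSA, dtype=np.int8)

    if want_palate or want_tongue:
        h1 = (rules.hamulus_left @ basis.T).ravel()
        h2 = (rules.hamulus_right @ basis.T).ravel()
        d = h2 - h1

        def cross2(q):  # z-component of the 2-D cross product d x q
            return d[0] * (q[..., 1] - h1[1]) - d[1] * (q[..., 0] - h1[0])

        side = cross2(uv)

        def anterior_of_hamuli(curve: np.ndarray) -> np.ndarray:
            ref_side = float(cross2(curve.mean(axis=0) @ basis.T))
            if ref_side == 0:
                raise ValueError("ridge curve centroid lies on the trans-hamular line")
            return side * np.sign(ref_side) >= 0

    if want_tongue:
        poly = PolyPath(rules.mandibular_ridge_curve @ basis.T)
        inside = poly.contains_points(uv)
        labels[~maxillary_side & inside & anterior_of_hamuli(rules.mandibular_ridge_curve)] = (
            Region.TONGUE
        )
    if want_palate:
        poly = PolyPath(rules.maxillary_ridge_curve @ basis.T)
        inside = poly.contains_points(uv)
        labels[maxillary_side & inside & anterior_of_hamuli(rules.maxillary_ridge_curve)] = (
            Region.PALATE
        )
    if len(rules.tooth_seeds):
        diff = centroids[:, None, :] - rules.tooth_seeds[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
        labels[dist <= rules.tooth_capture_radius_mm] = Region.HARD_TISSUE

    remaining = labels == Region.MUCOSA
    beyond_lip = rules.lip_crease_plane.signed_distance(centroids) > 0
    labels[remaining & beyond_lip] = Region.EXCLUDED
    return RegionLabeling(labels)


@dataclass(frozen=True)
class AreaReport:
    """Per-region areas in cm^2; total covers the four intra-oral regions."""

    region_area_cm2: dict[str, float]
    excluded_cm2: float
    total_cm2: float
    parameters: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "region_area_cm2": dict(self.region_area_cm2),
            "excluded_cm2": self.excluded_cm2,
            "total_cm2": self.total_cm2,
            "parameters": self.parameters,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        lines = ["region,area_cm2"]
        for name, area in self.region_area_cm2.items():
            lines.append(f"{name},{area:.6f}")
        lines.append(f"EXCLUDED,{self.excluded_cm2:.6f}")
        lines.append(f"TOTAL,{self.total_cm2:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def region_areas(
    mesh: TriangleMesh, labeling: RegionLabeling, parameters: dict | None = None
) -> AreaReport:
    """Sum face areas per region; total is the sum of the four intra-oral regions."""
    if len(labeling.face_region) != mesh.n_faces:
        raise ValueError(
            f"labeling covers {len(labeling.face_region)} faces, mesh has {mesh.n_faces}"
        )
    areas = {}
    for region in INTRAORAL_REGIONS:
        areas[region.name] = mesh_area(mesh, labeling.faces_of(region))
    excluded = mesh_area(mesh, labeling.faces_of(Region.EXCLUDED))
    return AreaReport(
        region_area_cm2=areas,
        excluded_cm2=excluded,
        total_cm2=float(sum(areas.values())),
        parameters=parameters or {},
    )


def run_pipeline(
    vol: HUVolume,
    rules: PartitionRules,
    cfg: SegmentationConfig | None = None,
    fill_max_boundary_mm: float = 100.0,
    isosurface_sigma_voxels: float = 1.0,
) -> AreaReport:
    """End-to-end quantification: segment -> mesh -> flat-fill -> partition -> areas."""
    cfg = cfg or SegmentationConfig()
    soft_mask, bone_mask = segment_pipeline(vol, cfg)
    mesh = extract_isosurface(soft_mask, smooth_sigma_voxels=isosurface_sigma_voxels)
    if mesh.n_faces == 0:
        raise ValueError("segmentation produced an empty surface")
    mesh, fill_report = flat_fill_holes(mesh, fill_max_boundary_mm)
    labeling = partition_regions(mesh, rules)
    params = {
        "soft_tissue_threshold_hu": cfg.soft_tissue_threshold_hu,
        "bone_threshold_hu": cfg.bone_threshold_hu,
        "smoothing_sigma_voxels": cfg.smoothing_sigma_voxels,
        "closing_radius_voxels": cfg.closing_radius_voxels,
        "isosurface_sigma_voxels": isosurface_sigma_voxels,
        "fill_max_boundary_mm": fill_max_boundary_mm,
        "holes_filled": fill_report.n_filled,
        "holes_skipped": fill_report.n_skipped,
        "n_faces": mesh.n_faces,
        "bone_mask_voxels": bone_mask.count(),
        "tooth_capture_radius_mm": rules.tooth_capture_radius_mm,
    }
    return region_areas(mesh, labeling, parameters=params)
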