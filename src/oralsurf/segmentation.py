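"""Binary segmentation of Hounsfield-unit volumes.

Turns a CT-style scalar grid into clean binary masks for soft tissue and
bone via thresholding, Gaussian pre-smoothing and morphological closing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "HUVolume",
    "BinaryMask",
    "SegmentationConfig",
    "threshold_segment",
    "smooth_volume",
    "morphological_close",
    "segment_pipeline",
    "ball_element",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
]

# Conventional HU anchors
HU_AIR = -1000.0
SOFT_TISSUE_HU_THRESHOLD = -300.0
BONE_HU_THRESHOLD = 350.0


@dataclass(frozen=True)
class HUVolume:
    """3-D scalar grid of Hounsfield units with geometry metadata.

    Axis order is (x, y, z) with x = left->right, y = posterior->anterior,
    z = inferior->superior; world coordinate of voxel (i, j, k) is
    ``origin_mm + (i, j, k) * spacing_mm``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError(f"HU volume must be 3-D, got shape {data.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing_mm}")
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("HU volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class BinaryMask:
    """Boolean voxel grid sharing geometry with its source volume.

    ``provenance`` records the threshold and every operation applied, in
    order, so a mask is self-describing.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "provenance", tuple(self.provenance))
        if data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {data.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the two-threshold segmentation pipeline."""

    soft_tissue_threshold_hu: float = SOFT_TISSUE_HU_THRESHOLD
    bone_threshold_hu: float = BONE_HU_THRESHOLD
    smoothing_sigma_voxels: float = 0.5
    closing_radius_voxels: int = 2
    #: smooth the binary mask (as a float field, re-thresholded at 0.5)
    #: instead of the gray volume; off by default.
    smooth_mask_instead: bool = False

    def __post_init__(self) -> None:
        if self.bone_threshold_hu <= self.soft_tissue_threshold_hu:
            raise ValueError(
                "bone threshold must exceed soft-tissue threshold: "
                f"{self.bone_threshold_hu} <= {self.soft_tissue_threshold_hu}"
            )
        if self.smoothing_sigma_voxels < 0:
            raise ValueError("smoothing sigma must be non-negative")
        if self.closing_radius_voxels < 0:
            raise ValueError("closing radius must be non-negative")


def threshold_segment(vol: HUVolume, threshold_hu: float) -> BinaryMask:
    """Binarize a volume: voxel is foreground iff HU >= ``threshold_hu``.

    The comparison is inclusive; geometry metadata is carried over.
    """
    if vol.data.size == 0:
        raise ValueError("cannot threshold an empty volume")
    return BinaryMask(
        data=vol.data >= threshold_hu,
        spacing_mm=vol.spacing_mm,
        origin_mm=vol.origin_mm,
        provenance=(f"threshold(hu>={threshold_hu:g})",),
    )


def smooth_volume(vol: HUVolume, sigma_voxels: float) -> HUVolume:
    """Gaussian low-pass of the HU grid; ``sigma_voxels == 0`` is identity."""
    if sigma_voxels < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma_voxels}")
    if sigma_voxels == 0:
        return vol
    smoothed = ndimage.gaussian_filter(vol.data.astype(np.float32), sigma=sigma_voxels)
    return replace(vol, data=smoothed)


def ball_element(radius: int) -> np.ndarray:
    """Discrete ball structuring element: voxels with center distance <= radius."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    grid = np.mgrid[-radius : radius + 1, -radius : radius + 1, -radius : radius + 1]
    return (grid**2).sum(axis=0) <= radius**2


def morphological_close(mask: BinaryMask, radius_voxels: int) -> BinaryMask:
    """Closing with a ball element: dilation then erosion, radius 0 is identity.

    The grid is padded by the radius before dilating so the operation is
    the true closing on an unbounded domain (extensive everywhere,
    including at the array border).
    """
    if radius_voxels < 0:
        raise ValueError("closing radius must be non-negative")
    if radius_voxels == 0 or mask.data.size == 0:
        return replace(mask, provenance=mask.provenance + (f"close(r={radius_voxels})",))
    r = int(radius_voxels)
    structure = ball_element(r)
    padded = np.pad(mask.data, r, mode="constant", constant_values=False)
    dilated = ndimage.binary_dilation(padded, structure=structure)
    closed = ndimage.binary_erosion(dilated, structure=structure, border_value=True)
    closed = closed[r:-r, r:-r, r:-r]
    return replace(mask, data=closed, provenance=mask.provenance + (f"close(r={r})",))


def _smooth_mask(mask: BinaryMask, sigma_voxels: float) -> BinaryMask:
    if sigma_voxels == 0:
        return mask
    field_ = ndimage.gaussian_filter(mask.data.astype(np.float32), sigma=sigma_voxels)
    return replace(
        mask,
        data=field_ >= 0.5,
        provenance=mask.provenance + (f"mask_smooth(sigma={sigma_voxels:g})",),
    )


def segment_pipeline(vol: HUVolume, cfg: SegmentationConfig) -> tuple[BinaryMask, BinaryMask]:
    """Full segmentation: smooth -> threshold (soft, bone) -> close.

    Returns ``(soft_mask, bone_mask)``.  The soft mask is everything at or
    above the soft-tissue threshold (tissue plus bone), the bone mask only
    voxels at or above the bone threshold.
    """
    sigma = cfg.smoothing_sigma_voxels
    src = vol if cfg.smooth_mask_instead else smooth_volume(vol, sigma)
    masks = []
    for threshold in (cfg.soft_tissue_threshold_hu, cfg.bone_threshold_hu):
        mask = threshold_segment(src, threshold)
        if cfg.smooth_mask_instead:
            mask = _smooth_mask(mask, sigma)
        elif sigma > 0:
            mask = replace(mask, provenance=(f"smooth(sigma={sigma:g})",) + mask.provenance)
        masks.append(morphological_close(mask, cfg.closing_radius_voxels))
    return masks[0], masks[1]


# ---------------------------------------------------------------------------
# raw-grid + JSON sidecar serialization


def _write_sidecar(path: Path, array: np.ndarray, spacing, origin, extra=None) -> None:
    meta = {
        "shape": list(array.shape),
        "dtype": str(array.dtype),
        "spacing_mm": list(spacing),
        "origin_mm": list(origin),
    }
    meta.update(extra or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    array.tofile(path)


def _read_sidecar(path: Path) -> tuple[np.ndarray, dict]:
    meta = json.loads(path.with_suffix(".json").read_text())
    array = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    return array, meta


def save_volume(vol: HUVolume, path: str | Path) -> None:
    _write_sidecar(Path(path), vol.data, vol.spacing_mm, vol.origin_mm)


def load_volume(path: str | Path) -> HUVolume:
    array, meta = _read_sidecar(Path(path))
    return HUVolume(array, tuple(meta["spacing_mm"]), tuple(meta["origin_mm"]))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    _write_sidecar(
        Path(path),
        mask.data.astype(np.uint8),
        mask.spacing_mm,
        mask.origin_mm,
        extra={"provenance": list(mask.provenance)},
    )


def load_mask(path: str | Path) -> BinaryMask:
    array, meta = _read_sidecar(Path(path))
    return BinaryMask(
        array.astype(bool),
        tuple(meta["spacing_mm"]),
        tuple(meta["origin_mm"]),
        provenance=tuple(meta.get("provenance", ())),
    )
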