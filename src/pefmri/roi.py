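"""Region-of-interest construction and mean-signal extraction.

Two ROI kinds cover the analysis: a sphere specified in world (MNI, mm)
coordinates — by convention a 14 mm-radius anterior-cingulate sphere at
(0, 42, 18) — and a binary or probabilistic mask volume such as an
atlas-defined nucleus accumbens. Distances are measured in world space
through the image affine, never in voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

__all__ = ["RoiSpec", "sphere_mask", "load_mask", "extract_mean"]


@dataclass(frozen=True)
class RoiSpec:
    """Declarative ROI: either a world-space sphere or a mask file.

    ``radius_is_diameter`` reinterprets ``radius_mm`` as a diameter for
    sphere specs written that way. ``threshold`` binarizes probabilistic
    masks (values > threshold are in).
    """

    name: str
    kind: str  # "sphere" | "mask"
    center_mm: Optional[Tuple[float, float, float]] = None
    radius_mm: Optional[float] = None
    mask_path: Optional[str] = None
    threshold: float = 0.5
    radius_is_diameter: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "mask"):
            raise ValueError("kind must be 'sphere' or 'mask'")
        if self.kind == "sphere":
            if self.center_mm is None or self.radius_mm is None:
                raise ValueError("sphere ROI needs center_mm and radius_mm")
            if self.radius_mm <= 0:
                raise ValueError("radius must be positive")
        elif self.mask_path is None:
            raise ValueError("mask ROI needs mask_path")

    @property
    def effective_radius_mm(self) -> float:
        r = float(self.radius_mm)
        return r / 2.0 if self.radius_is_diameter else r


def sphere_mask(
    spec: RoiSpec, affine: np.ndarray, shape: Tuple[int, int, int]
) -> np.ndarray:
    """Binary volume of voxels whose world-space centers lie within the sphere."""
    if spec.kind != "sphere":
        raise ValueError("spec is not a sphere")
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(world - np.asarray(spec.center_mm), axis=1)
    mask = (dist <= spec.effective_radius_mm).reshape(shape)
    if not mask.any():
        raise ValueError(f"sphere ROI {spec.name!r} is empty on this grid")
    return mask


def load_mask(spec: RoiSpec, reference: Optional[nib.Nifti1Image] = None) -> np.ndarray:
    """Load and binarize a mask volume, checking grid agreement with a reference."""
    if spec.kind != "mask":
        raise ValueError("spec is not a mask")
    img = nib.load(spec.mask_path)
    if reference is not None:
        if img.shape[:3] != reference.shape[:3] or not np.allclose(
            img.affine, reference.affine, atol=1e-4
        ):
            raise ValueError("mask and reference volumes are on different grids")
    return np.asarray(img.get_fdata()) > spec.threshold


def extract_mean(volume: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """Mean of in-mask voxels; NaN voxels excluded from the mean.

    Returns ``(mean, n_nan_excluded)``.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    vals = volume[mask]
    n_nan = int(np.isnan(vals).sum())
    if vals.size - n_nan == 0:
        raise ValueError("no finite voxels in mask")
    return float(np.nanmean(vals)), n_nan
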