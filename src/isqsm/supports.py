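"""Image-space and frequency-space supports for incomplete-spectrum QSM.

The method needs two binary supports: the image-space mask S_χ containing
the susceptibility sources (the brain mask, satisfying S_χ χ = χ), and the
frequency-space band limit S_k retaining only the "well-posed" samples where
the dipole kernel magnitude exceeds a threshold t_well.  A single threshold
is used — no transition band between well- and ill-posed regions.

Because |D| = 0 at zero frequency, the band limit always excludes the k = 0
sample for any t_well > 0: the reconstruction recovers the volume mean
through the image-space support constraint instead.  This is documented
behavior, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dipole import DipoleKernelSpectrum, LocalFieldMap, VolumeGrid, _check_same_grid
from .errors import ValidationError

__all__ = [
    "ImageSupport",
    "KSpaceSupport",
    "band_limit",
    "ball_structuring_element",
    "morph_mask",
    "validate_support_consistency",
]


@dataclass
class ImageSupport:
    """Binary image-space mask S_χ (brain mask)."""

    grid: VolumeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.shape:
            raise ValidationError(
                f"mask shape {vals.shape} != grid shape {self.grid.shape}"
            )
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("mask values must be binary (0/1)")
        self.values = vals.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class KSpaceSupport:
    """Binary frequency-space band limit S_k in FFT layout.

    ``t_well`` records the kernel-magnitude threshold that generated it.
    """

    grid: VolumeGrid
    values: np.ndarray = field(repr=False)
    t_well: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.shape:
            raise ValidationError(
                f"support shape {vals.shape} != grid shape {self.grid.shape}"
            )
        self.values = vals.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def fraction(self) -> float:
        return self.values.mean()


def band_limit(kernel: DipoleKernelSpectrum, t_well: float) -> KSpaceSupport:
    """Well-posed frequency support: samples with |D| strictly above t_well.

    Strict inequality means thresholding at max|D| yields an all-zero
    support, and t_well = 0 keeps exactly the samples where D ≠ 0 (the
    magic-angle cone and k = 0 are always excluded).
    """
    if t_well < 0:
        raise ValidationError(f"t_well must be non-negative, got {t_well}")
    return KSpaceSupport(
        grid=kernel.grid, values=np.abs(kernel.values) > t_well, t_well=float(t_well)
    )


def ball_structuring_element(diameter: int) -> np.ndarray:
    """Discrete ball: integer offsets with Euclidean norm ≤ diameter/2.

    Diameter 1 is a single voxel; diameter 3 is the 19-voxel ball.
    """
    if diameter < 1:
        raise ValidationError(f"diameter must be >= 1, got {diameter}")
    r = diameter / 2.0
    n = int(np.floor(r))
    ax = np.arange(-n, n + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (ox**2 + oy**2 + oz**2) <= r**2 + 1e-12


def morph_mask(mask: ImageSupport, diameter: int, mode: str) -> ImageSupport:
    """Erode or dilate a mask with a spherical kernel of the given diameter.

    An erosion that empties the mask returns the (empty) result with a
    warning rather than raising.
    """
    if mode not in ("erode", "dilate"):
        raise ValidationError(f"mode must be 'erode' or 'dilate', got {mode!r}")
    selem = ball_structuring_element(diameter)
    op = ndimage.binary_erosion if mode == "erode" else ndimage.binary_dilation
    out = op(mask.values.astype(bool), structure=selem)
    if mode == "erode" and not out.any():
        warnings.warn(
            f"erosion with diameter {diameter} emptied the mask", RuntimeWarning
        )
    return ImageSupport(grid=mask.grid, values=out.astype(np.uint8))


def validate_support_consistency(
    field_map: LocalFieldMap, mask: ImageSupport
) -> tuple[LocalFieldMap, float]:
    """Mask the input field with S_χ, as the inversion assumes (S_χ χ = χ).

    Returns the masked field and the fraction of field energy that lay
    outside the mask before masking (0 for an already-consistent input).
    """
    _check_same_grid(field_map.grid, mask.grid)
    total = float(np.sum(field_map.values**2))
    inside = float(np.sum((field_map.values * mask.values) ** 2))
    leak = 0.0 if total == 0 else (total - inside) / total
    return LocalFieldMap(grid=field_map.grid, values=field_map.values * mask.values), leak
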