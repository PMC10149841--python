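"""Synthetic brain-like susceptibility phantom and forward-simulated field.

The phantom emulates the role of a simulated QSM benchmark dataset: a
known, piecewise-constant ground-truth susceptibility distribution inside
an ellipsoidal "head" mask, with bilateral deep-gray-matter nuclei (globus
pallidus, caudate, putamen, red nucleus, thalamus, substantia nigra) at
anatomically plausible relative positions, one small strongly diamagnetic
focal calcification (the classic source of streaking artifacts), an
integer label volume for ROI analysis, and a forward-simulated local field
with additive Gaussian noise at a chosen SNR.

Default χ values are plausible order-of-magnitude settings for iron-rich
nuclei (GP highest, ~0.15 ppm; calcification −1 ppm); they are generator
defaults, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dipole import (
    DipoleKernelSpectrum,
    LocalFieldMap,
    SusceptibilityMap,
    VolumeGrid,
    dipole_kernel,
    forward_field,
)
from .errors import ValidationError
from .supports import ImageSupport

__all__ = [
    "ROI_LABELS",
    "DEFAULT_ROI_VALUES",
    "PhantomSpec",
    "PhantomData",
    "make_phantom",
    "simulate_field",
    "make_default_phantom",
]

# integer label code per structure in the label volume (0 = background)
ROI_LABELS: dict[str, int] = {
    "globus_pallidus": 1,
    "caudate": 2,
    "putamen": 3,
    "red_nucleus": 4,
    "thalamus": 5,
    "substantia_nigra": 6,
    "calcification": 7,
}

# default susceptibility per structure, ppm
DEFAULT_ROI_VALUES: dict[str, float] = {
    "globus_pallidus": 0.15,
    "substantia_nigra": 0.12,
    "red_nucleus": 0.10,
    "putamen": 0.07,
    "caudate": 0.05,
    "thalamus": 0.02,
}

# geometry in fractions of the grid extent: (center offset from grid center,
# ellipsoid semi-axes); bilateral structures are mirrored in the first axis.
# The head fills a modest part of the FOV, as brain masks do in practice.
_STRUCTURES: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "caudate": ((0.082, 0.075, 0.045), (0.026, 0.056, 0.034)),
    "putamen": ((0.142, 0.030, 0.015), (0.034, 0.064, 0.041)),
    "globus_pallidus": ((0.090, 0.015, 0.000), (0.024, 0.038, 0.026)),
    "thalamus": ((0.052, -0.060, 0.015), (0.038, 0.056, 0.041)),
    "red_nucleus": ((0.026, -0.105, -0.045), (0.017, 0.020, 0.020)),
    "substantia_nigra": ((0.045, -0.128, -0.075), (0.023, 0.024, 0.017)),
}
_HEAD_SEMI_AXES = (0.32, 0.35, 0.32)  # fractions of each axis extent
_CALC_CENTER = (0.030, 0.045, 0.195)  # near the top of the "brain"
_CALC_RADIUS = 0.028
_SOURCE_MARGIN_DIAM = 7  # voxels: sources stop short of the mask edge (CSF-like rim)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom.

    ``snr`` is the field-map signal-to-noise ratio: the ratio of the RMS
    noiseless field within the mask to the noise standard deviation
    (np.inf for a noiseless field).
    """

    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid((64, 64, 64)))
    seed: int = 0
    roi_values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROI_VALUES)
    )
    calcification_value: float = -1.0
    background_value: float = 0.0
    texture_sigma_ppm: float = 0.02
    texture_smooth_vox: float = 2.5
    snr: float = 100.0

    def __post_init__(self) -> None:
        missing = set(DEFAULT_ROI_VALUES) - set(self.roi_values)
        if missing:
            raise ValidationError(f"roi_values missing structures: {sorted(missing)}")
        if not (self.snr > 0):
            raise ValidationError(f"snr must be positive (or inf), got {self.snr}")


@dataclass
class PhantomData:
    """Ground truth, mask, labels, and (after simulation) the noisy field."""

    chi_truth: SusceptibilityMap
    mask: ImageSupport
    labels: np.ndarray
    field: LocalFieldMap | None = None
    noise_sigma: float | None = None


def _ellipsoid(grid_shape, center_vox, semi_axes_vox) -> np.ndarray:
    coords = np.meshgrid(*(np.arange(n) for n in grid_shape), indexing="ij", sparse=True)
    q = sum(
        ((c - c0) / a) ** 2 for c, c0, a in zip(coords, center_vox, semi_axes_vox)
    )
    return q <= 1.0


def make_phantom(spec: PhantomSpec | None = None) -> PhantomData:
    """Build the ground-truth susceptibility, head mask, and ROI labels.

    Deterministic given ``spec.seed`` (the seed jitters structure centers
    by up to half a voxel, emulating anatomical variability).  Every
    structure must fall inside the head mask; a spec that pushes one
    outside raises a validation error.
    """
    spec = spec or PhantomSpec()
    shape = np.array(spec.grid.shape, dtype=float)
    center = (shape - 1) / 2.0
    rng = np.random.default_rng(spec.seed)

    mask = _ellipsoid(spec.grid.shape, center, shape * np.array(_HEAD_SEMI_AXES))
    # sources stop a few voxels short of the mask edge, like the low-contrast
    # CSF rim of a real brain mask; masking the input field then removes
    # only far-field tails rather than near-boundary source fields
    from scipy import ndimage

    from .supports import ball_structuring_element

    core = ndimage.binary_erosion(mask, ball_structuring_element(_SOURCE_MARGIN_DIAM))
    chi = np.where(core, spec.background_value, 0.0)
    labels = np.zeros(spec.grid.shape, dtype=np.int16)

    def paint(name: str, region: np.ndarray, value: float) -> None:
        if not region.any():
            raise ValidationError(f"structure {name!r} has no voxels on this grid")
        if (region & ~core).any():
            raise ValidationError(f"structure {name!r} exceeds the head mask interior")
        chi[region] = value
        labels[region] = ROI_LABELS[name]

    for name, (offset, semi) in _STRUCTURES.items():
        for side in (+1, -1):
            off = np.array(offset) * np.array([side, 1.0, 1.0]) * shape
            jitter = rng.uniform(-0.5, 0.5, size=3)
            semi_vox = np.maximum(shape * np.array(semi), 1.0)
            paint(
                name,
                _ellipsoid(spec.grid.shape, center + off + jitter, semi_vox),
                spec.roi_values[name],
            )

    calc_center = center + np.array(_CALC_CENTER) * shape + rng.uniform(-0.5, 0.5, 3)
    r = max(_CALC_RADIUS * shape.min(), 1.5)
    paint(
        "calcification",
        _ellipsoid(spec.grid.shape, calc_center, (r, r, r)),
        spec.calcification_value,
    )

    if spec.texture_sigma_ppm > 0:
        # smooth zero-mean susceptibility texture: tissue is not piecewise
        # constant, and SSIM-family metrics need nonzero local variance in
        # the reference to behave as they do on realistic data
        tex = ndimage.gaussian_filter(
            rng.standard_normal(spec.grid.shape), spec.texture_smooth_vox
        )
        tex *= spec.texture_sigma_ppm / tex[core].std()
        tex -= tex[core].mean()
        chi += tex * core

    return PhantomData(
        chi_truth=SusceptibilityMap(grid=spec.grid, values=chi),
        mask=ImageSupport(grid=spec.grid, values=mask.astype(np.uint8)),
        labels=labels,
    )


def simulate_field(
    phantom: PhantomData,
    kernel: DipoleKernelSpectrum | None = None,
    snr: float = 100.0,
    seed: int = 0,
) -> PhantomData:
    """Forward-simulate the noisy local field for a phantom.

    field = forward(χ) + N(0, σ²) with σ = rms(noiseless field within
    mask)/snr, then masked with the head mask — the same masking the
    inversion assumes on its input.
    """
    if not (snr > 0):
        raise ValidationError(f"snr must be positive (or inf), got {snr}")
    grid = phantom.chi_truth.grid
    kernel = kernel or dipole_kernel(grid)
    clean = forward_field(phantom.chi_truth, kernel).values
    m = phantom.mask.values.astype(bool)
    if np.isinf(snr):
        sigma = 0.0
        noisy = clean
    else:
        sigma = float(np.sqrt(np.mean(clean[m] ** 2)) / snr)
        rng = np.random.default_rng(seed)
        noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
    field_map = LocalFieldMap(grid=grid, values=noisy * phantom.mask.values)
    return replace(phantom, field=field_map, noise_sigma=sigma)


def make_default_phantom(
    size: int = 64, seed: int = 0, snr: float = 100.0
) -> PhantomData:
    """Convenience: default phantom at ``size``³ with a simulated field."""
    spec = PhantomSpec(grid=VolumeGrid((size, size, size)), seed=seed, snr=snr)
    data = make_phantom(spec)
    return simulate_field(data, snr=snr, seed=seed + 1)
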