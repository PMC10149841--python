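"""Dipole forward model for quantitative susceptibility mapping (QSM).

A magnetic susceptibility distribution χ (in ppm) placed in a uniform main
field B0 perturbs the field.  Expressed as a fractional field shift b (also
in ppm), the relation is a convolution with the unit dipole response, which
in the frequency domain is an elementwise product with the kernel

    D(k) = 1/3 - (k·ĥ)² / |k|²,

where ĥ is the unit vector along B0.  D vanishes on the cone at the magic
angle (≈54.7° from ĥ), which is what makes field-to-source inversion
ill-posed.  This module builds D on a discrete grid and applies the forward
model b = F⁻¹ D F χ.

Conventions
-----------
* Unitary FFT (``norm="ortho"``), so the inverse transform is the exact
  adjoint and inverse of the forward transform.
* The kernel is evaluated at discrete frequencies k_i = n_i / (N_i Δ_i)
  (cycles/mm), with anisotropic voxel sizes Δ_i entering per axis; this is
  the continuous (Salomir / Marques–Bowtell) k-space formulation.
* D(0) := 0, so simulated fields have zero mean over the periodic domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, ValidationError

__all__ = [
    "VolumeGrid",
    "SusceptibilityMap",
    "LocalFieldMap",
    "DipoleKernelSpectrum",
    "dipole_kernel",
    "forward_field",
    "fft3",
    "ifft3",
]


def fft3(x: np.ndarray) -> np.ndarray:
    """Unitary 3D forward FFT (F)."""
    return np.fft.fftn(x, norm="ortho")


def ifft3(x: np.ndarray) -> np.ndarray:
    """Unitary 3D inverse FFT (F^H = F^-1)."""
    return np.fft.ifftn(x, norm="ortho")


@dataclass(frozen=True)
class VolumeGrid:
    """Discretization of a 3D volume.

    Parameters
    ----------
    shape
        Number of voxels along each axis (each ≥ 2).
    voxel_size
        Voxel edge lengths in mm (each > 0).  Default 1 mm isotropic.
    b0_dir
        Unit vector along the main magnetic field.  Default third axis.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        b0 = np.asarray(self.b0_dir, dtype=float)
        if len(shape) != 3 or any(n < 2 for n in shape):
            raise ValidationError(f"grid shape must be three integers >= 2, got {self.shape}")
        if len(voxel) != 3 or any(v <= 0 for v in voxel):
            raise ValidationError(f"voxel size entries must be positive, got {self.voxel_size}")
        if b0.shape != (3,) or abs(np.linalg.norm(b0) - 1.0) > 1e-9:
            raise ValidationError(f"b0_dir must be a unit 3-vector, got {self.b0_dir}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        object.__setattr__(self, "b0_dir", tuple(float(c) for c in b0))

    def freq_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Frequency samples per axis in cycles/mm, FFT (unshifted) layout."""
        return tuple(
            np.fft.fftfreq(n, d=d) for n, d in zip(self.shape, self.voxel_size)
        )


def _check_same_grid(a: "VolumeGrid", b: "VolumeGrid") -> None:
    if a.shape != b.shape or a.voxel_size != b.voxel_size:
        raise GridMismatchError(f"grids differ: {a} vs {b}")


@dataclass
class _Volume:
    grid: VolumeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite values")


class SusceptibilityMap(_Volume):
    """3D magnetic susceptibility χ in ppm."""


class LocalFieldMap(_Volume):
    """3D fractional field shift b in ppm (background-field-removed)."""


@dataclass
class DipoleKernelSpectrum:
    """Frequency-domain dipole kernel D (dimensionless), FFT layout.

    Values lie in [-2/3, 1/3]; D(0) = 0; even under negation of any
    frequency axis.
    """

    grid: VolumeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"kernel shape {self.values.shape} != grid shape {self.grid.shape}"
            )


def dipole_kernel(grid: VolumeGrid) -> DipoleKernelSpectrum:
    """Build the frequency-domain dipole kernel on ``grid``.

    D(k) = 1/3 - (k·ĥ)²/|k|² at every nonzero frequency sample, D(0) = 0.
    """
    kx, ky, kz = np.meshgrid(*grid.freq_axes(), indexing="ij", sparse=True)
    h = grid.b0_dir
    k_par = kx * h[0] + ky * h[1] + kz * h[2]
    k_sq = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - (k_par**2) / k_sq
    d[0, 0, 0] = 0.0  # zero-frequency: expression undefined, mean unconstrained
    return DipoleKernelSpectrum(grid=grid, values=d)


def forward_field(chi: SusceptibilityMap, kernel: DipoleKernelSpectrum) -> LocalFieldMap:
    """Apply the forward model b = F^H (D · F χ).

    The imaginary residue (float noise only; D is real and even) is
    discarded.  Output is in ppm on the same grid.
    """
    _check_same_grid(chi.grid, kernel.grid)
    b = ifft3(kernel.values * fft3(chi.values)).real
    return LocalFieldMap(grid=chi.grid, values=b)
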