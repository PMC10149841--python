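"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's FFT-based operators: the DFT is
materialized as an explicit (Kronecker-product) matrix and least-squares
problems are solved densely, so solver results can be checked against a
completely separate computation path.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=8)
def dense_dft_matrix(shape: tuple[int, ...]) -> np.ndarray:
    """Unitary multidimensional DFT as an explicit matrix (C-order vec)."""
    mats = []
    for n in shape:
        w = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        mats.append(w / np.sqrt(n))
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def dense_minimum_norm_solution(
    shape, mask: np.ndarray, sk: np.ndarray, nu: np.ndarray
) -> np.ndarray:
    """Minimum-norm real LS solution of S_k F S_χ x = ν by dense lstsq.

    Builds A explicitly as a (#band-limit rows × #mask columns) complex
    matrix, stacks real and imaginary parts, and solves with lstsq (which
    returns the minimum-norm solution for rank-deficient systems).
    """
    f3 = dense_dft_matrix(tuple(shape))
    cols = np.where(mask.ravel() > 0)[0]
    rows = np.where(sk.ravel())[0]
    a = f3[np.ix_(rows, cols)]
    b = nu.ravel()[rows]
    a_real = np.vstack([a.real, a.imag])
    b_real = np.concatenate([b.real, b.imag])
    x_cols, *_ = np.linalg.lstsq(a_real, b_real, rcond=None)
    x = np.zeros(np.prod(shape))
    x[cols] = x_cols
    return x.reshape(shape)


def brute_force_kernel(shape, voxel_size, b0_dir) -> np.ndarray:
    """Elementwise dipole-kernel scan with explicit loops (no vectorization)."""
    d = np.zeros(shape)
    axes = [np.fft.fftfreq(n, dv) for n, dv in zip(shape, voxel_size)]
    for i, ki in enumerate(axes[0]):
        for j, kj in enumerate(axes[1]):
            for k, kk in enumerate(axes[2]):
                ksq = ki * ki + kj * kj + kk * kk
                if ksq == 0.0:
                    continue
                kpar = ki * b0_dir[0] + kj * b0_dir[1] + kk * b0_dir[2]
                d[i, j, k] = 1.0 / 3.0 - kpar * kpar / ksq
    return d


def sphere_field_analytic(shape, radius: float, chi: float = 1.0) -> np.ndarray:
    """Closed-form fractional field shift of a uniform sphere (Lorentz-corrected).

    Interior: 0.  Exterior: (χ a³/3)·(3cos²θ − 1)/r³ with θ measured from
    the B0 axis (third axis), evaluated at voxel centers of an isotropic
    grid centered on the volume.
    """
    c = [(n - 1) / 2.0 for n in shape]
    xx, yy, zz = np.meshgrid(
        *(np.arange(n) - ci for n, ci in zip(shape, c)), indexing="ij"
    )
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        field = (chi * radius**3 / 3.0) * (3 * (zz / r) ** 2 - 1) / r**3
    field[r <= radius] = 0.0
    return field
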