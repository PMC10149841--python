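"""Volume I/O (NIfTI) and the reproducible experiment driver.

NIfTI is the sole volume format; voxel size comes from the header, the B0
direction from configuration (headers do not carry it reliably).  Every
run writes a JSON sidecar with the full effective configuration so runs
are replayable from sidecars alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .baselines import TKDConfig, cs_reconstruct, tkd_reconstruct
from .dipole import (
    LocalFieldMap,
    SusceptibilityMap,
    VolumeGrid,
    dipole_kernel,
    forward_field,
)
from .errors import GridMismatchError, ValidationError, VolumeIOError
from .inversion import (
    ReconResult,
    SolverConfig,
    is_reconstruct,
    is_reconstruct_regularized,
    threshold_sweep,
)
from .metrics import MetricReport, evaluate
from .phantom import ROI_LABELS
from .supports import ImageSupport, band_limit, morph_mask, validate_support_consistency

log = logging.getLogger("isqsm")

__all__ = [
    "read_volume",
    "write_volume",
    "RunConfig",
    "run_experiment",
    "run_threshold_sweep",
    "run_mask_sweep",
    "run_compare",
]

_KINDS = ("chi", "field", "mask", "labels")


def _load(path) -> tuple[np.ndarray, VolumeGrid, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data.astype(float), zooms, img.affine


def read_volume(path, kind: str = "chi", b0_dir=(0.0, 0.0, 1.0)):
    """Read a NIfTI volume as a typed object.

    kind: "chi" → SusceptibilityMap, "field" → LocalFieldMap, "mask" →
    ImageSupport (binarized at 0.5), "labels" → integer ndarray (returned
    with its grid).  The returned object carries the file's affine as an
    ``affine`` attribute for round-tripping.
    """
    if kind not in _KINDS:
        raise ValidationError(f"kind must be one of {_KINDS}, got {kind!r}")
    data, zooms, affine = _load(path)
    grid = VolumeGrid(shape=data.shape, voxel_size=zooms, b0_dir=tuple(b0_dir))
    if kind == "chi":
        vol = SusceptibilityMap(grid=grid, values=data)
    elif kind == "field":
        vol = LocalFieldMap(grid=grid, values=data)
    elif kind == "mask":
        vol = ImageSupport(grid=grid, values=(data > 0.5).astype(np.uint8))
    else:
        return np.rint(data).astype(np.int32), grid
    vol.affine = affine
    return vol


def write_volume(volume, path) -> None:
    """Write a typed volume (or a labels array paired with a grid) to NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, tuple):  # (labels, grid)
        values, grid = volume
        values = np.asarray(values).astype(np.int16)
    else:
        values, grid = volume.values, volume.grid
    affine = getattr(volume, "affine", None)
    if affine is None:
        affine = np.diag((*grid.voxel_size, 1.0))
    img = nib.Nifti1Image(np.asarray(values), affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def _check_grids(*vols) -> None:
    g0 = vols[0].grid
    for v in vols[1:]:
        if v.grid.shape != g0.shape or v.grid.voxel_size != g0.voxel_size:
            raise GridMismatchError(
                f"input volumes disagree on the grid: {v.grid.shape} vs {g0.shape}"
            )


@dataclass
class RunConfig:
    """Full configuration of a reconstruction run (echoed into sidecars)."""

    method: str  # is | isreg | tkd | cs
    field_path: str
    mask_path: str
    out_path: str
    truth_path: str | None = None
    labels_path: str | None = None
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0
    t_well: float = 0.25
    tol: float = 1e-6
    max_iter: int = 50
    lambda_l1: float = 1e-5
    wavelet_name: str = "db2"
    wavelet_levels: int = 3
    delta: float = 2.0 / 3.0
    psf_correct: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("is", "isreg", "tkd", "cs"):
            raise ValidationError(f"unknown method {self.method!r}")


def _reconstruct(cfg: RunConfig, field_map, mask, kernel) -> ReconResult:
    solver = SolverConfig(
        t_well=cfg.t_well,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        lambda_l1=cfg.lambda_l1 if cfg.method == "isreg" else 0.0,
        wavelet_name=cfg.wavelet_name,
        wavelet_levels=cfg.wavelet_levels,
    )
    if cfg.method == "is":
        return is_reconstruct(field_map, mask, kernel, solver)
    if cfg.method == "isreg":
        return is_reconstruct_regularized(field_map, mask, kernel, solver)
    if cfg.method == "cs":
        support = band_limit(kernel, cfg.t_well)
        return cs_reconstruct(
            field_map,
            mask,
            kernel,
            support,
            lambda_l1=cfg.lambda_l1,
            wavelet_name=cfg.wavelet_name,
            wavelet_levels=cfg.wavelet_levels,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
        )
    chi = tkd_reconstruct(
        field_map, kernel, TKDConfig(delta=cfg.delta, psf_correct=cfg.psf_correct)
    )
    return ReconResult(
        chi=chi,
        residual_history=[],
        iterations=0,
        converged=True,
        config_echo={"method": "tkd", "delta": cfg.delta, "psf_correct": cfg.psf_correct},
    )


def run_experiment(cfg: RunConfig) -> tuple[ReconResult, MetricReport | None]:
    """Load inputs, reconstruct, write χ + JSON sidecar (+ metrics if truth given)."""
    field_map = read_volume(cfg.field_path, kind="field", b0_dir=cfg.b0_dir)
    mask = read_volume(cfg.mask_path, kind="mask", b0_dir=cfg.b0_dir)
    _check_grids(field_map, mask)
    kernel = dipole_kernel(field_map.grid)
    field_map, leak = validate_support_consistency(field_map, mask)
    if leak > 1e-6:
        log.warning("%.2f%% of field energy lay outside the mask", 100 * leak)
    result = _reconstruct(cfg, field_map, mask, kernel)
    write_volume(result.chi, cfg.out_path)

    report = None
    if cfg.truth_path:
        truth = read_volume(cfg.truth_path, kind="chi", b0_dir=cfg.b0_dir)
        _check_grids(field_map, truth)
        labels = names = None
        if cfg.labels_path:
            labels, _ = read_volume(cfg.labels_path, kind="labels")
            names = {v: k for k, v in ROI_LABELS.items()}
        report = evaluate(result.chi, truth, mask, labels=labels, names=names)

    sidecar = {
        "config": asdict(cfg),
        "config_echo": result.config_echo,
        "iterations": result.iterations,
        "converged": result.converged,
        "residual_history": list(map(float, result.residual_history)),
    }
    if report is not None:
        sidecar["metrics"] = report.to_dict()
    sidecar_path = Path(cfg.out_path).with_suffix("").with_suffix("")
    sidecar_path = Path(str(sidecar_path) + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return result, report


def run_threshold_sweep(
    field_path, mask_path, truth_path, out_csv, thresholds, b0_dir=(0, 0, 1), **solver_kw
):
    """Sweep the band-limit threshold, writing a (t_well, XSIM, PSNR) CSV."""
    field_map = read_volume(field_path, kind="field", b0_dir=b0_dir)
    mask = read_volume(mask_path, kind="mask", b0_dir=b0_dir)
    truth = read_volume(truth_path, kind="chi", b0_dir=b0_dir)
    _check_grids(field_map, mask, truth)
    kernel = dipole_kernel(field_map.grid)
    field_map, _ = validate_support_consistency(field_map, mask)
    res = threshold_sweep(
        field_map, mask, kernel, truth, thresholds, SolverConfig(**solver_kw)
    )
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(out_csv, index=False)
    best = {"best_xsim": res.best_xsim, "best_psnr": res.best_psnr}
    Path(str(out_csv.with_suffix("")) + "_best.json").write_text(
        json.dumps(best, indent=2)
    )
    return res


def run_mask_sweep(
    field_path,
    mask_path,
    truth_path,
    out_csv,
    diameters=range(1, 9),
    b0_dir=(0, 0, 1),
    **solver_kw,
):
    """Erode/dilate the mask by spherical kernels and score each reconstruction."""
    import pandas as pd

    field_map = read_volume(field_path, kind="field", b0_dir=b0_dir)
    mask = read_volume(mask_path, kind="mask", b0_dir=b0_dir)
    truth = read_volume(truth_path, kind="chi", b0_dir=b0_dir)
    _check_grids(field_map, mask, truth)
    kernel = dipole_kernel(field_map.grid)
    solver = SolverConfig(**solver_kw)
    rows = []
    for mode, sign in (("erode", -1), ("dilate", +1)):
        for d in diameters:
            m = morph_mask(mask, d, mode) if d > 1 or mode == "dilate" else mask
            if m.n_voxels == 0:
                continue
            fm, _ = validate_support_consistency(field_map, m)
            res = is_reconstruct(fm, m, kernel, solver)
            rep = evaluate(res.chi, truth, m)
            rows.append(
                {
                    "mode": mode,
                    "diameter": d,
                    "delta_voxels": sign * d,
                    "xsim": rep.xsim,
                    "psnr": rep.psnr_db,
                    "mask_voxels": m.n_voxels,
                }
            )
    table = pd.DataFrame(rows)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_csv, index=False)
    return table


def run_compare(
    field_path,
    mask_path,
    truth_path,
    out_dir,
    methods=("is", "isreg", "tkd", "cs"),
    labels_path=None,
    b0_dir=(0, 0, 1),
    **cfg_kw,
) -> dict[str, MetricReport]:
    """Run several methods on the same data; one MetricReport per method."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports = {}
    for method in methods:
        cfg = RunConfig(
            method=method,
            field_path=str(field_path),
            mask_path=str(mask_path),
            out_path=str(out_dir / f"chi_{method}.nii.gz"),
            truth_path=str(truth_path),
            labels_path=str(labels_path) if labels_path else None,
            b0_dir=tuple(b0_dir),
            **cfg_kw,
        )
        _, reports[method] = run_experiment(cfg)
    return reports
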