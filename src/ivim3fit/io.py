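"""NIfTI / bval file I/O, signal normalisation and provenance records.

Volumes are indexed (x, y, z, b), 0-based, with spatial semantics carried
solely by the NIfTI affine.  b-values come from FSL-style whitespace
separated text files (one row).  Parameter maps are written as one float32
NIfTI per parameter plus a JSON sidecar recording the bounds, method,
convergence statistics and a hash of the configuration, which is enough to
re-run the fit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .lsq import FitReport
from .models import BValueScheme, ValidationError

__all__ = [
    "DwiDataset",
    "read_bval",
    "write_bval",
    "read_dwi",
    "write_dwi",
    "write_maps",
    "normalize_signals",
    "unflatten_map",
    "collapse_directions",
    "config_hash",
]


@dataclass
class DwiDataset:
    """A 4D diffusion-weighted volume with its b-value axis and optional mask."""

    volume: np.ndarray  # (X, Y, Z, B)
    bvalues: BValueScheme
    affine: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.volume.ndim != 4:
            raise ValidationError("DWI volume must be 4D (x, y, z, b)")
        if self.volume.shape[3] != len(self.bvalues):
            raise ValidationError(
                f"4th dimension ({self.volume.shape[3]}) does not match "
                f"b-value count ({len(self.bvalues)})"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.volume.shape[:3]:
                raise ValidationError("mask shape does not match spatial dimensions")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.volume.shape[:3]


def read_bval(path) -> np.ndarray:
    values = np.atleast_1d(np.loadtxt(path, dtype=float).ravel())
    if values.size == 0:
        raise ValidationError(f"no b-values found in {path}")
    return values


def write_bval(values, path) -> None:
    np.savetxt(path, np.asarray(values, dtype=float)[None, :], fmt="%g")


def read_dwi(volume_path, bval_path, mask_path=None) -> DwiDataset:
    """Load and validate a 4D NIfTI volume with its bval file and optional mask.

    A missing b=0 entry is tolerated with a warning (normalisation to S(b=0)
    is then unavailable); non-finite voxel values are rejected.
    """
    img = nib.load(str(volume_path))
    volume = np.asarray(img.dataobj, dtype=np.float64)
    if volume.ndim == 3:
        volume = volume[..., None]
    bvals = read_bval(bval_path)
    if volume.ndim != 4 or volume.shape[3] != bvals.size:
        raise ValidationError(
            f"volume has {volume.shape[3] if volume.ndim == 4 else 'no'} "
            f"b-dimension entries but bval file lists {bvals.size}"
        )
    if not np.all(np.isfinite(volume)):
        raise ValidationError("volume contains non-finite values")
    if not np.any(bvals == 0):
        warnings.warn(
            "b-value scheme has no b=0 entry; S(b=0) normalisation disabled",
            stacklevel=2,
        )
        scheme = BValueScheme(bvals, require_b0=False)
    else:
        scheme = BValueScheme(bvals)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return DwiDataset(volume=volume, bvalues=scheme, affine=img.affine, mask=mask)


def write_dwi(ds: DwiDataset, volume_path, bval_path, mask_path=None) -> None:
    """Write a dataset back to NIfTI + bval (+ mask); float64 volume."""
    nib.save(nib.Nifti1Image(ds.volume, ds.affine), str(volume_path))
    write_bval(ds.bvalues.values, bval_path)
    if mask_path is not None and ds.mask is not None:
        nib.save(nib.Nifti1Image(ds.mask.astype(np.uint8), ds.affine), str(mask_path))


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration dict."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def normalize_signals(ds: DwiDataset) -> tuple[np.ndarray, np.ndarray, int]:
    """Flatten masked voxels to rows and normalise each to its mean b=0 signal.

    Returns ``(signals, voxel_indices, n_excluded)`` where ``voxel_indices``
    are flat (C-order) indices into the spatial grid; voxels whose mean b=0
    signal is non-positive are dropped and counted.  Multiple b=0 volumes
    are averaged before division.
    """
    if not ds.bvalues.has_b0:
        raise ValidationError("cannot normalise: no b=0 volume present")
    mask = ds.mask if ds.mask is not None else np.ones(ds.spatial_shape, dtype=bool)
    flat = ds.volume.reshape(-1, ds.volume.shape[3])
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValidationError("mask selects no voxels")
    rows = flat[idx]
    b0 = rows[:, ds.bvalues.b0_indices].mean(axis=1)
    keep = b0 > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValidationError("all masked voxels have non-positive b=0 signal")
    signals = rows[keep] / b0[keep, None]
    return signals, idx[keep], n_excluded


def collapse_directions(ds: DwiDataset, method: str = "geometric") -> DwiDataset:
    """Average per-direction repeats of each b-value into a trace signal.

    Acquisitions that repeat every weighting along several gradient
    directions are collapsed to one volume per unique b-value, using the
    geometric mean by default (the arithmetic mean is available).  Geometric
    averaging of non-positive voxel values falls back to 0 for that voxel.
    A dataset without repeated b-values is returned unchanged.
    """
    if method not in ("geometric", "arithmetic"):
        raise ValidationError("method must be 'geometric' or 'arithmetic'")
    bv = ds.bvalues.values
    unique = np.unique(bv)
    if unique.size == bv.size:
        return ds
    out = np.empty(ds.spatial_shape + (unique.size,))
    for j, b in enumerate(unique):
        group = ds.volume[..., bv == b]
        if method == "arithmetic":
            out[..., j] = group.mean(axis=-1)
        else:
            positive = np.all(group > 0, axis=-1)
            logs = np.log(np.where(group > 0, group, 1.0)).mean(axis=-1)
            out[..., j] = np.where(positive, np.exp(logs), 0.0)
    return DwiDataset(
        volume=out,
        bvalues=BValueScheme(unique, require_b0=bool(np.any(unique == 0))),
        affine=ds.affine,
        mask=ds.mask,
    )


def unflatten_map(values, voxel_indices, spatial_shape, fill=np.nan) -> np.ndarray:
    """Inverse of the flattening in :func:`normalize_signals`."""
    out = np.full(int(np.prod(spatial_shape)), fill, dtype=float)
    out[np.asarray(voxel_indices)] = np.asarray(values, dtype=float)
    return out.reshape(spatial_shape)


def write_maps(
    report: FitReport,
    affine: np.ndarray,
    out_dir,
    voxel_indices=None,
    spatial_shape=None,
    extra_config: Optional[dict] = None,
) -> list[Path]:
    """Write one float32 NIfTI per parameter plus a JSON provenance sidecar.

    When ``voxel_indices``/``spatial_shape`` are given, flat per-voxel values
    are scattered back into the 3D grid (unfitted voxels become NaN);
    otherwise the parameter arrays are saved with their own shape.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, values in report.maps().items():
        arr = np.asarray(values, dtype=float)
        if voxel_indices is not None:
            if spatial_shape is None:
                raise ValidationError("spatial_shape required with voxel_indices")
            arr = unflatten_map(arr, voxel_indices, spatial_shape)
        path = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))
        written.append(path)
    config = {
        "model": report.model,
        "bounds": report.bounds.bounds,
        "n_params": report.n_params,
        **(extra_config or {}),
    }
    sidecar = {
        **config,
        "config_hash": config_hash(config),
        "n_voxels": int(np.asarray(report.converged).size),
        "n_converged": int(np.asarray(report.converged).sum()),
        "ordering_violations": report.ordering_violations,
        "adjusted_r2": report.adjusted_r2,
        "maps": [p.name for p in written],
    }
    sidecar_path = out_dir / "fit_summary.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=str))
    written.append(sidecar_path)
    return written
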