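"""Sinogram and volume I/O.

NPZ is the primary container (exact integer counts); NIfTI is provided for
interoperability, with frame durations stored explicitly in a JSON sidecar
because 4-D NIfTI timing conventions vary between tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .kinetics import DynamicSinogram

__all__ = ["read_sinogram", "write_sinogram", "write_nifti", "read_nifti"]


class FormatError(ValueError):
    """Raised when a container is missing required arrays or metadata."""


def write_sinogram(path: str | Path, sino: DynamicSinogram) -> Path:
    """Write a dynamic sinogram to NPZ (counts, frame_durations[, clean])."""
    path = Path(path)
    arrays = {"counts": sino.counts, "frame_durations": sino.frame_durations}
    if sino.clean is not None:
        arrays["clean"] = sino.clean
    np.savez_compressed(path, **arrays)
    return path


def read_sinogram(path: str | Path) -> DynamicSinogram:
    """Read a dynamic sinogram from NPZ written by :func:`write_sinogram`."""
    path = Path(path)
    with np.load(path) as npz:
        for key in ("counts", "frame_durations"):
            if key not in npz:
                raise FormatError(f"{path} is missing required array {key!r}")
        return DynamicSinogram(
            counts=npz["counts"],
            frame_durations=npz["frame_durations"],
            clean=npz["clean"] if "clean" in npz else None,
        )


def write_nifti(
    path: str | Path,
    data: np.ndarray,
    voxel_size: float = 1.5,
    frame_durations: np.ndarray | None = None,
) -> Path:
    """Write a 4-D (frames, slices, H, W) volume as NIfTI (X, Y, Z, T).

    Frame durations (seconds) go to a ``.json`` sidecar next to the image.
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim != 4:
        raise FormatError("expected a 4-D (frames, slices, H, W) array")
    # NIfTI order: spatial first, time last
    xyzt = np.transpose(data, (3, 2, 1, 0))
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(xyzt.astype(np.float32), affine)
    img.header.set_zooms((voxel_size,) * 3 + (1.0,))
    nib.save(img, path)
    if frame_durations is not None:
        sidecar = path.with_suffix("").with_suffix(".json")
        sidecar.write_text(
            json.dumps({"frame_durations_s": list(map(float, frame_durations))})
        )
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Read a 4-D NIfTI back to (frames, slices, H, W) plus metadata."""
    path = Path(path)
    img = nib.load(path)
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise FormatError(f"{path} is not a 4-D volume")
    data = np.transpose(arr, (3, 2, 1, 0)).astype(np.float64)
    voxel = float(img.header.get_zooms()[0])
    sidecar = path.with_suffix("").with_suffix(".json")
    durations = None
    if sidecar.exists():
        durations = np.asarray(
            json.loads(sidecar.read_text())["frame_durations_s"], dtype=np.float64
        )
    return data, voxel, durations
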