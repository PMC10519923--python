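"""Quantitative evaluation: SSIM, PSNR, time-activity curves and TAC RMSE.

Ground truth throughout is the reconstruction of the *noiseless* sinogram,
not the phantom itself, so that the metrics isolate the denoiser from the
reconstruction algorithm.

The SSIM used here is the single global-moment formula

    SSIM = (2 mu_g mu_d + c1)(2 cov_gd + c2)
           / ((mu_g^2 + mu_d^2 + c1)(sigma_g^2 + sigma_d^2 + c2))

with c1 = c2 = 0.01^2, computed over the whole frame volume after
normalizing both images by the ground-truth peak.  This deliberately
differs from the common sliding-window SSIM of image libraries.  PSNR is
``20 log10(peak / RMSE)`` dB with the peak taken from the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recon import ReconVolume

__all__ = [
    "FrameMetrics",
    "TacReport",
    "ssim_global",
    "psnr",
    "frame_metrics",
    "extract_tac",
    "tac_rmse",
    "metric_table",
]

_C1 = 0.01**2
_C2 = 0.01**2


@dataclass
class FrameMetrics:
    """Per-frame image-quality metrics for one method."""

    ssim: np.ndarray  # per frame, in [-1, 1]
    psnr_db: np.ndarray  # per frame, dB (inf when images are identical)


@dataclass
class TacReport:
    """Per-tissue TAC comparison over a 4x4x4 VOI."""

    tissue: str
    ground_truth: np.ndarray
    estimate: np.ndarray
    rmse: float
    voi_center: tuple[int, int, int]
    voi_size: int = 4


def ssim_global(ground: np.ndarray, denoised: np.ndarray) -> float:
    """Global-moment structural similarity of one frame volume."""
    g = np.asarray(ground, dtype=np.float64)
    d = np.asarray(denoised, dtype=np.float64)
    if g.shape != d.shape:
        raise ValueError("images must share shape")
    peak = g.max()
    if peak > 0:
        g = g / peak
        d = d / peak
    mu_g, mu_d = g.mean(), d.mean()
    var_g, var_d = g.var(), d.var()
    cov = ((g - mu_g) * (d - mu_d)).mean()
    return float(
        (2 * mu_g * mu_d + _C1)
        * (2 * cov + _C2)
        / ((mu_g**2 + mu_d**2 + _C1) * (var_g + var_d + _C2))
    )


def psnr(ground: np.ndarray, denoised: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak from the ground truth."""
    g = np.asarray(ground, dtype=np.float64)
    d = np.asarray(denoised, dtype=np.float64)
    if g.shape != d.shape:
        raise ValueError("images must share shape")
    if np.all(g == g.flat[0]):
        raise ValueError("ground truth must not be constant")
    rmse = float(np.sqrt(np.mean((g - d) ** 2)))
    if rmse == 0.0:
        return np.inf
    return float(20.0 * np.log10(g.max() / rmse))


def _as_volume(x) -> np.ndarray:
    return np.asarray(x.data if isinstance(x, ReconVolume) else x)


def frame_metrics(ground: np.ndarray, test: np.ndarray) -> FrameMetrics:
    """SSIM and PSNR per frame over the full per-frame volume."""
    g = _as_volume(ground)
    t = _as_volume(test)
    if g.shape != t.shape:
        raise ValueError("volumes must share shape")
    ssim = np.array([ssim_global(g[f], t[f]) for f in range(g.shape[0])])
    ps = np.array([psnr(g[f], t[f]) for f in range(g.shape[0])])
    return FrameMetrics(ssim=ssim, psnr_db=ps)


def extract_tac(
    volume: ReconVolume | np.ndarray,
    voi_center: tuple[int, int, int],
    voi_size: int = 4,
) -> np.ndarray:
    """Per-frame mean over a cubic VOI of ``voi_size`` voxels per side."""
    data = _as_volume(volume)
    if data.ndim != 4:
        raise ValueError("volume must be (frames, slices, H, W)")
    half = voi_size // 2
    starts = [c - half for c in voi_center]
    stops = [s + voi_size for s in starts]
    for ax, (lo, hi) in enumerate(zip(starts, stops)):
        if lo < 0 or hi > data.shape[ax + 1]:
            raise IndexError("VOI extends outside the volume")
    z0, y0, x0 = starts
    voi = data[:, z0 : z0 + voi_size, y0 : y0 + voi_size, x0 : x0 + voi_size]
    return voi.mean(axis=(1, 2, 3))


def clamp_voi_center(
    center: tuple[int, int, int], shape: tuple[int, ...], voi_size: int = 4
) -> tuple[int, int, int]:
    """Shift a VOI center minimally so the cube fits inside the volume."""
    half = voi_size // 2
    out = []
    for c, extent in zip(center, shape[-3:]):
        out.append(int(min(max(c, half), extent - voi_size + half)))
    return tuple(out)


def tac_rmse(gt: np.ndarray, est: np.ndarray) -> float:
    """Root mean square per-frame difference of two TACs."""
    gt = np.asarray(gt, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    if gt.shape != est.shape:
        raise ValueError("TACs must have equal length")
    return float(np.sqrt(np.mean((gt - est) ** 2)))


def metric_table(
    ground: np.ndarray, methods: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Tidy table of per-frame SSIM/PSNR for several methods.

    Rows: (method, frame); columns: ssim, psnr_db.
    """
    records = []
    for name, vol in methods.items():
        fm = frame_metrics(ground, vol)
        for f in range(len(fm.ssim)):
            records.append(
                {
                    "method": name,
                    "frame": f + 1,
                    "ssim": fm.ssim[f],
                    "psnr_db": fm.psnr_db[f],
                }
            )
    return pd.DataFrame.from_records(records)
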