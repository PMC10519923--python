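"""Collaborative filtering core of the GBM4D denoiser.

A matched group is an ``N x N x |T| x |S|`` stack: two spatial block axes,
the time-frame axis and the group (similar-block) axis.  The group is
transformed with a separable orthonormal DCT along all four axes; because
matched blocks share structure across space, time and the group axis, the
signal concentrates in few coefficients while the noise stays spread out, so
shrinking the spectrum removes noise without destroying edges.

Two passes are run (both reusing the guided matching of
:mod:`gbm4d.matching`):

* Step 1 hard-thresholds the 4-D spectrum at ``lambda_4d * sigma`` and
  aggregates the filtered blocks into a basic estimate.
* Step 2 re-matches on the accumulated basic estimate and applies empirical
  Wiener shrinkage, using the basic estimate's spectrum as the pilot.

Overlapping filtered blocks are combined by a weighted average whose weights
are the group reliability (inverse residual-variance surrogate) times a 2-D
Kaiser window that de-emphasizes block borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .matching import (
    BlockGroup,
    GuideImage,
    GuidedMatcher,
    MatchConfig,
    MatchSet,
    guide_sigma,
    reference_grid,
)
from .vst import StabilizedSinogram

__all__ = [
    "DenoiseConfig",
    "FilteredGroup",
    "transform_4d",
    "inverse_transform_4d",
    "hard_threshold",
    "ht_filter_group",
    "wiener_filter_group",
    "aggregate",
    "gbm4d_denoise",
]

_WEIGHT_EPS = 1e-12


@dataclass
class DenoiseConfig:
    """Tunable parameters of the two-step denoiser."""

    lambda_4d: float = 2.8
    sigma: float = 1.0
    kaiser_beta: float = 2.0
    match: MatchConfig = field(default_factory=MatchConfig)
    #: Force the Wiener shrinkage factor to one (pass-through spectrum);
    #: used for degeneracy checks.
    force_wiener_identity: bool = False

    def __post_init__(self) -> None:
        if not self.lambda_4d >= 0:
            raise ValueError("lambda_4d must be nonnegative")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class FilteredGroup:
    """A filtered block stack with its aggregation weight."""

    stack: np.ndarray
    weight: float
    match: MatchSet
    slice_index: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.weight) and self.weight > 0):
            raise ValueError("aggregation weight must be positive and finite")


def _transform_axes(shape: tuple[int, ...], axes: tuple[int, ...]) -> tuple[int, ...]:
    # A DCT-II (norm='ortho') along a length-1 axis is the identity; skip
    # such axes so degenerate groups reduce exactly to the lower-D transform.
    return tuple(ax for ax in axes if shape[ax] > 1)


def transform_4d(stack: np.ndarray) -> np.ndarray:
    """Separable orthonormal DCT-II along all four group axes."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 4:
        raise ValueError(f"expected a 4-D group stack, got shape {stack.shape}")
    axes = _transform_axes(stack.shape, (0, 1, 2, 3))
    if not axes:
        return stack.copy()
    return scipy.fft.dctn(stack, type=2, norm="ortho", axes=axes)


def inverse_transform_4d(coeffs: np.ndarray) -> np.ndarray:
    """Exact inverse (adjoint) of :func:`transform_4d`."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.ndim != 4:
        raise ValueError(f"expected a 4-D coefficient stack, got shape {coeffs.shape}")
    axes = _transform_axes(coeffs.shape, (0, 1, 2, 3))
    if not axes:
        return coeffs.copy()
    return scipy.fft.idctn(coeffs, type=2, norm="ortho", axes=axes)


def hard_threshold(
    coeffs: np.ndarray, sigma: float, lambda_4d: float
) -> tuple[np.ndarray, int]:
    """Zero coefficients with ``|v| <= lambda_4d * sigma`` (boundary inclusive).

    Returns the shrunk coefficients and the number of surviving nonzeros.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    keep = np.abs(coeffs) > lambda_4d * sigma
    out = np.where(keep, coeffs, 0.0)
    return out, int(np.count_nonzero(out))


def ht_filter_group(group: BlockGroup, cfg: DenoiseConfig) -> FilteredGroup:
    """Step-1 collaborative filtering of one group by 4-D hard thresholding.

    The aggregation weight is ``1 / (sigma**2 * max(n_retained, 1))``: the
    sparser the filtered spectrum, the more reliable the estimate.
    """
    coeffs = transform_4d(group.stack)
    shrunk, n_ret = hard_threshold(coeffs, cfg.sigma, cfg.lambda_4d)
    stack = inverse_transform_4d(shrunk)
    weight = 1.0 / (cfg.sigma**2 * max(n_ret, 1))
    return FilteredGroup(
        stack=stack, weight=weight, match=group.match, slice_index=group.slice_index
    )


def wiener_filter_group(
    noisy_group: BlockGroup,
    basic_group: BlockGroup,
    sigma: float,
    force_identity: bool = False,
) -> FilteredGroup:
    """Step-2 empirical Wiener shrinkage using the basic estimate as pilot.

    The shrinkage factor ``W = |B|**2 / (|B|**2 + sigma**2)`` (``B`` the
    4-D spectrum of the basic-estimate group) lies in ``[0, 1)`` and is
    applied to the spectrum of the noisy group.  The aggregation weight is
    ``1 / (sigma**2 * ||W||_2**2)``.
    """
    if noisy_group.stack.shape != basic_group.stack.shape:
        raise ValueError("noisy and basic groups must share shape")
    pilot = transform_4d(basic_group.stack)
    if force_identity:
        w = np.ones_like(pilot)
    else:
        p2 = pilot**2
        w = p2 / (p2 + sigma**2)
    coeffs = transform_4d(noisy_group.stack)
    stack = inverse_transform_4d(w * coeffs)
    wnorm = max(float(np.sum(w**2)), _WEIGHT_EPS)
    weight = 1.0 / (sigma**2 * wnorm)
    return FilteredGroup(
        stack=stack,
        weight=weight,
        match=noisy_group.match,
        slice_index=noisy_group.slice_index,
    )


def kaiser_window_2d(block_size: int, beta: float) -> np.ndarray:
    """Separable 2-D Kaiser window used in the aggregation weights."""
    k = np.kaiser(block_size, beta)
    return np.outer(k, k)


def aggregate(
    filtered: list[FilteredGroup],
    slice_shape: tuple[int, int],
    kaiser_beta: float = 2.0,
    require_coverage: bool = True,
) -> np.ndarray:
    """Weighted-average aggregation of filtered groups into one slice.

    Each voxel is the ratio of accumulated ``weight * kaiser * value`` to
    accumulated ``weight * kaiser`` over all blocks covering it.  With
    ``require_coverage`` (the pipeline default) a voxel covered by no block
    raises, since the reference grid must cover the slice; otherwise
    uncovered voxels are left at zero.
    """
    if not filtered:
        raise ValueError("no filtered groups to aggregate")
    n = filtered[0].stack.shape[0]
    n_frames = filtered[0].stack.shape[2]
    h, w = slice_shape
    kaiser = kaiser_window_2d(n, kaiser_beta)
    num = np.zeros((n_frames, h, w))
    den = np.zeros((h, w))
    for grp in filtered:
        wk = grp.weight * kaiser
        blocks = grp.stack * wk[:, :, None, None]  # (N, N, T, S)
        for m, (r, c) in enumerate(grp.match.members):
            num[:, r : r + n, c : c + n] += blocks[:, :, :, m].transpose(2, 0, 1)
            den[r : r + n, c : c + n] += wk
    uncovered = den <= 0
    if uncovered.any():
        if require_coverage:
            raise RuntimeError("aggregation found voxels covered by no block")
        den = np.where(uncovered, 1.0, den)
    return num / den[None]


# ---------------------------------------------------------------------------
# Batched two-step orchestration


def _stack_batch(plane: np.ndarray, matches: list[MatchSet], n: int) -> np.ndarray:
    """Stack groups of equal size from one (T, H, W) plane: (G, N, N, T, S)."""
    rows = np.array([[p[0] for p in m.members] for m in matches])
    cols = np.array([[p[1] for p in m.members] for m in matches])
    ar = np.arange(n)
    idx_r = rows[:, :, None, None] + ar[None, None, :, None]
    idx_c = cols[:, :, None, None] + ar[None, None, None, :]
    stacks = plane[:, idx_r, idx_c]  # (T, G, S, N, N)
    return np.ascontiguousarray(stacks.transpose(1, 3, 4, 0, 2))


def _batch_dct(stacks: np.ndarray, inverse: bool = False) -> np.ndarray:
    axes = _transform_axes(stacks.shape, (1, 2, 3, 4))
    if not axes:
        return stacks.copy()
    fn = scipy.fft.idctn if inverse else scipy.fft.dctn
    return fn(stacks, type=2, norm="ortho", axes=axes)


def _bucket_by_size(matches: list[MatchSet]) -> dict[int, list[MatchSet]]:
    buckets: dict[int, list[MatchSet]] = {}
    for m in matches:
        buckets.setdefault(len(m), []).append(m)
    return buckets


def _ht_pass(
    plane: np.ndarray, matches: list[MatchSet], cfg: DenoiseConfig
) -> np.ndarray:
    n = cfg.match.block_size
    filtered: list[FilteredGroup] = []
    for size, bucket in _bucket_by_size(matches).items():
        stacks = _stack_batch(plane, bucket, n)
        coeffs = _batch_dct(stacks)
        keep = np.abs(coeffs) > cfg.lambda_4d * cfg.sigma
        shrunk = np.where(keep, coeffs, 0.0)
        n_ret = np.count_nonzero(shrunk, axis=(1, 2, 3, 4))
        out = _batch_dct(shrunk, inverse=True)
        weights = 1.0 / (cfg.sigma**2 * np.maximum(n_ret, 1))
        filtered.extend(
            FilteredGroup(stack=out[g], weight=float(weights[g]), match=bucket[g])
            for g in range(len(bucket))
        )
    return aggregate(filtered, plane.shape[1:], cfg.kaiser_beta)


def _wiener_pass(
    plane: np.ndarray,
    basic_plane: np.ndarray,
    matches: list[MatchSet],
    cfg: DenoiseConfig,
) -> np.ndarray:
    n = cfg.match.block_size
    s2 = cfg.sigma**2
    filtered: list[FilteredGroup] = []
    for size, bucket in _bucket_by_size(matches).items():
        noisy = _batch_dct(_stack_batch(plane, bucket, n))
        if cfg.force_wiener_identity:
            w = np.ones_like(noisy)
        else:
            pilot = _batch_dct(_stack_batch(basic_plane, bucket, n))
            p2 = pilot**2
            w = p2 / (p2 + s2)
        out = _batch_dct(w * noisy, inverse=True)
        wnorm = np.maximum(np.sum(w**2, axis=(1, 2, 3, 4)), _WEIGHT_EPS)
        weights = 1.0 / (s2 * wnorm)
        filtered.extend(
            FilteredGroup(stack=out[g], weight=float(weights[g]), match=bucket[g])
            for g in range(len(bucket))
        )
    return aggregate(filtered, plane.shape[1:], cfg.kaiser_beta)


def gbm4d_denoise(
    sino: StabilizedSinogram,
    cfg: DenoiseConfig | None = None,
    return_basic: bool = False,
) -> StabilizedSinogram | tuple[StabilizedSinogram, StabilizedSinogram]:
    """Two-step guided 4-D collaborative filtering of a stabilized sinogram.

    Step 1 matches blocks on the frame-accumulated noisy sinogram, hard-
    thresholds each 4-D group and aggregates a basic estimate.  Step 2
    re-matches on the accumulated basic estimate (plain, unprefiltered
    distance) and Wiener-filters the noisy groups with the basic groups as
    pilot.  Slices are processed independently; the procedure contains no
    randomness.

    Parameters
    ----------
    sino : StabilizedSinogram
        Anscombe-stabilized dynamic sinogram, shape (frames, slices,
        angles, bins).
    cfg : DenoiseConfig, optional
        Filter parameters; defaults are used when omitted.
    return_basic : bool
        Also return the Step-1 basic estimate.
    """
    if cfg is None:
        cfg = DenoiseConfig(sigma=sino.sigma)
    n_frames = sino.n_frames
    sig_g = guide_sigma(cfg.sigma, n_frames)
    grid = reference_grid(sino.data.shape[2:], cfg.match.block_size, cfg.match.step)
    out = np.empty_like(sino.data)
    basic_out = np.empty_like(sino.data) if return_basic else None
    for s in range(sino.n_slices):
        plane = sino.data[:, s]
        guide1 = GuideImage(plane.sum(axis=0), source="noisy_accumulated")
        matcher1 = GuidedMatcher(
            guide1, cfg.match, sig_g, tau=cfg.match.tau_match, prefilter=True
        )
        matches1 = [matcher1.match(p) for p in grid]
        basic = _ht_pass(plane, matches1, cfg)
        guide2 = GuideImage(basic.sum(axis=0), source="basic_estimate_accumulated")
        matcher2 = GuidedMatcher(
            guide2, cfg.match, sig_g, tau=cfg.match.tau_match_wiener, prefilter=False
        )
        matches2 = [matcher2.match(p) for p in grid]
        out[:, s] = _wiener_pass(plane, basic, matches2, cfg)
        if basic_out is not None:
            basic_out[:, s] = basic
    result = StabilizedSinogram(out, sigma=sino.sigma, frame_durations=sino.frame_durations)
    if return_basic:
        return result, StabilizedSinogram(
            basic_out, sigma=sino.sigma, frame_durations=sino.frame_durations
        )
    return result
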