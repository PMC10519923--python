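"""Guide-image construction and guided block matching.

Matching single low-count frames against each other is unreliable: the
estimated block distance is a non-central chi-square variable whose variance
grows with sigma^4, so at frame-level noise the distance densities of truly
similar and dissimilar blocks overlap and blocks are mis-grouped.  The guide
image — the sinogram accumulated over all time frames — has the same
structure but a much lower relative noise level, so matching is performed
once on the guide and the resulting member set is reused to stack the
per-frame blocks of every frame into one 4-D group.

Distances are computed after coarse prefiltering: each block is transformed
with an orthonormal 2-D DCT and the coefficients hard-thresholded at
``prefilter_threshold * sigma_guide`` before the squared l2 distance
(normalized by the block area) is taken.  With the threshold at zero this
reduces to the plain l2 block distance by Parseval's identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from numpy.lib.stride_tricks import sliding_window_view

from .vst import StabilizedSinogram

__all__ = [
    "MatchConfig",
    "GuideImage",
    "MatchSet",
    "BlockGroup",
    "build_guide",
    "prefiltered_distance",
    "match_blocks",
    "stack_group",
    "GuidedMatcher",
    "reference_grid",
]


@dataclass
class MatchConfig:
    """Block-matching parameters (BM3D-conventional defaults).

    ``tau_match`` and ``tau_match_wiener`` are expressed in normalized
    intensity units; the effective threshold on the area-normalized block
    distance is ``tau * sigma_guide**2`` so that matching stays calibrated
    as the frame count (and hence the guide noise level) changes.
    """

    block_size: int = 8
    step: int = 3
    window: int = 39
    max_group: int = 16
    tau_match: float = 3000.0 / 255.0**2
    tau_match_wiener: float = 400.0 / 255.0**2
    prefilter_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.block_size < 1 or self.window < self.block_size:
            raise ValueError("window must be at least the block size")
        if self.step < 1 or self.max_group < 1:
            raise ValueError("step and max_group must be positive")


@dataclass
class GuideImage:
    """2-D guide for one sinogram slice: the frame-accumulated sinogram."""

    data: np.ndarray
    source: str = "noisy_accumulated"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("guide image must be 2-D (angles, bins)")


@dataclass
class MatchSet:
    """Positions matched to one reference block, reference first."""

    reference: tuple[int, int]
    members: list[tuple[int, int]]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if len(self.members) < 1 or self.members[0] != self.reference:
            raise ValueError("reference must be the first member")
        if len(self.members) != len(self.distances):
            raise ValueError("one distance per member required")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class BlockGroup:
    """4-D stack of matched blocks: (N, N, frames, members)."""

    stack: np.ndarray
    match: MatchSet
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        if self.stack.ndim != 4:
            raise ValueError("block group stack must be N x N x |T| x |S|")
        if self.stack.shape[3] != len(self.match):
            raise ValueError("group axis must match the member count")


def build_guide(
    sino: StabilizedSinogram, slice_index: int, source: str = "noisy_accumulated"
) -> GuideImage:
    """Accumulate one slice of the sinogram over the frame axis."""
    if not 0 <= slice_index < sino.n_slices:
        raise IndexError(f"slice_index {slice_index} out of range")
    return GuideImage(sino.data[:, slice_index].sum(axis=0), source=source)


def guide_sigma(sigma: float, n_frames: int) -> float:
    """Noise sd of a guide built from ``n_frames`` independent frames."""
    return float(sigma) * np.sqrt(n_frames)


def _dct2(block: np.ndarray) -> np.ndarray:
    return scipy.fft.dctn(block, type=2, norm="ortho")


def _hard(coeffs: np.ndarray, threshold: float) -> np.ndarray:
    if threshold <= 0:
        # |c| <= 0 only zeroes exact zeros: the identity on the support.
        return coeffs
    return np.where(np.abs(coeffs) <= threshold, 0.0, coeffs)


def prefiltered_distance(
    guide: GuideImage,
    x_ref: tuple[int, int],
    x: tuple[int, int],
    block_size: int,
    prefilter_threshold: float = 2.0,
    sigma_guide: float = 1.0,
) -> float:
    """Prefiltered block distance on the guide image.

    Both blocks are DCT-transformed and hard-thresholded at
    ``prefilter_threshold * sigma_guide``; the squared l2 distance of the
    surviving coefficients is divided by the block area ``N**2``.
    """
    n = block_size
    h, w = guide.data.shape
    for (r, c) in (x_ref, x):
        if not (0 <= r <= h - n and 0 <= c <= w - n):
            raise IndexError(f"block at {(r, c)} not inside the guide image")
    thr = prefilter_threshold * sigma_guide
    a = _hard(_dct2(guide.data[x_ref[0] : x_ref[0] + n, x_ref[1] : x_ref[1] + n]), thr)
    b = _hard(_dct2(guide.data[x[0] : x[0] + n, x[1] : x[1] + n]), thr)
    return float(np.sum((a - b) ** 2) / n**2)


class GuidedMatcher:
    """Block matcher over one guide image with precomputed block spectra.

    Precomputes the prefiltered DCT coefficients of every block position so
    that repeated matching over the reference grid costs one vectorized
    distance evaluation per reference.
    """

    def __init__(
        self,
        guide: GuideImage,
        cfg: MatchConfig,
        sigma_guide: float,
        tau: float | None = None,
        prefilter: bool = True,
    ) -> None:
        self.guide = guide
        self.cfg = cfg
        self.sigma_guide = float(sigma_guide)
        self.tau = cfg.tau_match if tau is None else float(tau)
        n = cfg.block_size
        blocks = sliding_window_view(guide.data, (n, n))
        coeffs = scipy.fft.dctn(blocks, type=2, norm="ortho", axes=(-2, -1))
        thr = cfg.prefilter_threshold * self.sigma_guide if prefilter else 0.0
        self._coeffs = _hard(coeffs, thr)
        self._n_pos = self._coeffs.shape[:2]

    def match(self, x_ref: tuple[int, int]) -> MatchSet:
        cfg = self.cfg
        n = cfg.block_size
        h_pos, w_pos = self._n_pos
        r0, c0 = x_ref
        if not (0 <= r0 < h_pos and 0 <= c0 < w_pos):
            raise IndexError(f"reference {x_ref} not a valid block position")
        half = (cfg.window - n) // 2
        rlo, rhi = max(0, r0 - half), min(h_pos, r0 + half + 1)
        clo, chi = max(0, c0 - half), min(w_pos, c0 + half + 1)
        ref = self._coeffs[r0, c0]
        win = self._coeffs[rlo:rhi, clo:chi]
        dist = np.sum((win - ref) ** 2, axis=(-2, -1)) / n**2
        thresh = self.tau * self.sigma_guide**2
        keep = dist <= thresh
        keep[r0 - rlo, c0 - clo] = False  # reference handled separately
        rows, cols = np.nonzero(keep)
        d = dist[rows, cols]
        order = np.argsort(d, kind="stable")  # raster order breaks ties
        order = order[: cfg.max_group - 1]
        members = [(r0, c0)] + [
            (int(rows[k] + rlo), int(cols[k] + clo)) for k in order
        ]
        distances = np.concatenate(([0.0], d[order]))
        return MatchSet(reference=(r0, c0), members=members, distances=distances)


def match_blocks(
    guide: GuideImage,
    x_ref: tuple[int, int],
    cfg: MatchConfig,
    sigma_guide: float = 1.0,
    tau: float | None = None,
    prefilter: bool = True,
) -> MatchSet:
    """Match blocks in the search window around ``x_ref`` on the guide.

    Candidates within the ``cfg.window`` square around the reference whose
    prefiltered distance is at most ``tau * sigma_guide**2`` are kept,
    sorted by ascending distance (reference first, raster order on ties)
    and truncated to ``cfg.max_group`` members.  Deterministic.
    """
    return GuidedMatcher(guide, cfg, sigma_guide, tau=tau, prefilter=prefilter).match(
        x_ref
    )


def stack_group(
    sino: StabilizedSinogram,
    match: MatchSet,
    block_size: int,
    slice_index: int = 0,
) -> BlockGroup:
    """Stack matched blocks from every frame into a 4-D group.

    ``stack[i, j, t, m]`` is the sinogram value of frame ``t`` at member
    ``m``'s position offset by ``(i, j)``; the result has shape
    ``N x N x |T| x |S|``.
    """
    n = block_size
    _, _, h, w = sino.data.shape
    rows = np.array([m[0] for m in match.members])
    cols = np.array([m[1] for m in match.members])
    if rows.min() < 0 or cols.min() < 0 or rows.max() > h - n or cols.max() > w - n:
        raise IndexError("match member block out of sinogram bounds")
    plane = sino.data[:, slice_index]  # (T, H, W)
    idx_r = rows[:, None, None] + np.arange(n)[None, :, None]  # (S, N, 1)
    idx_c = cols[:, None, None] + np.arange(n)[None, None, :]  # (S, 1, N)
    stack = plane[:, idx_r, idx_c]  # (T, S, N, N)
    return BlockGroup(
        stack=np.ascontiguousarray(stack.transpose(2, 3, 0, 1)),
        match=match,
        slice_index=slice_index,
    )


def reference_grid(shape: tuple[int, int], block_size: int, step: int) -> list[tuple[int, int]]:
    """Reference-block positions covering a slice on a regular step grid.

    The final row/column is snapped to the image border so every pixel is
    covered by at least one block.
    """
    h, w = shape
    n = block_size
    if h < n or w < n:
        raise ValueError("slice smaller than the block size")

    def axis_positions(extent: int) -> list[int]:
        pos = list(range(0, extent - n + 1, step))
        if pos[-1] != extent - n:
            pos.append(extent - n)
        return pos

    return [(r, c) for r in axis_positions(h) for c in axis_positions(w)]
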