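"""Synthetic dynamic-PET generation: kinetics, phantoms, projection, noise.

The simulator produces the inputs the denoiser is validated on:

* a Feng-model arterial input function (plasma activity versus time),
* tissue time-activity curves (TACs) from the irreversible two-tissue
  compartment model with rate constants ``K1`` (mL/min/mL), ``k2``, ``k3``
  (1/min) and blood volume fraction ``Fv``,
* phantom volumes — a Shepp–Logan stack with physical decay only, and a
  procedural brain-like label phantom (gray-matter shell, white-matter core,
  ventricles, one 4x4x4-voxel tumor) driven by the compartment TACs,
* parallel-beam forward projection (scikit-image Radon transform) into
  per-slice sinograms, and
* Poisson count noise at a stated total photon budget.

Default study conditions: 8 frames of 6 min, 128x128 matrix with 1.5 mm
voxels, 128 projection angles, and a total photon budget of 5e8 counts for
the full 128-slice volume (scaled proportionally when fewer slices are
simulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from skimage.transform import radon

__all__ = [
    "KineticParams",
    "PhantomSpec",
    "FrameScheme",
    "DynamicSinogram",
    "PAPER_TISSUES",
    "F18_HALF_LIFE_MIN",
    "input_function",
    "tac_2tc",
    "frame_average",
    "make_shepp_logan_volume",
    "make_brain_like_phantom",
    "make_dynamic_phantom",
    "forward_project",
    "add_poisson_noise",
]

#: F-18 physical half-life in minutes.
F18_HALF_LIFE_MIN = 109.77

#: Feng arterial input-function defaults (activity in arbitrary kBq/mL-like
#: units, rates in 1/min): Cp(t) = (A1*t - A2 - A3)*exp(-l1*t)
#: + A2*exp(-l2*t) + A3*exp(-l3*t).
FENG_PARAMS = {
    "A1": 851.1,
    "A2": 21.88,
    "A3": 20.81,
    "l1": 4.1339,
    "l2": 0.1191,
    "l3": 0.0104,
}


class DegenerateModelError(ValueError):
    """Raised when the compartment model is degenerate (k2 + k3 = 0)."""


@dataclass(frozen=True)
class KineticParams:
    """Two-tissue-compartment rate constants for one tissue."""

    K1: float  # mL/min/mL
    k2: float  # 1/min
    k3: float  # 1/min
    Fv: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be nonnegative")
        if not 0.0 <= self.Fv <= 1.0:
            raise ValueError("Fv must be a fraction in [0, 1]")


#: FDG-like rate constants for the three simulated tissues.
PAPER_TISSUES: dict[str, KineticParams] = {
    "gray_matter": KineticParams(K1=0.1104, k2=0.1910, k3=0.1024, Fv=0.0),
    "white_matter": KineticParams(K1=0.0622, k2=0.1248, k3=0.0070, Fv=0.0),
    "tumor": KineticParams(K1=0.0640, k2=0.0890, k3=0.0738, Fv=0.0),
}

#: Label assignment in the brain-like phantom (0 = background/ventricle CSF,
#: assumed tracer-free).
BRAIN_LABELS = {"gray_matter": 1, "white_matter": 2, "tumor": 3}


@dataclass
class FrameScheme:
    """Dynamic framing protocol."""

    n_frames: int = 8
    frame_duration: float = 6.0  # minutes
    half_life: float = F18_HALF_LIFE_MIN  # minutes; np.inf disables decay

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.frame_duration <= 0:
            raise ValueError("need at least one frame of positive duration")

    @property
    def edges(self) -> np.ndarray:
        """Frame boundary times in minutes, length n_frames + 1."""
        return np.arange(self.n_frames + 1) * self.frame_duration

    @property
    def durations_seconds(self) -> np.ndarray:
        return np.full(self.n_frames, self.frame_duration * 60.0)


@dataclass
class PhantomSpec:
    """A label phantom with per-tissue kinetics (plus optional intensities).

    ``labels`` is a (slices, H, W) integer volume; ``tissue_params`` maps
    label values to kinetic parameters.  ``values``, when given, is a float
    volume of the same shape used by decay-only simulation.
    """

    labels: np.ndarray
    tissue_params: dict[int, KineticParams] = field(default_factory=dict)
    voxel_size: float = 1.5  # mm
    tumor_extent: int = 4  # voxels per side
    values: np.ndarray | None = None
    tissue_names: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D (slices, H, W) volume")

    def centroid(self, label: int) -> tuple[int, int, int]:
        """Rounded centroid of a label region."""
        idx = np.argwhere(self.labels == label)
        if idx.size == 0:
            raise ValueError(f"label {label} absent from phantom")
        return tuple(int(round(v)) for v in idx.mean(axis=0))

    def voi_center(self, label: int) -> tuple[int, int, int]:
        """Deterministic VOI center: the most interior voxel of the region.

        The voxel maximizing the Euclidean distance transform of the label
        mask; for convex regions (the tumor cube) this is the centroid, and
        for annular regions (the gray-matter shell) it stays inside the
        tissue, which a plain centroid does not.
        """
        from scipy.ndimage import distance_transform_edt

        mask = self.labels == label
        if not mask.any():
            raise ValueError(f"label {label} absent from phantom")
        dist = distance_transform_edt(mask)
        # mean of the deepest voxels near the global argmax (not of the
        # whole deepest set, which for an annulus would fall outside the
        # tissue) so the VOI centers on symmetric inserts like the tumor
        p0 = np.array(np.unravel_index(np.argmax(dist), mask.shape))
        deepest = np.argwhere(dist >= dist.max() - 1e-9)
        local = deepest[np.abs(deepest - p0).max(axis=1) <= 2]
        return tuple(int(round(v)) for v in local.mean(axis=0))


@dataclass
class DynamicSinogram:
    """Noisy dynamic sinogram in counts, with the noiseless reference."""

    counts: np.ndarray  # (frames, slices, angles, bins), integer counts
    frame_durations: np.ndarray  # seconds
    clean: np.ndarray | None = None  # expected counts at the same scale

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValueError("counts must be (frames, slices, angles, bins)")
        self.frame_durations = np.asarray(self.frame_durations, dtype=np.float64)


def input_function(t_grid: np.ndarray, params: dict | None = None) -> np.ndarray:
    """Feng-model arterial plasma curve on a time grid (minutes).

    Cp(t) = (A1*t - A2 - A3)*exp(-l1*t) + A2*exp(-l2*t) + A3*exp(-l3*t),
    which starts at zero, peaks within the first minute and decays slowly.
    """
    t = np.asarray(t_grid, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("time grid must be nonnegative")
    p = dict(FENG_PARAMS)
    if params:
        p.update(params)
    cp = (
        (p["A1"] * t - p["A2"] - p["A3"]) * np.exp(-p["l1"] * t)
        + p["A2"] * np.exp(-p["l2"] * t)
        + p["A3"] * np.exp(-p["l3"] * t)
    )
    return cp


def _exp_convolve(cp: np.ndarray, t: np.ndarray, alpha: float) -> np.ndarray:
    """Exact ``exp(-alpha t) (*) Cp`` for a piecewise-linear Cp on grid t."""
    out = np.zeros_like(cp)
    dt = np.diff(t)
    e = np.exp(-alpha * dt)
    # integral over one interval of exp(-alpha(dt-u)) * (c0 + (c1-c0) u/dt)
    i0 = (1.0 - e) / alpha
    i1 = (dt / alpha) - i0 / alpha
    for k in range(len(dt)):
        seg = cp[k] * i0[k] + (cp[k + 1] - cp[k]) / dt[k] * i1[k]
        out[k + 1] = out[k] * e[k] + seg
    return out


def tac_2tc(
    params: KineticParams, cp: np.ndarray, t_grid: np.ndarray
) -> np.ndarray:
    """Tissue TAC of the irreversible two-tissue compartment model.

    C_T(t) = K1*k3/(k2+k3) * int_0^t Cp
           + K1*k2/(k2+k3) * exp(-(k2+k3) t) (*) Cp
           + Fv * Cp(t)

    evaluated on ``t_grid`` (minutes) with ``cp`` sampled on the same grid.
    """
    t = np.asarray(t_grid, dtype=np.float64)
    cp = np.asarray(cp, dtype=np.float64)
    if cp.shape != t.shape:
        raise ValueError("cp must be sampled on t_grid")
    alpha = params.k2 + params.k3
    if alpha <= 0:
        raise DegenerateModelError("two-tissue model requires k2 + k3 > 0")
    if params.K1 == 0 and params.Fv == 0:
        return np.zeros_like(t)
    cumint = cumulative_trapezoid(cp, t, initial=0.0)
    conv = _exp_convolve(cp, t, alpha)
    ct = (
        params.K1 * params.k3 / alpha * cumint
        + params.K1 * params.k2 / alpha * conv
        + params.Fv * cp
    )
    return np.maximum(ct, 0.0)


def frame_average(
    curve: np.ndarray, t_grid: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Time-average a curve over each frame window by trapezoid integration."""
    t = np.asarray(t_grid, dtype=np.float64)
    out = np.empty(len(edges) - 1)
    for f in range(len(out)):
        lo, hi = edges[f], edges[f + 1]
        grid = np.union1d(t[(t >= lo) & (t <= hi)], [lo, hi])
        vals = np.interp(grid, t, curve)
        out[f] = np.trapezoid(vals, grid) / (hi - lo)
    return out


def _decay_curve(t: np.ndarray, half_life: float) -> np.ndarray:
    if not np.isfinite(half_life):
        return np.ones_like(t)
    return np.exp2(-t / half_life)


def make_shepp_logan_volume(size: int = 128, n_slices: int = 4) -> PhantomSpec:
    """Shepp–Logan intensity stack masked to the scanner field of view."""
    from skimage.data import shepp_logan_phantom
    from skimage.transform import resize

    img = shepp_logan_phantom()
    img = resize(img, (size, size), order=1, anti_aliasing=True)
    yy, xx = np.mgrid[0:size, 0:size]
    fov = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= (size // 2) ** 2
    img = np.where(fov, img, 0.0)
    values = np.repeat(img[None], n_slices, axis=0)
    return PhantomSpec(labels=np.zeros_like(values, dtype=np.int32), values=values)


def make_brain_like_phantom(
    size: int = 128, seed: int = 0, n_slices: int = 8
) -> PhantomSpec:
    """Procedural brain-like label phantom.

    Concentric smooth ellipsoids: a gray-matter shell (label 1) around a
    white-matter core (label 2), tracer-free ventricles (label 0, as the
    background) and one tumor insert of exactly 4x4x4 voxels (label 3)
    placed in the white matter.  The seed jitters the ellipse axes slightly;
    the construction is deterministic for a fixed (size, seed, n_slices).
    """
    if size < 64:
        raise ValueError("phantom size must be at least 64")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(0.97, 1.03, size=4)
    labels = np.zeros((n_slices, size, size), dtype=np.int32)
    c = (size - 1) / 2.0
    zc = (n_slices - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    # axial extent of the head: ellipsoidal in z when several slices exist
    z_half = max(n_slices / 2.0, 1.0)
    for z in range(n_slices):
        zf = ((z - zc) / (z_half + 0.5)) ** 2
        scale = np.sqrt(max(1.0 - zf, 0.0))
        if scale <= 0:
            continue
        a_out = 0.42 * size * jitter[0] * scale
        b_out = 0.34 * size * jitter[1] * scale
        a_in = 0.33 * size * jitter[2] * scale
        b_in = 0.25 * size * jitter[3] * scale
        outer = ((yy - c) / a_out) ** 2 + ((xx - c) / b_out) ** 2 <= 1.0
        inner = ((yy - c) / max(a_in, 1e-6)) ** 2 + (
            (xx - c) / max(b_in, 1e-6)
        ) ** 2 <= 1.0
        vent = ((yy - c) / (0.08 * size)) ** 2 + (
            (xx - c) / (0.045 * size)
        ) ** 2 <= 1.0
        sl = np.zeros((size, size), dtype=np.int32)
        sl[outer] = BRAIN_LABELS["gray_matter"]
        sl[inner] = BRAIN_LABELS["white_matter"]
        sl[vent & inner] = 0
        labels[z] = sl
    # 4x4x4 tumor in white matter, offset from center, axially centered
    tz = max(int(np.floor(zc)) - 1, 0) if n_slices >= 4 else 0
    ty = int(round(c - 0.12 * size))
    tx = int(round(c + 0.10 * size))
    labels[tz : tz + 4, ty : ty + 4, tx : tx + 4] = BRAIN_LABELS["tumor"]
    params = {
        BRAIN_LABELS["gray_matter"]: PAPER_TISSUES["gray_matter"],
        BRAIN_LABELS["white_matter"]: PAPER_TISSUES["white_matter"],
        BRAIN_LABELS["tumor"]: PAPER_TISSUES["tumor"],
    }
    return PhantomSpec(
        labels=labels,
        tissue_params=params,
        tissue_names=dict(BRAIN_LABELS),
    )


def make_dynamic_phantom(
    spec: PhantomSpec,
    scheme: FrameScheme,
    mode: str = "kinetic",
    t_step: float = 0.05,
) -> np.ndarray:
    """Frame-averaged 4-D activity volume (frames, slices, H, W).

    ``decay_only`` scales the static intensity volume by the frame-averaged
    physical-decay factor.  ``kinetic`` assigns each labelled voxel its
    tissue's frame-averaged compartment TAC (times the decay factor).
    """
    edges = scheme.edges
    t = np.arange(0.0, edges[-1] + t_step / 2, t_step)
    decay = _decay_curve(t, scheme.half_life)
    if mode == "decay_only":
        if spec.values is None:
            base = spec.labels.astype(np.float64)
        else:
            base = np.asarray(spec.values, dtype=np.float64)
        factors = frame_average(decay, t, edges)
        return factors[:, None, None, None] * base[None]
    if mode != "kinetic":
        raise ValueError(f"unknown mode {mode!r}")
    cp = input_function(t)
    present = [int(l) for l in np.unique(spec.labels) if l != 0]
    missing = [l for l in present if l not in spec.tissue_params]
    if missing:
        raise ValueError(f"no kinetic parameters for labels {missing}")
    frames = np.zeros((scheme.n_frames, *spec.labels.shape))
    for label in present:
        tac = tac_2tc(spec.tissue_params[label], cp, t) * decay
        fa = frame_average(tac, t, edges)
        mask = spec.labels == label
        for f in range(scheme.n_frames):
            frames[f][mask] = fa[f]
    return frames


def forward_project(volume_frame: np.ndarray, n_angles: int = 128) -> np.ndarray:
    """Parallel-beam Radon transform of each slice: (slices, angles, bins).

    Angles are uniformly spaced over [0, 180) degrees; bins equal the slice
    side (field-of-view circle geometry).
    """
    vol = np.asarray(volume_frame, dtype=np.float64)
    if vol.ndim != 3 or vol.shape[1] != vol.shape[2]:
        raise ValueError("expected a (slices, N, N) volume with square slices")
    thetas = np.arange(n_angles) * (180.0 / n_angles)
    out = np.empty((vol.shape[0], n_angles, vol.shape[1]))
    for s in range(vol.shape[0]):
        out[s] = radon(vol[s], theta=thetas, circle=True, preserve_range=True).T
    return out


def project_dynamic(volume: np.ndarray, n_angles: int = 128) -> np.ndarray:
    """Forward-project every frame: (frames, slices, angles, bins)."""
    return np.stack([forward_project(frame, n_angles) for frame in volume])


def add_poisson_noise(
    clean_sino: np.ndarray,
    total_counts: float,
    seed: int,
    frame_durations: np.ndarray | None = None,
) -> DynamicSinogram:
    """Scale a clean sinogram to a photon budget and sample Poisson counts.

    The sinogram is scaled globally (over all frames and slices) so its sum
    equals ``total_counts``; early high-activity frames therefore receive
    proportionally more counts, as in a real acquisition.
    """
    clean = np.asarray(clean_sino, dtype=np.float64)
    if clean.ndim != 4:
        raise ValueError("clean sinogram must be (frames, slices, angles, bins)")
    if np.any(clean < 0):
        raise ValueError("clean sinogram must be nonnegative")
    if not total_counts > 0:
        raise ValueError("total_counts must be positive")
    total = clean.sum()
    if total <= 0:
        raise ValueError("cannot impose a count budget on an all-zero sinogram")
    scaled = clean * (float(total_counts) / total)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(scaled)
    if frame_durations is None:
        frame_durations = np.full(clean.shape[0], 360.0)
    return DynamicSinogram(
        counts=counts, frame_durations=frame_durations, clean=scaled
    )
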