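"""Seeded generators for every input class the quantification pipeline consumes.

Real inputs to the pipeline are time-lapse images and cell tracks from tumor
spheroids embedded in a 1D metabolic-gradient chamber. None of those raw data
are redistributable, so this module synthesizes inputs with the same
statistical structure: star-convex spheroid masks with controllable boundary
ruffling, nuclei point clouds, 2D random-walk track ensembles at the imaging
cadence used in such experiments (15–30 min frames over ~24 h), monotone
ratiometric gradient images, and exponential drug-intensity decay profiles.

Every generator is a pure function of its spec (including the seed): the same
spec reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GradientProfile, LabelMask, PointSet, Track, TrackSet
from .errors import SpecError

WALK_MODELS = ("brownian", "ballistic", "persistent", "biased")


# ---------------------------------------------------------------------------
# spheroid masks
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpec:
    """Star-convex spheroid outline r(θ) = R·(1 + A·S(θ)).

    ``S(θ)`` is the mean of ``sin(kθ + φ_k)`` over the requested angular
    modes ``k`` with seeded random phases ``φ_k``; dividing by the number of
    modes keeps ``|A·S| ≤ A < 1`` so the boundary never self-intersects.
    ``ruffle_amplitude`` 0 gives a disk; larger values give the protrusive,
    ruffled outlines characteristic of invasive ischemic spheroids.
    """

    radius_px: float = 100.0
    ruffle_amplitude: float = 0.0
    ruffle_modes: tuple[int, ...] = (8,)
    pixel_size_um: float = 1.0
    seed: int = 0
    canvas_px: int | None = None  # default: fits radius*(1+amplitude) + margin

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise SpecError("radius_px must be positive")
        if not (0 <= self.ruffle_amplitude < 1):
            raise SpecError("ruffle_amplitude must lie in [0, 1)")
        if any(int(k) < 2 for k in self.ruffle_modes):
            raise SpecError("ruffle modes must be integers >= 2")
        if self.pixel_size_um <= 0:
            raise SpecError("pixel_size_um must be positive")


def boundary_radius(spec: ShapeSpec, theta: np.ndarray) -> np.ndarray:
    """Analytic boundary radius r(θ) in pixels for a given shape spec."""
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0, 2 * np.pi, size=len(spec.ruffle_modes))
    theta = np.asarray(theta, dtype=float)
    s = np.zeros_like(theta)
    for k, phi in zip(spec.ruffle_modes, phases):
        s += np.sin(int(k) * theta + phi)
    s /= max(len(spec.ruffle_modes), 1)
    return spec.radius_px * (1.0 + spec.ruffle_amplitude * s)


def make_spheroid_mask(spec: ShapeSpec) -> LabelMask:
    """Rasterize the analytic star-convex boundary into a single-label mask."""
    r_max = spec.radius_px * (1 + spec.ruffle_amplitude)
    size = spec.canvas_px or int(np.ceil(2 * r_max)) + 8
    if size < 2 * r_max:
        raise SpecError(
            f"canvas {size} px cannot contain radius*(1+amplitude) = {r_max:.1f} px"
        )
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    dx = cols - c
    dy = rows - c
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    inside = rho <= boundary_radius(spec, theta)
    return LabelMask(inside.astype(np.int32), pixel_size_um=spec.pixel_size_um)


# ---------------------------------------------------------------------------
# nuclei point clouds
# ---------------------------------------------------------------------------

def make_nuclei_points(
    n: int, box_um: tuple[float, float], dispersion: float = 0.0, seed: int = 0
) -> PointSet:
    """n nuclei in a box: a regular grid jittered by Gaussian noise.

    ``dispersion`` is the jitter standard deviation in μm; 0 returns the
    exact grid. At least 3 points are required for downstream triangulation.
    """
    if n < 3:
        raise SpecError("need n >= 3 points for triangulation")
    if dispersion < 0:
        raise SpecError("dispersion must be non-negative")
    bx, by = float(box_um[0]), float(box_um[1])
    ncol = int(np.ceil(np.sqrt(n * bx / by))) or 1
    nrow = int(np.ceil(n / ncol))
    gx = np.linspace(0, bx, ncol) if ncol > 1 else np.array([bx / 2])
    gy = np.linspace(0, by, nrow) if nrow > 1 else np.array([by / 2])
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])[:n]
    if dispersion > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0, dispersion, size=pts.shape)
    return PointSet(pts)


# ---------------------------------------------------------------------------
# track ensembles
# ---------------------------------------------------------------------------

@dataclass
class WalkSpec:
    """Ensemble of 2D random-walk tracks at fixed imaging cadence.

    Defaults follow the experimental cadence: 15-min frames over 24 h
    (96 steps). ``step_scale_um`` is the RMS displacement per frame.

    models
        brownian    i.i.d. Gaussian steps (diffusive, MSD exponent 1)
        ballistic   constant random heading per track (MSD exponent 2)
        persistent  constant speed, heading decorrelating as exp(-dt/P)
                    with P = ``persistence_time_min``
        biased      brownian plus the constant drift ``bias_vector_um``
    """

    model: str = "brownian"
    n_tracks: int = 100
    n_steps: int = 96
    dt_min: float = 15.0
    step_scale_um: float = 2.0
    persistence_time_min: float = 120.0
    bias_vector_um: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in WALK_MODELS:
            raise SpecError(f"unknown walk model {self.model!r}; use one of {WALK_MODELS}")
        if self.n_steps < 2:
            raise SpecError("n_steps must be >= 2")
        if self.n_tracks < 1:
            raise SpecError("n_tracks must be >= 1")
        if self.step_scale_um <= 0:
            raise SpecError("step_scale_um must be positive")
        if self.dt_min <= 0:
            raise SpecError("dt_min must be positive")
        if self.model == "persistent" and self.persistence_time_min <= 0:
            raise SpecError("persistence_time_min must be positive")


def heading_correlation(spec: WalkSpec) -> float:
    """Per-step heading autocorrelation α = exp(-dt/P) of the persistent walk."""
    return float(np.exp(-spec.dt_min / spec.persistence_time_min))


def correlated_walk_msd(spec: WalkSpec, n_lags: int) -> np.ndarray:
    """Closed-form ensemble MSD of the constant-speed correlated walk.

    For step length l and heading correlation α per step,
    ``MSD(n) = l²·[n(1+α)/(1-α) - 2α(1-α^n)/(1-α)²]``; this is exact for the
    generator used here and serves as an independent oracle in tests. The
    α→1 limit is ballistic (l²n²), α→0 is diffusive (l²n).
    """
    a = heading_correlation(spec)
    n = np.arange(1, n_lags + 1, dtype=float)
    l2 = spec.step_scale_um**2
    if a >= 1.0:
        return l2 * n**2
    return l2 * (n * (1 + a) / (1 - a) - 2 * a * (1 - a**n) / (1 - a) ** 2)


def make_tracks(spec: WalkSpec) -> TrackSet:
    """Generate the track ensemble described by ``spec`` (seed-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_tracks, spec.n_steps
    t = np.arange(m) * spec.dt_min
    if spec.model == "brownian":
        steps = rng.normal(0, spec.step_scale_um / np.sqrt(2), size=(n, m - 1, 2))
    elif spec.model == "ballistic":
        theta = rng.uniform(0, 2 * np.pi, size=n)
        u = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        steps = spec.step_scale_um * u[:, None, :] * np.ones((n, m - 1, 1))
    elif spec.model == "persistent":
        a = heading_correlation(spec)
        # heading increment sd chosen so E[cos Δθ] = exp(-sd²/2) = α
        sd = np.sqrt(-2.0 * np.log(a)) if a < 1 else 0.0
        theta0 = rng.uniform(0, 2 * np.pi, size=(n, 1))
        dtheta = rng.normal(0, sd, size=(n, m - 1))
        theta = theta0 + np.concatenate(
            [np.zeros((n, 1)), np.cumsum(dtheta[:, :-1], axis=1)], axis=1
        )
        steps = spec.step_scale_um * np.stack([np.cos(theta), np.sin(theta)], axis=2)
    else:  # biased
        steps = rng.normal(0, spec.step_scale_um / np.sqrt(2), size=(n, m - 1, 2))
        steps = steps + np.asarray(spec.bias_vector_um, dtype=float)
    xy = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    tracks = [Track(i, t, xy[i, :, 0], xy[i, :, 1]) for i in range(n)]
    return TrackSet(tracks)


# ---------------------------------------------------------------------------
# gradient images and decay profiles
# ---------------------------------------------------------------------------

@dataclass
class GradientImage:
    """Two-channel ratiometric image of a 1D chamber gradient.

    The gradient runs along the image columns; ``mm_per_px`` maps column
    index to distance from the opening (column 0 = opening).
    """

    channels: dict[str, np.ndarray]
    mm_per_px: float
    meta: dict = field(default_factory=dict)


def make_gradient_image(
    axis_length_mm: float,
    profile: GradientProfile,
    noise_sd: float = 0.0,
    seed: int = 0,
    px_per_mm: float = 10.0,
    n_rows: int = 32,
    denominator_level: float = 100.0,
    channel_names: tuple[str, str] = ("green", "blue"),
) -> GradientImage:
    """Render a ratio-vs-distance profile as a two-channel image.

    The denominator channel is flat at ``denominator_level``; the numerator
    equals ``denominator · profile(d)``, so the per-column channel ratio
    reproduces the profile. Gaussian read noise of sd ``noise_sd`` (intensity
    units) is added independently to both channels. The chamber gradient is
    one-dimensional, so a single gradient row is repeated along the short
    axis.
    """
    if profile.distance_mm[0] > 1e-9 or profile.distance_mm[-1] < axis_length_mm - 1e-9:
        raise SpecError(
            "profile must be defined over the whole axis [0, axis_length_mm]"
        )
    if noise_sd < 0:
        raise SpecError("noise_sd must be non-negative")
    n_cols = int(round(axis_length_mm * px_per_mm))
    d = (np.arange(n_cols) + 0.5) / px_per_mm
    ratio = np.interp(d, profile.distance_mm, profile.value)
    denom_row = np.full(n_cols, denominator_level)
    num_row = denom_row * ratio
    num = np.tile(num_row, (n_rows, 1))
    den = np.tile(denom_row, (n_rows, 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        num = num + rng.normal(0, noise_sd, size=num.shape)
        den = den + rng.normal(0, noise_sd, size=den.shape)
    return GradientImage(
        channels={channel_names[0]: num, channel_names[1]: den},
        mm_per_px=1.0 / px_per_mm,
        meta={"seed": seed, "noise_sd": noise_sd, "axis_length_mm": axis_length_mm},
    )


def make_decay_profile(
    c0: float,
    length_scale_mm: float,
    axis_length_mm: float,
    n_points: int = 25,
    value_kind: str = "intensity",
) -> GradientProfile:
    """Exponential decay profile value(d) = c0·exp(-d/length_scale).

    Emulates how a drug diffusing in from the chamber opening dilutes with
    distance; the profile starts at ``c0`` at the opening and decreases
    monotonically.
    """
    if c0 <= 0:
        raise SpecError("c0 must be positive")
    if length_scale_mm <= 0:
        raise SpecError("length_scale_mm must be positive")
    if axis_length_mm <= 0:
        raise SpecError("axis_length_mm must be positive")
    d = np.linspace(0, axis_length_mm, n_points)
    return GradientProfile(d, c0 * np.exp(-d / length_scale_mm), value_kind=value_kind)
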