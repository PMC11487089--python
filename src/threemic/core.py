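"""Shared in-memory containers.

Conventions used throughout the package:

* image pixels are indexed ``[row, col]``; ``pixel_size_um`` converts to μm
* track positions are in μm, times in minutes
* chamber distances are in mm, measured from the nutrient opening
* the opening (high nutrients) lies toward ``-x`` in image coordinates
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, TrackIntegrityError

#: minimum number of foreground pixels for a measurable object
MIN_OBJECT_PIXELS = 16


@dataclass
class LabelMask:
    """2D integer label image. 0 is background; positive labels are objects."""

    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError("label mask must be 2D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise FormatError("label mask must have an integer dtype")
        if self.pixels.min() < 0:
            raise FormatError("labels must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.pixels)
        return lab[lab > 0]


@dataclass
class PointSet:
    """Planar point cloud (e.g., nuclei centroids), coordinates in μm."""

    xy: np.ndarray
    unit: str = "um"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise FormatError("point set must be an (n, 2) array")

    def __len__(self) -> int:
        return len(self.xy)


@dataclass
class Track:
    """Time-ordered positions of one cell."""

    track_id: int
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_min) == len(self.x_um) == len(self.y_um)):
            raise TrackIntegrityError(f"track {self.track_id}: ragged columns")
        if len(self.t_min) < 2:
            raise TrackIntegrityError(f"track {self.track_id}: needs >=2 samples")
        if np.any(np.diff(self.t_min) <= 0):
            raise TrackIntegrityError(
                f"track {self.track_id}: times must be strictly increasing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t_min)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    @property
    def duration_min(self) -> float:
        return float(self.t_min[-1] - self.t_min[0])

    def nominal_dt_min(self) -> float:
        """Median sampling interval; robust to occasional dropped frames."""
        return float(np.median(np.diff(self.t_min)))

    def missing_fraction(self) -> float:
        """Fraction of expected frames absent, inferred from the nominal dt."""
        dt = self.nominal_dt_min()
        if dt <= 0:
            return 0.0
        expected = round(self.duration_min / dt) + 1
        return max(0.0, 1.0 - self.n_samples / expected)


@dataclass
class TrackSet:
    """A collection of tracks sharing condition / position metadata."""

    tracks: list[Track]
    condition: str | None = None
    distance_mm: float | None = None

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]


@dataclass
class SpheroidRecord:
    """One spheroid: label mask, named intensity channels, chamber position."""

    mask: LabelMask
    channel_images: dict[str, np.ndarray]
    distance_mm: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.distance_mm < 0:
            raise FormatError("distance_mm must be >= 0")
        for name, img in self.channel_images.items():
            img = np.asarray(img)
            if img.shape != self.mask.pixels.shape:
                raise FormatError(
                    f"channel {name!r} shape {img.shape} does not match mask "
                    f"{self.mask.pixels.shape}"
                )
            self.channel_images[name] = img


@dataclass
class GradientProfile:
    """A quantity sampled along the chamber axis (distance from the opening)."""

    distance_mm: np.ndarray
    value: np.ndarray
    value_kind: str = "ratio"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.distance_mm) != len(self.value):
            raise FormatError("profile distance/value length mismatch")
        if len(self.distance_mm) and self.distance_mm.min() < 0:
            raise FormatError("profile distances must be non-negative")
        if np.any(np.diff(self.distance_mm) <= 0):
            raise FormatError("profile distances must be strictly increasing")

    def __len__(self) -> int:
        return len(self.distance_mm)
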