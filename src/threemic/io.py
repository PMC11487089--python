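"""Readers and writers for the package's on-disk formats.

Tracks travel as CSV with the schema ``track_id,frame,t_min,x_um,y_um``;
label masks and intensity channels as TIFF; profiles as CSV
``distance_mm,value``. Writers can attach a JSON sidecar carrying the
generating spec and seed so every artifact is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import GradientProfile, LabelMask, SpheroidRecord, Track, TrackSet
from .errors import FormatError

TRACK_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um"]


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sidecar(path: str | Path, spec) -> Path:
    """Write ``<path>.json`` describing how the artifact was generated."""
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(_jsonable(spec), indent=2, sort_keys=True))
    return side


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------


def write_tracks(trackset: TrackSet, path: str | Path, spec=None) -> None:
    rows = []
    for t in trackset:
        for f in range(t.n_samples):
            rows.append((t.track_id, f, t.t_min[f], t.x_um[f], t.y_um[f]))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False)
    if spec is not None:
        write_sidecar(path, spec)


def read_tracks(path: str | Path) -> TrackSet:
    """Read a track CSV; rows are re-sorted by (track_id, t_min).

    Malformed rows and duplicate (track_id, frame) pairs are rejected with
    the offending line numbers (1-based, header = line 1).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(df.columns) != TRACK_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(TRACK_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]
        raise FormatError(f"{path}: malformed rows at lines {lines}")
    df = numeric
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise FormatError(f"{path}: duplicate (track_id, frame) at lines {lines}")
    df = df.sort_values(["track_id", "t_min"], kind="stable")
    tracks = [
        Track(int(tid), g["t_min"].to_numpy(), g["x_um"].to_numpy(),
              g["y_um"].to_numpy())
        for tid, g in df.groupby("track_id", sort=True)
    ]
    return TrackSet(tracks)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_labels(mask: LabelMask, path: str | Path, spec=None) -> None:
    """Write a label mask as TIFF; pixel size goes in the resolution tags."""
    res = 1.0 / mask.pixel_size_um
    tifffile.imwrite(
        path,
        mask.pixels,
        resolution=(res, res),
        metadata={"unit": "um"},
    )
    if spec is not None:
        write_sidecar(path, spec)


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    return den / num


def read_labels(path: str | Path, pixel_size_um: float | None = None) -> LabelMask:
    """Read an integer label TIFF; pixel size from metadata unless given."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: label image must have integer dtype, "
                          f"got {data.dtype}")
    return LabelMask(data, pixel_size_um=pixel_size_um or meta_px or 1.0)


def write_channel(image: np.ndarray, path: str | Path, spec=None) -> None:
    tifffile.imwrite(path, np.asarray(image))
    if spec is not None:
        write_sidecar(path, spec)


def read_channels(
    mask_path: str | Path,
    channel_paths: dict[str, str | Path],
    distance_mm: float = 0.0,
    condition: str = "",
    pixel_size_um: float | None = None,
) -> SpheroidRecord:
    """Assemble a spheroid record from a label TIFF plus channel TIFFs."""
    mask = read_labels(mask_path, pixel_size_um=pixel_size_um)
    channels = {}
    for name, p in channel_paths.items():
        img = tifffile.imread(p)
        if img.shape != mask.pixels.shape:
            raise FormatError(
                f"channel {name!r} shape {img.shape} does not match mask "
                f"{mask.pixels.shape}"
            )
        channels[name] = img
    return SpheroidRecord(mask, channels, distance_mm=distance_mm,
                          condition=condition)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def write_profile(profile: GradientProfile, path: str | Path, spec=None) -> None:
    pd.DataFrame(
        {"distance_mm": profile.distance_mm, "value": profile.value}
    ).to_csv(path, index=False)
    if spec is not None:
        write_sidecar(path, spec)


def read_profile(path: str | Path, value_kind: str = "ratio") -> GradientProfile:
    df = pd.read_csv(path)
    if list(df.columns) != ["distance_mm", "value"]:
        raise FormatError(f"{path}: expected header distance_mm,value")
    return GradientProfile(df["distance_mm"].to_numpy(), df["value"].to_numpy(),
                           value_kind=value_kind)
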