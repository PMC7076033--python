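"""Shared in-memory containers.

The analysis passes four kinds of data between stages:

* :class:`IntensityImage` — a single-channel 2D grayscale image (the
  second-harmonic-generation collagen channel) with a physical pixel size.
* :class:`LabeledMask` — integer-labeled cell regions on the same grid.
* :class:`AngularProfile` — a 360-bin circular sequence indexed by degree,
  holding either the fiber spectral magnitude f(theta) or the mean cell
  radius g(theta).
* :class:`TrackSet` — time-stamped cell centroid tracks in micrometres.

Containers are thin, validated wrappers around numpy arrays / pandas
frames; they never copy unless validation requires a dtype change.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, LabelNotFoundError, ValidationError

#: default physical pixel size, micrometres per pixel.  At this scale a
#: 10-pixel spatial period corresponds to ~3.2 um, the low-pass cut-off
#: used by the fiber-orientation analysis.
DEFAULT_PIXEL_SIZE_UM = 0.32

#: number of 1-degree angular bins in a circular profile.
N_ANGLE_BINS = 360

PROFILE_KINDS = ("fiber_magnitude", "cell_radius")

TRACK_COLUMNS = ("track_id", "time_min", "x_um", "y_um")


@dataclass(frozen=True)
class IntensityImage:
    """2D grayscale image with physical pixel size.

    Parameters
    ----------
    pixels
        2D float array.  Raw images are expected in [0, 1]; images that
        have been mean-subtracted and windowed may contain negatives
        (``meta['windowed']`` is then set).
    pixel_size_um
        Physical size of one pixel in micrometres.
    meta
        Free-form provenance (e.g. generator parameters, windowing flag).
        Not used in equality comparisons.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValidationError("pixels must be finite")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def is_square(self) -> bool:
        return self.pixels.shape[0] == self.pixels.shape[1]

    def crop(self, x: int, y: int, size: int) -> "IntensityImage":
        """Square crop with top-left corner at column *x*, row *y*."""
        h, w = self.pixels.shape
        if size <= 0 or x < 0 or y < 0 or x + size > w or y + size > h:
            raise ValidationError(
                f"crop ({x},{y},{size}) outside image of shape {h}x{w}"
            )
        return dataclasses.replace(self, pixels=self.pixels[y:y + size, x:x + size])


@dataclass(frozen=True)
class LabeledMask:
    """Integer-labeled 2D cell mask; 0 is background."""

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValidationError("labels must be a non-empty 2D array")
        if not np.issubdtype(lab.dtype, np.integer):
            if np.any(lab != np.round(lab)):
                raise ValidationError("labels must be integers")
            lab = lab.astype(np.int32)
        if lab.min() < 0:
            raise ValidationError("labels must be nonnegative")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be positive")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def region(self, label: int) -> np.ndarray:
        """Boolean pixel mask of one label (no presence check)."""
        return self.labels == label


@dataclass(frozen=True)
class AngularProfile:
    """Circular sequence of 360 nonnegative values indexed by degree.

    ``kind='fiber_magnitude'`` holds the summed Fourier magnitude per
    1-degree direction bin, f(theta); it is centro-symmetric,
    f(theta) = f(theta+180), because the spectrum of a real image is.
    ``kind='cell_radius'`` holds the mean centroid-to-boundary distance
    per bin, g(theta), in pixels.
    """

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_ANGLE_BINS,):
            raise ValidationError(
                f"profile must have exactly {N_ANGLE_BINS} bins, got {v.shape}"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError("profile values must be finite and nonnegative")
        if self.kind not in PROFILE_KINDS:
            raise ValidationError(f"kind must be one of {PROFILE_KINDS}")
        object.__setattr__(self, "values", v)

    def shifted(self, shift_deg: int) -> "AngularProfile":
        """Profile circularly shifted so bin theta reads the old theta-shift."""
        return AngularProfile(np.roll(self.values, shift_deg), self.kind)


@dataclass(frozen=True)
class TrackSet:
    """Per-cell centroid tracks: columns track_id, time_min, x_um, y_um."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"track table missing columns {missing}")
        df = df.loc[:, list(TRACK_COLUMNS)].copy()
        df["track_id"] = df["track_id"].astype(int)
        for c in TRACK_COLUMNS[1:]:
            df[c] = df[c].astype(float)
        df = df.sort_values(["track_id", "time_min"], kind="stable")
        df = df.reset_index(drop=True)
        for tid, grp in df.groupby("track_id"):
            t = grp["time_min"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"track {tid} has non-increasing or duplicate timestamps"
                )
        object.__setattr__(self, "frame", df)

    def track_ids(self) -> list[int]:
        return sorted(self.frame["track_id"].unique().tolist())

    def points(self, track_id: int) -> np.ndarray:
        """(n, 3) array of (time_min, x_um, y_um) for one track."""
        grp = self.frame[self.frame["track_id"] == track_id]
        if grp.empty:
            raise LabelNotFoundError(track_id)
        return grp[["time_min", "x_um", "y_um"]].to_numpy()

    def __len__(self) -> int:
        return len(self.track_ids())

    # ---- I/O -----------------------------------------------------------
    @classmethod
    def from_mapping(
        cls, tracks: Mapping[int, Iterable[tuple[float, float, float]]]
    ) -> "TrackSet":
        rows = [
            (tid, t, x, y)
            for tid, pts in tracks.items()
            for (t, x, y) in pts
        ]
        return cls(pd.DataFrame(rows, columns=list(TRACK_COLUMNS)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackSet":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # noqa: BLE001 - re-raise as format error
            raise FormatError(f"cannot read track CSV {path}: {exc}") from exc
        try:
            return cls(df)
        except ValidationError as exc:
            raise FormatError(f"bad track CSV {path}: {exc}") from exc

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)
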