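"""Cell dynamics: track-based mean velocity and the cell-deformation index.

Osteoblast motility is summarised per tracked cell as the mean of
per-interval speeds (Euclidean displacement over elapsed time) along its
centroid track, in um/min — the convention of time-lapse tracking
software, robust to tracks with missing frames because each interval
uses its actual elapsed time.

Osteoclast activity is summarised by the cell-deformation index (CDI)
between two mask frames (nominally 10 min apart):

    CDI = |A xor B| / |A or B|

for the pixel sets A, B of the same label in the two frames — 0 for an
identical (static) footprint, 1 for disjoint footprints.  A low CDI
marks a static cell, which correlates with high bone-resorptive
activity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LabeledMask, TrackSet
from .errors import EmptyInputError, LabelNotFoundError, ValidationError


@dataclass(frozen=True)
class CdiResult:
    """Per-cell deformation between two frames."""

    label: int
    area_t0_px: int
    area_t1_px: int
    changed_area_px: int
    cdi: float


def mean_velocity(points: np.ndarray) -> float:
    """Mean speed of one track in um/min.

    ``points`` is an (n, 3) array of (time_min, x_um, y_um) rows; the
    result is the unweighted mean over consecutive intervals of
    displacement / elapsed time.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("track points must be an (n, 3) array of (t, x, y)")
    if pts.shape[0] < 2:
        raise ValidationError("mean velocity needs at least 2 time points")
    dt = np.diff(pts[:, 0])
    if np.any(dt <= 0):
        raise ValidationError("timestamps must be strictly increasing")
    disp = np.hypot(np.diff(pts[:, 1]), np.diff(pts[:, 2]))
    return float(np.mean(disp / dt))


def cohort_velocity(tracks: TrackSet) -> tuple[pd.DataFrame, float, float]:
    """Per-track mean velocities plus the cohort mean and SD.

    Each data point is one cell.  Returns ``(table, mean, sd)``; the SD
    is the sample standard deviation over tracks (0 for a single track).
    """
    ids = tracks.track_ids()
    if not ids:
        raise EmptyInputError("track set is empty")
    vels = [mean_velocity(tracks.points(tid)) for tid in ids]
    table = pd.DataFrame({"track_id": ids, "mean_velocity_um_min": vels})
    v = np.asarray(vels)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return table, float(v.mean()), sd


def cdi(mask_t0: LabeledMask, mask_t1: LabeledMask, label: int) -> CdiResult:
    """Cell-deformation index of one label between two frames.

    CDI = changed area (symmetric difference) / union area, in [0, 1].
    Raises :class:`LabelNotFoundError` if the label is absent from
    either frame (cell lost by tracking).
    """
    if mask_t0.shape != mask_t1.shape:
        raise ValidationError("mask frames must share the same grid")
    a = mask_t0.region(label)
    b = mask_t1.region(label)
    if not a.any() or not b.any():
        raise LabelNotFoundError(label)
    changed = int(np.count_nonzero(a ^ b))
    union = int(np.count_nonzero(a | b))
    return CdiResult(
        label=int(label),
        area_t0_px=int(np.count_nonzero(a)),
        area_t1_px=int(np.count_nonzero(b)),
        changed_area_px=changed,
        cdi=changed / union,
    )


def cdi_table(mask_t0: LabeledMask, mask_t1: LabeledMask) -> pd.DataFrame:
    """CDI for every label present in both frames."""
    common = sorted(set(mask_t0.label_ids()) & set(mask_t1.label_ids()))
    if not common:
        raise EmptyInputError("no labels present in both frames")
    rows = [cdi(mask_t0, mask_t1, int(lab)) for lab in common]
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "area_t0_px": [r.area_t0_px for r in rows],
            "area_t1_px": [r.area_t1_px for r in rows],
            "changed_area_px": [r.changed_area_px for r in rows],
            "cdi": [r.cdi for r in rows],
        }
    )
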