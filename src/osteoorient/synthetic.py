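"""Synthetic images, masks and tracks with known ground truth.

This module generates the inputs the analysis consumes — oriented
fiber textures standing in for the second-harmonic-generation collagen
channel, labeled elliptical cell masks, centroid tracks, and deforming
mask pairs — with every ground-truth property (orientation dispersion,
eccentricity, speed, deformation) set explicitly, so each downstream
metric can be validated by parameter recovery.

Fiber orientations are axial (180-degree periodic) quantities, so they
are sampled with the standard doubled-angle trick: draw from a von Mises
distribution on 2*theta with concentration kappa and halve the result.
kappa = 0 gives an isotropic field, large kappa a nearly parallel one;
the early-stage / late-stage contrast of forming bone is modelled as a
high-kappa field with aligned spindle cells versus an isotropic field
with rounded, randomly oriented cells (see :func:`scenario_specs`).

All generators are bit-deterministic under their seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line_aa

from .containers import DEFAULT_PIXEL_SIZE_UM, IntensityImage, LabeledMask, TrackSet
from .errors import EmptyInputError, PlacementError, ValidationError

#: retries per cell before overlap-free placement is declared impossible.
MAX_PLACEMENT_RETRIES = 1000

_FULL_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FiberFieldSpec:
    """Parameters of a synthetic oriented fiber texture.

    ``concentration`` is the von Mises kappa on the doubled-angle scale:
    0 yields uniformly distributed orientations, values above ~20 an
    essentially parallel field.  ``mean_orientation_deg`` is the mean
    fiber direction in image coordinates (from +x toward +y).
    """

    width_px: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    mean_orientation_deg: float = 0.0
    concentration: float = 0.0
    n_fibers: int = 2000
    fiber_width_px: float = 2.0
    background_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 64:
            raise ValidationError("width_px must be >= 64")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be positive")
        if not (0 <= self.mean_orientation_deg < 180):
            raise ValidationError("mean_orientation_deg must be in [0, 180)")
        if self.concentration < 0:
            raise ValidationError("concentration (kappa) must be nonnegative")
        if self.n_fibers < 0:
            raise ValidationError("n_fibers must be nonnegative")
        if not (self.fiber_width_px > 0):
            raise ValidationError("fiber_width_px must be positive")
        if self.background_noise_sd < 0:
            raise ValidationError("background_noise_sd must be nonnegative")


@dataclass(frozen=True)
class CellPopulationSpec:
    """Parameters of a synthetic elliptical cell population.

    ``orientation_deg`` is either a fixed angle in [0, 180), the string
    ``'match_fibers'`` (cells elongated along the fiber mean direction,
    supplied at generation time), or ``'random'`` (independent uniform
    orientation per cell).  Ellipse half-axes are chosen so that
    eccentricity = sqrt(1 - b^2/a^2) holds exactly before
    rasterization.
    """

    n_cells: int = 10
    eccentricity: float = 0.8
    orientation_deg: float | Literal["match_fibers", "random"] = "random"
    mean_area_px: float = 1257.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be positive")
        if not (0 <= self.eccentricity < 1):
            raise ValidationError("eccentricity must be in [0, 1)")
        if isinstance(self.orientation_deg, str):
            if self.orientation_deg not in ("match_fibers", "random"):
                raise ValidationError(
                    "orientation_deg must be an angle, 'match_fibers' or 'random'"
                )
        elif not (0 <= float(self.orientation_deg) < 180):
            raise ValidationError("orientation_deg must be in [0, 180)")
        if not (self.mean_area_px > 0):
            raise ValidationError("mean_area_px must be positive")


@dataclass(frozen=True)
class ScenarioLabel:
    """Named stage of the early/late bone-formation contrast."""

    stage: Literal["day10like", "day21like"]

    def __post_init__(self) -> None:
        if self.stage not in ("day10like", "day21like"):
            raise ValidationError("stage must be 'day10like' or 'day21like'")


def sample_fiber_orientations(spec: FiberFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Axial fiber orientations in degrees, von Mises on doubled angles."""
    mu = math.radians(2.0 * spec.mean_orientation_deg)
    doubled = rng.vonmises(mu, spec.concentration, size=spec.n_fibers)
    return (np.degrees(doubled) / 2.0) % 180.0


def _clip_segment(
    p0: tuple[float, float], p1: tuple[float, float], lo: float, hi: float
) -> tuple[tuple[float, float], tuple[float, float]] | None:
    """Liang-Barsky clip of a segment to the square [lo, hi]^2."""
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - lo),
        (dx, hi - x0),
        (-dy, y0 - lo),
        (dy, hi - y0),
    ):
        if p == 0:
            if q < 0:
                return None
            continue
        t = q / p
        if p < 0:
            if t > t1:
                return None
            t0 = max(t0, t)
        else:
            if t < t0:
                return None
            t1 = min(t1, t)
    return (x0 + t0 * dx, y0 + t0 * dy), (x0 + t1 * dx, y0 + t1 * dy)


def make_fiber_texture(spec: FiberFieldSpec) -> IntensityImage:
    """Render an oriented fiber texture in [0, 1].

    Each fiber is an anti-aliased line segment through a random centre,
    with orientation drawn by :func:`sample_fiber_orientations`.
    Segments are combined by maximum (a fiber crossing another does not
    double the brightness, as SHG intensity saturates rather than adds),
    blurred with a Gaussian of sigma ``fiber_width_px / 2`` to give
    fibers a Gaussian cross-section, rescaled to [0, 1]; Gaussian
    background noise is then added and the result clipped back to
    [0, 1].  Many short segments rather than a few canvas-spanning ones
    keep the spatial spectrum flat enough that an isotropic field
    measures as isotropic at a single-image scale.

    The drawn orientations are recorded in
    ``meta['fiber_orientations_deg']`` so tests can recover the ground
    truth.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.width_px
    canvas = np.zeros((n, n), dtype=float)
    angles = sample_fiber_orientations(spec, rng)
    lengths = rng.uniform(0.1, 0.2, size=spec.n_fibers) * n
    centers = rng.uniform(0, n - 1, size=(spec.n_fibers, 2))  # (x, y)
    for theta, length, (cx, cy) in zip(angles, lengths, centers):
        ux, uy = math.cos(math.radians(theta)), math.sin(math.radians(theta))
        seg = _clip_segment(
            (cx - 0.5 * length * ux, cy - 0.5 * length * uy),
            (cx + 0.5 * length * ux, cy + 0.5 * length * uy),
            0.0,
            n - 1.0,
        )
        if seg is None:
            continue
        (x0, y0), (x1, y1) = seg
        rr, cc, val = line_aa(
            int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
        )
        inside = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        np.maximum.at(canvas, (rr[inside], cc[inside]), val[inside])
    canvas = ndimage.gaussian_filter(canvas, sigma=spec.fiber_width_px / 2.0)
    peak = canvas.max()
    if peak > 0:
        canvas /= peak
    if spec.background_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.background_noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    return IntensityImage(
        canvas,
        pixel_size_um=spec.pixel_size_um,
        meta={
            "fiber_orientations_deg": angles,
            "spec": spec,
        },
    )


def _ellipse_axes(area_px: float, ecc: float) -> tuple[float, float]:
    """Half-axes (a, b) of an ellipse with given area and eccentricity.

    Solves pi*a*b = area with b = a*sqrt(1 - e^2), so the requested
    eccentricity holds exactly for the continuous ellipse.
    """
    ratio = math.sqrt(1.0 - ecc * ecc)  # b / a
    a = math.sqrt(area_px / math.pi) / math.sqrt(ratio)
    return a, a * ratio


def make_cell_masks(
    spec: CellPopulationSpec,
    canvas_px: int,
    fiber_orientation_deg: float | None = None,
) -> LabeledMask:
    """Rasterize an overlap-free population of ellipses, labels 1..n.

    ``fiber_orientation_deg`` supplies the fiber mean direction and is
    required when ``spec.orientation_deg == 'match_fibers'``.  Placement
    is by rejection sampling with at most ``MAX_PLACEMENT_RETRIES``
    attempts per cell (cells are kept fully inside the canvas with a
    one-pixel separating margin); exhaustion raises
    :class:`PlacementError`.
    """
    if canvas_px < 8:
        raise ValidationError("canvas_px too small")
    if spec.orientation_deg == "match_fibers" and fiber_orientation_deg is None:
        raise ValidationError(
            "orientation 'match_fibers' requires fiber_orientation_deg"
        )
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros((canvas_px, canvas_px), dtype=np.int32)
    blocked = np.zeros((canvas_px, canvas_px), dtype=bool)
    for lab in range(1, spec.n_cells + 1):
        area = spec.mean_area_px * rng.uniform(0.85, 1.15)
        a, b = _ellipse_axes(area, spec.eccentricity)
        if isinstance(spec.orientation_deg, str):
            if spec.orientation_deg == "match_fibers":
                theta = float(fiber_orientation_deg) % 180.0
            else:
                theta = rng.uniform(0.0, 180.0)
        else:
            theta = float(spec.orientation_deg)
        if 2 * a + 2 >= canvas_px:
            raise PlacementError(
                f"cell axis {a:.1f} px does not fit a {canvas_px}-px canvas"
            )
        placed = False
        for _ in range(MAX_PLACEMENT_RETRIES):
            # integer centres: fractional centres rasterize slightly
            # asymmetrically, which biases near-zero eccentricities
            cx = round(rng.uniform(a + 1, canvas_px - a - 2))
            cy = round(rng.uniform(a + 1, canvas_px - a - 2))
            rr, cc = draw_ellipse(cy, cx, b, a, rotation=-math.radians(theta))
            if rr.size == 0 or blocked[rr, cc].any():
                continue
            labels[rr, cc] = lab
            cell = np.zeros_like(blocked)
            cell[rr, cc] = True
            blocked |= ndimage.binary_dilation(cell, structure=_FULL_3X3)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {lab} after {MAX_PLACEMENT_RETRIES} tries"
            )
    return LabeledMask(labels)


def make_tracks(
    n_cells: int,
    speed_um_min: float,
    step_min: float = 10.0,
    n_steps: int = 18,
    turn_sd_deg: float = 20.0,
    seed: int = 0,
    field_um: float = 512 * DEFAULT_PIXEL_SIZE_UM,
) -> TrackSet:
    """Persistent-random-walk centroid tracks at fixed sampling interval.

    Each of ``n_cells`` tracks has ``n_steps + 1`` points ``step_min``
    minutes apart; every step displaces the cell by exactly
    ``speed_um_min * step_min`` micrometres while the heading performs a
    Gaussian random walk with per-step SD ``turn_sd_deg``.  Defaults
    mimic 3 h of imaging at 10-min intervals.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be positive")
    if speed_um_min < 0 or turn_sd_deg < 0:
        raise ValidationError("speed and turn SD must be nonnegative")
    if not (step_min > 0) or n_steps < 1:
        raise ValidationError("step_min and n_steps must be positive")
    rng = np.random.default_rng(seed)
    step_len = speed_um_min * step_min
    tracks: dict[int, list[tuple[float, float, float]]] = {}
    for tid in range(1, n_cells + 1):
        x, y = rng.uniform(0, field_um, size=2)
        heading = rng.uniform(0, 2 * math.pi)
        pts = [(0.0, x, y)]
        for k in range(1, n_steps + 1):
            heading += math.radians(rng.normal(0.0, turn_sd_deg)) if turn_sd_deg > 0 else 0.0
            x += step_len * math.cos(heading)
            y += step_len * math.sin(heading)
            pts.append((k * step_min, x, y))
        tracks[tid] = pts
    return TrackSet.from_mapping(tracks)


def make_deforming_masks(
    base: LabeledMask, deformation_level: float, seed: int = 0
) -> tuple[LabeledMask, LabeledMask]:
    """Pair of mask frames with controlled per-cell footprint change.

    The first frame is ``base`` unchanged.  In the second frame each
    region is translated along a canvas axis (toward the canvas interior
    so nothing is clipped) by ``ceil(level * (extent + 1))`` pixels,
    where ``extent`` is the region's size along that axis: level 0
    returns an identical copy, level 1 translates every region past its
    own footprint, making the pair disjoint (downstream CDI exactly 1),
    and intermediate levels give partial overlap.
    """
    if not (0 <= deformation_level <= 1):
        raise ValidationError("deformation_level must be in [0, 1]")
    ids = base.label_ids()
    if ids.size == 0:
        raise EmptyInputError("base mask has no regions")
    if deformation_level == 0:
        return base, LabeledMask(base.labels.copy(), base.pixel_size_um)
    rng = np.random.default_rng(seed)
    h, w = base.shape
    out = np.zeros_like(base.labels)
    for lab in ids:
        ys, xs = np.nonzero(base.labels == lab)
        options = list(rng.permutation(4))  # 0:+x 1:-x 2:+y 3:-y
        done = False
        for axis_dir in options:
            horizontal = axis_dir in (0, 1)
            coord = xs if horizontal else ys
            extent = int(coord.max() - coord.min()) + 1
            d = math.ceil(deformation_level * (extent + 1))
            sign = 1 if axis_dir in (0, 2) else -1
            nxs = xs + sign * d if horizontal else xs
            nys = ys + sign * d if not horizontal else ys
            if nxs.min() < 0 or nxs.max() >= w or nys.min() < 0 or nys.max() >= h:
                continue
            if out[nys, nxs].any():
                continue
            out[nys, nxs] = lab
            done = True
            break
        if not done:
            raise PlacementError(
                f"region {lab} cannot be displaced within the canvas"
            )
    return base, LabeledMask(out, base.pixel_size_um)


def scenario_specs(
    label: ScenarioLabel | str, seed: int
) -> tuple[FiberFieldSpec, CellPopulationSpec]:
    """Fiber and cell specs encoding the early/late-stage contrast.

    ``day10like`` (early woven-bone stage): strongly concentrated fiber
    orientations (kappa 32) with highly eccentric cells (0.9) elongated
    along the fibers.  ``day21like`` (late stage): isotropic fibers
    (kappa 0) with rounded cells (eccentricity 0.25) at random
    orientations.  The mean fiber direction varies with the seed so the
    contrast is tested across orientations.
    """
    if isinstance(label, str):
        label = ScenarioLabel(label)
    rng = np.random.default_rng(seed)
    mean_deg = float(rng.uniform(0.0, 180.0))
    if label.stage == "day10like":
        fibers = FiberFieldSpec(
            mean_orientation_deg=mean_deg, concentration=32.0, seed=seed
        )
        cells = CellPopulationSpec(
            n_cells=10,
            eccentricity=0.9,
            orientation_deg="match_fibers",
            mean_area_px=1257.0,
            seed=seed + 10_000,
        )
    else:
        fibers = FiberFieldSpec(
            mean_orientation_deg=mean_deg, concentration=0.0, seed=seed
        )
        cells = CellPopulationSpec(
            n_cells=10,
            eccentricity=0.25,
            orientation_deg="random",
            mean_area_px=1257.0,
            seed=seed + 10_000,
        )
    return fibers, cells
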