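"""Fiber-cell orientation coupling: the orientation correlated index.

The OCI measures whether collagen fibers and cells are anisotropic in a
coordinated way.  Both angular profiles — the fiber spectral magnitude
f(theta) and the cell radius g(theta) — are mean-centered and
l2-normalized, then circularly cross-correlated; the OCI is the
correlation at a 90-degree shift:

    OCI = sum_theta  f_hat(theta) * g_hat(theta + 90).

The 90-degree shift compensates for the fact that the spectral peak of a
fiber texture is orthogonal to the real-space fiber direction: cells
elongated *along* the fibers therefore score OCI near +1, while
isotropy in either profile (after centering, a near-zero vector) makes
the index undefined.  Normalization bounds the index in [-1, 1]
(Cauchy-Schwarz) and makes it invariant to offset and positive scaling
of either profile.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AngularProfile, N_ANGLE_BINS
from .errors import DegenerateInputError, ValidationError

DEFAULT_TAU_DEG = 90

#: relative variance below which a profile is treated as isotropic to
#: machine precision (zero after centering).
_VAR_EPS = 1e-24


@dataclass(frozen=True)
class OciResult:
    """OCI plus the full normalized circular correlogram."""

    oci: float
    tau_deg: int
    full_correlogram: np.ndarray  # correlation at every shift 0..359

    def __post_init__(self) -> None:
        c = np.asarray(self.full_correlogram, dtype=float)
        if c.shape != (N_ANGLE_BINS,):
            raise ValidationError("correlogram must have 360 entries")
        object.__setattr__(self, "full_correlogram", c)


def _center_normalize(profile: AngularProfile, name: str) -> np.ndarray:
    v = profile.values
    vc = v - v.mean()
    norm = np.linalg.norm(vc)
    if norm * norm <= _VAR_EPS * max(1.0, float(v @ v)):
        raise DegenerateInputError(
            f"{name}(theta) has zero variance (isotropic profile); OCI undefined"
        )
    return vc / norm


def oci(
    f: AngularProfile,
    g: AngularProfile,
    tau_deg: int = DEFAULT_TAU_DEG,
) -> OciResult:
    """Normalized circular cross-correlation of f and g at shift tau.

    Parameters
    ----------
    f
        Fiber spectral magnitude profile (``kind='fiber_magnitude'``).
    g
        Cell radius profile (``kind='cell_radius'``).
    tau_deg
        Angular shift in degrees at which the correlogram is read out;
        90 by default so that cells aligned with the real-space fiber
        direction score highly.
    """
    if f.kind != "fiber_magnitude":
        raise ValidationError("f must be a fiber_magnitude profile")
    if g.kind != "cell_radius":
        raise ValidationError("g must be a cell_radius profile")
    fh = _center_normalize(f, "f")
    gh = _center_normalize(g, "g")
    # corr[tau] = sum_theta fh[theta] * gh[(theta + tau) % 360]
    corr = np.array([fh @ np.roll(gh, -t) for t in range(N_ANGLE_BINS)])
    tau = int(tau_deg) % N_ANGLE_BINS
    return OciResult(oci=float(corr[tau]), tau_deg=tau, full_correlogram=corr)
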