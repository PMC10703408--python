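"""Circular (directional) statistics and periodic-kernel utilities.

All public interfaces use degrees. Directions live in ``[0, 360)``, signed
angular differences in ``(-180, +180]``. Angles are converted to radians only
inside trigonometric evaluations, so kernel length-scales are dimensionless
quantities acting on radian arguments (e.g. a length-scale of 0.46 confines
generalization to a few tens of degrees).

The periodic kernel is the standard one from the Gaussian-process literature,

    G(theta, theta') = exp(-2 sin^2((theta - theta') / 2) / l^2),

which is symmetric, 360-periodic, equals 1 iff theta = theta' (mod 360), and
approaches 1 everywhere as l -> inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Concentration cap for degenerate (near point-mass) von Mises fits.
KAPPA_MAX = 1000.0

#: Below this mean resultant length the circular mean is treated as undefined.
RESULTANT_EPS = 1e-12


class UndefinedMeanError(ValueError):
    """Raised when the mean resultant vector has (numerically) zero length."""


def _as_finite(x, name: str = "angle") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def wrap_signed(x):
    """Wrap angle(s) in degrees to the signed interval ``(-180, +180]``.

    Idempotent; the output is congruent to the input modulo 360. The boundary
    convention maps -180 to +180 so that ``|wrap_signed(x)| <= 180`` with the
    maximum attained only at +180.
    """
    arr = _as_finite(x)
    wrapped = arr - 360.0 * np.floor(arr / 360.0)  # [0, 360)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    return float(wrapped) if np.ndim(x) == 0 else wrapped


def wrap_direction(x):
    """Wrap angle(s) in degrees to the direction interval ``[0, 360)``."""
    arr = _as_finite(x)
    wrapped = arr - 360.0 * np.floor(arr / 360.0)
    # floating wrap can land exactly on 360.0 for inputs like -1e-14
    wrapped = np.where(wrapped >= 360.0, wrapped - 360.0, wrapped)
    return float(wrapped) if np.ndim(x) == 0 else wrapped


def angular_distance(a, b):
    """Signed angular distance ``a - b`` in degrees, in ``(-180, +180]``."""
    return wrap_signed(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def abs_angular_distance(a, b):
    """Absolute angular distance between two directions, in ``[0, 180]``."""
    return np.abs(angular_distance(a, b))


@dataclass(frozen=True)
class KernelSpec:
    """Length-scale of the periodic generalization kernel (dimensionless)."""

    length_scale: float

    def __post_init__(self):
        if not np.isfinite(self.length_scale) or self.length_scale <= 0:
            raise ValueError(
                f"length_scale must be a positive finite number, got {self.length_scale!r}"
            )


def periodic_kernel(a, b, spec: KernelSpec | float):
    """Periodic kernel weight between directions ``a`` and ``b`` (degrees).

    ``spec`` may be a :class:`KernelSpec` or a bare positive length-scale.
    Returns value(s) in ``(0, 1]``.
    """
    if not isinstance(spec, KernelSpec):
        spec = KernelSpec(float(spec))
    delta = np.radians(_as_finite(a) - _as_finite(b))
    out = np.exp(-2.0 * np.sin(delta / 2.0) ** 2 / spec.length_scale**2)
    return float(out) if np.ndim(out) == 0 else out


def mean_resultant_length(angles) -> float:
    """Length R in [0, 1] of the mean resultant vector of directions (degrees)."""
    arr = _as_finite(angles, "angles")
    if arr.size == 0:
        raise ValueError("angles must be non-empty")
    rad = np.radians(arr)
    return float(np.hypot(np.mean(np.cos(rad)), np.mean(np.sin(rad))))


def circular_mean(angles) -> float:
    """Direction of the mean resultant vector, in ``[0, 360)``.

    Raises :class:`UndefinedMeanError` when the resultant length is
    numerically zero (e.g. two diametrically opposed angles).
    """
    arr = _as_finite(angles, "angles")
    if arr.size == 0:
        raise ValueError("angles must be non-empty")
    rad = np.radians(arr)
    c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    if np.hypot(c, s) < RESULTANT_EPS:
        raise UndefinedMeanError("mean resultant length is zero; circular mean undefined")
    return float(wrap_direction(np.degrees(np.arctan2(s, c))))


def circular_sd(angles) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)`` in degrees.

    Returns ``inf`` (rather than raising) when the mean resultant length is
    zero, flagging a maximally dispersed sample.
    """
    r = mean_resultant_length(angles)
    if r < RESULTANT_EPS:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(min(r, 1.0)))))


@dataclass(frozen=True)
class VonMisesFit:
    """Maximum-likelihood von Mises parameters (``mu`` degrees, ``kappa`` >= 0).

    ``mu`` is NaN when the sample resultant is zero (mean undefined, kappa 0).
    """

    mu: float
    kappa: float


def _a1inv(r: float) -> float:
    # Best & Fisher approximation to the inverse of A1(kappa) = I1(kappa)/I0(kappa)
    if r < 0.53:
        kappa = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        denom = r**3 - 4.0 * r**2 + 3.0 * r
        kappa = KAPPA_MAX if denom <= 0 else 1.0 / denom
    return float(min(max(kappa, 0.0), KAPPA_MAX))


def fit_von_mises(angles) -> VonMisesFit:
    """Fit a von Mises distribution by maximum likelihood.

    mu is the circular mean; kappa solves A1(kappa) = R via the standard
    Best-Fisher approximation, capped at :data:`KAPPA_MAX` for degenerate
    (near point-mass) samples.
    """
    arr = _as_finite(angles, "angles")
    if arr.size < 2:
        raise ValueError("need at least 2 angles to fit a von Mises distribution")
    r = mean_resultant_length(arr)
    if r < RESULTANT_EPS:
        return VonMisesFit(mu=float("nan"), kappa=0.0)
    return VonMisesFit(mu=circular_mean(arr), kappa=_a1inv(r))


def periodic_smooth(directions, values, bandwidth, eval_grid) -> np.ndarray:
    """Nadaraya-Watson smoother on the circle using the periodic kernel.

    ``bandwidth`` is the kernel length-scale. Weights normalize per evaluation
    point, so a single data point yields a constant function.
    """
    d = _as_finite(directions, "directions")
    v = np.asarray(values, dtype=float)
    g = _as_finite(eval_grid, "eval_grid")
    if d.size == 0:
        raise ValueError("directions must be non-empty")
    if d.shape != v.shape:
        raise ValueError("directions and values must have equal length")
    w = periodic_kernel(g[:, None], d[None, :], bandwidth)
    return w @ v / np.sum(w, axis=1)
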