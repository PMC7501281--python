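"""Parametric hemodynamic response function (HRF) model and response features.

The HRF is modeled as a difference of two gamma densities — a positive
response lobe and a delayed undershoot — scaled by an amplitude ``A`` and an
undershoot ratio ``c``:

    h(t) = A * [ g(t; alpha1, beta1) - c * g(t; alpha2, beta2) ],   t >= 0

with ``g(t; a, b) = t**(a-1) * b**a * exp(-b*t) / Gamma(a)`` the gamma
probability density (shape ``a``, rate ``b``).  The measured hemodynamic
response (HDR) to a stimulus of finite duration is the convolution of this
kernel with a boxcar spanning the stimulus.

Two canonical parameter sets are built in: the standard human one
(6, 16, 1, 1, 1/6) and the pigeon one estimated from awake-bird visual
responses (7.71, 11.48, 1.74, 0.74, 0.25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

__all__ = [
    "HRFParams",
    "HDRFeatures",
    "SampledCurve",
    "double_gamma_kernel",
    "hrf_response",
    "hdr_features",
    "canonical_params",
    "CANONICAL",
]


@dataclass(frozen=True)
class HRFParams:
    """Shape parameters of the double-gamma HRF.

    alpha1, beta1 : shape (dimensionless) and rate (1/s) of the response lobe
    alpha2, beta2 : shape and rate of the undershoot lobe
    c             : undershoot-to-response amplitude ratio, in [0, 1]
    A             : overall amplitude (percent-signal-change units)
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    c: float
    A: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha1 > 1 and self.alpha2 > 1):
            raise ValueError("gamma shapes alpha1, alpha2 must be > 1")
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ValueError("gamma rates beta1, beta2 must be > 0")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError("undershoot ratio c must be in [0, 1]")
        if not math.isfinite(self.A):
            raise ValueError("amplitude A must be finite")

    def with_amplitude(self, A: float) -> "HRFParams":
        return replace(self, A=A)

    def as_dict(self) -> dict:
        return {
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "c": self.c,
            "A": self.A,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HRFParams":
        return cls(
            alpha1=float(d["alpha1"]),
            alpha2=float(d["alpha2"]),
            beta1=float(d["beta1"]),
            beta2=float(d["beta2"]),
            c=float(d["c"]),
            A=float(d.get("A", 1.0)),
        )


@dataclass(frozen=True)
class HDRFeatures:
    """Summary features of a hemodynamic response curve.

    H : peak amplitude (% signal change)
    T : time-to-peak from stimulus onset (s)
    W : full width at half maximum of the main positive lobe (s)
    """

    H: float
    T: float
    W: float


@dataclass(frozen=True)
class SampledCurve:
    """A regularly sampled time course.

    values : signal samples
    dt     : sampling interval (s)
    t0     : time of the first sample relative to stimulus onset (s)
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    sem: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("curve must be a 1-D sequence of length >= 2")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)


# Printed canonical parameter sets (amplitude fixed at 1).
CANONICAL: dict[str, HRFParams] = {
    "human": HRFParams(6.0, 16.0, 1.0, 1.0, 1.0 / 6.0),
    "pigeon": HRFParams(7.71, 11.48, 1.74, 0.74, 0.25),
}


def canonical_params(species: str) -> HRFParams:
    """Return the canonical double-gamma parameters for a species label."""
    try:
        return CANONICAL[species.lower()]
    except KeyError:
        valid = ", ".join(sorted(CANONICAL))
        raise ValueError(f"unknown species {species!r}; valid labels: {valid}") from None


def _gamma_pdf(t: np.ndarray, a: float, b: float) -> np.ndarray:
    # log-space evaluation; a > 1 so the density is 0 at t = 0
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((a - 1.0) * np.log(tp) + a * math.log(b) - b * tp - gammaln(a))
    return out


def double_gamma_kernel(
    t: float | np.ndarray, p: HRFParams, *, strict_normalization: bool = False
) -> np.ndarray:
    """Evaluate the double-gamma kernel at times ``t`` (seconds).

    Returns ``A * (g(t; alpha1, beta1) - c * g(t; alpha2, beta2))`` for
    ``t >= 0`` and 0 for ``t < 0``.

    With ``strict_normalization=True`` the undershoot term is divided by
    Gamma(alpha1) instead of Gamma(alpha2); the default normalizes each lobe
    as a unit-mass gamma density, which is the only normalization under which
    ``c`` is a true undershoot-to-response mass ratio.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    resp = _gamma_pdf(t, p.alpha1, p.beta1)
    under = _gamma_pdf(t, p.alpha2, p.beta2)
    if strict_normalization:
        under = under * np.exp(gammaln(p.alpha2) - gammaln(p.alpha1))
    return p.A * (resp - p.c * under)


def hrf_response(
    p: HRFParams,
    stim_duration: float = 2.0,
    dt: float = 0.01,
    t_max: float = 30.0,
    *,
    strict_normalization: bool = False,
) -> SampledCurve:
    """Model HDR: a unit boxcar of ``stim_duration`` convolved with the kernel.

    The discrete convolution is scaled by ``dt`` so the result approximates
    the continuous-time convolution integral; the curve starts at 0 at t = 0.
    """
    if stim_duration <= 0:
        raise ValueError("stim_duration must be positive")
    if t_max < stim_duration:
        raise ValueError("t_max must be at least stim_duration")
    n = int(round(t_max / dt)) + 1
    t = dt * np.arange(n)
    kernel = double_gamma_kernel(t, p, strict_normalization=strict_normalization)
    n_box = max(int(round(stim_duration / dt)), 1)
    boxcar = np.ones(n_box)
    full = np.convolve(boxcar, kernel)[:n] * dt
    return SampledCurve(values=full, dt=dt, t0=0.0)


def hdr_features(curve: SampledCurve) -> HDRFeatures:
    """Extract peak height H, time-to-peak T, and FWHM W from a curve.

    W is the width of the main positive lobe at half of H; the half-maximum
    crossings are located by linear interpolation between samples.  The
    undershoot is excluded: crossings are searched outward from the peak.
    """
    v = curve.values
    if not np.any(v > 0):
        raise ValueError("no positive response: curve has no positive samples")
    i_peak = int(np.argmax(v))
    H = float(v[i_peak])
    T = float(curve.t0 + i_peak * curve.dt)
    half = H / 2.0

    def _cross(i0: int, i1: int) -> float:
        # linear interpolation of the half-maximum crossing between samples
        y0, y1 = v[i0], v[i1]
        frac = (half - y0) / (y1 - y0)
        return curve.t0 + (i0 + frac * (i1 - i0)) * curve.dt

    # walk left from the peak to the last sample below half-maximum
    left = i_peak
    while left > 0 and v[left - 1] >= half:
        left -= 1
    t_left = _cross(left - 1, left) if left > 0 else float(curve.t0)

    # walk right from the peak
    right = i_peak
    n = v.size
    while right < n - 1 and v[right + 1] >= half:
        right += 1
    if right < n - 1:
        t_right = _cross(right + 1, right)
    else:
        t_right = float(curve.t0 + (n - 1) * curve.dt)

    return HDRFeatures(H=H, T=T, W=float(t_right - t_left))
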