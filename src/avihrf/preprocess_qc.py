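"""Time-series conditioning and quality-control statistics for 4D BOLD data.

Implements the deterministic preprocessing stages of the pipeline — spatial
smoothing, grand-mean scaling, high-pass filtering, polynomial detrending,
percent signal change — plus the two QC statistics used for run screening:
the voxelwise temporal signal-to-noise ratio (tSNR) and the median absolute
deviation (MAD) of motion traces.

High-pass filtering is implemented as regression against a discrete-cosine
(DCT-II) basis restricted to periods longer than the cutoff, with the
temporal mean restored afterwards.  This is a linear filter with a sharp,
easily testable frequency response and is the standard drift model in
SPM-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .hrf_core import SampledCurve

__all__ = [
    "BOLDSeries",
    "MotionTrace",
    "gaussian_smooth",
    "grand_mean_scale",
    "highpass_filter",
    "project_out_polynomials",
    "percent_signal_change",
    "tsnr_map",
    "mad",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BOLDSeries:
    """A 4D BOLD time series.

    data       : array (x, y, z, time)
    TR         : repetition time, s
    voxel_size : (dx, dy, dz) in mm
    mask       : optional boolean brain mask, same spatial shape as data
    """

    data: np.ndarray
    TR: float
    voxel_size: tuple[float, float, float] = (0.47, 0.47, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 4 or data.shape[3] < 2:
            raise ValueError("BOLD data must be 4D with >= 2 time points")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != data.shape[:3]:
                raise ValueError("mask shape must match spatial dimensions")
            object.__setattr__(self, "mask", mask)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def in_mask(self) -> np.ndarray:
        """Time-by-voxel view of in-mask data (all voxels if no mask)."""
        if self.mask is None:
            return self.data.reshape(-1, self.n_volumes)
        return self.data[self.mask]


@dataclass(frozen=True)
class MotionTrace:
    """Six rigid-body motion parameters per volume.

    rotations    : (n_volumes, 3), radians unless ``rotation_unit='deg'``
    translations : (n_volumes, 3), mm
    """

    rotations: np.ndarray
    translations: np.ndarray
    rotation_unit: str = "rad"

    def __post_init__(self) -> None:
        rot = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        tra = np.atleast_2d(np.asarray(self.translations, dtype=float))
        if rot.shape != tra.shape or rot.shape[1] != 3:
            raise ValueError("rotations and translations must both be (n, 3)")
        if self.rotation_unit not in ("rad", "deg"):
            raise ValueError("rotation_unit must be 'rad' or 'deg'")
        object.__setattr__(self, "rotations", rot)
        object.__setattr__(self, "translations", tra)

    @property
    def n_volumes(self) -> int:
        return self.rotations.shape[0]

    def as_matrix(self) -> np.ndarray:
        """(n_volumes, 6) array: rotations first, then translations."""
        return np.hstack([self.rotations, self.translations])


def gaussian_smooth(series: BOLDSeries, fwhm: float) -> BOLDSeries:
    """Per-volume 3D Gaussian smoothing with a given FWHM in mm.

    The kernel sigma per axis is fwhm * FWHM_TO_SIGMA converted to voxel
    units via the voxel size.  Boundaries are reflective, preserving the
    spatial sum of each volume.  fwhm = 0 is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return series
    sigma_vox = [fwhm * FWHM_TO_SIGMA / vs for vs in series.voxel_size]
    out = np.empty_like(series.data)
    for t in range(series.n_volumes):
        out[..., t] = gaussian_filter(
            series.data[..., t], sigma=sigma_vox, mode="reflect", truncate=4.0
        )
    return replace(series, data=out)


def grand_mean_scale(series: BOLDSeries, target: float = 10000.0) -> BOLDSeries:
    """Scale the whole run by one factor so its 4D in-mask mean equals target."""
    mean = float(series.in_mask().mean())
    if mean <= 0:
        raise ValueError("in-mask mean must be positive for grand-mean scaling")
    return replace(series, data=series.data * (target / mean))


def _dct_drift_basis(n: int, TR: float, cutoff: float) -> np.ndarray:
    """DCT-II basis columns with period > cutoff (excluding the constant).

    Column k (k = 1..K) is cos(pi * k * (t + 0.5) / n); its period is
    2 * n * TR / k, so K = floor(2 * n * TR / cutoff).
    """
    k_max = int(np.floor(2.0 * n * TR / cutoff))
    t = (np.arange(n) + 0.5) / n
    cols = [np.cos(np.pi * k * t) for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def highpass_filter(series: BOLDSeries, cutoff: float) -> BOLDSeries:
    """Remove fluctuations slower than ``cutoff`` seconds from each voxel.

    Regresses out a low-frequency DCT basis per voxel and restores the
    temporal mean, so constant series pass through unchanged.
    """
    if cutoff <= 2 * series.TR:
        raise ValueError("cutoff must exceed twice the TR")
    n = series.n_volumes
    basis = _dct_drift_basis(n, series.TR, cutoff)
    flat = series.data.reshape(-1, n)
    means = flat.mean(axis=1, keepdims=True)
    centered = flat - means
    if basis.shape[1]:
        coef = centered @ basis  # basis is orthonormal
        centered = centered - coef @ basis.T
    out = (centered + means).reshape(series.data.shape)
    return replace(series, data=out)


def _polynomial_basis(n: int, order: int) -> np.ndarray:
    """Orthonormal Legendre-like polynomial basis on n samples, degrees 0..order."""
    x = np.linspace(-1.0, 1.0, n)
    cols = np.polynomial.legendre.legvander(x, order)
    q, _ = np.linalg.qr(cols)
    return q


def project_out_polynomials(timecourse: SampledCurve, order: int = 2) -> SampledCurve:
    """Least-squares removal of polynomial trends up to ``order``."""
    if order < 0:
        raise ValueError("order must be non-negative")
    n = timecourse.values.size
    if n <= order + 1:
        raise ValueError("time course too short for the requested order")
    basis = _polynomial_basis(n, order)
    v = timecourse.values
    resid = v - basis @ (basis.T @ v)
    return replace(timecourse, values=resid)


def percent_signal_change(
    timecourse: SampledCurve,
    stimulus_onsets: np.ndarray,
    baseline_window: float = 2.0,
    epoch: float = 28.0,
) -> list[SampledCurve]:
    """Per-trial percent signal change relative to a pre-stimulus baseline.

    For each onset, the baseline b is the mean over [onset - baseline_window,
    onset); the trial curve is 100 * (x - b) / b over [onset, onset + epoch],
    time-locked to the onset.  Trials whose epoch runs past the end of the
    series are dropped.
    """
    dt = timecourse.dt
    t = timecourse.times
    v = timecourse.values
    out: list[SampledCurve] = []
    n_epoch = int(np.floor(epoch / dt)) + 1
    for k, onset in enumerate(np.asarray(stimulus_onsets, dtype=float)):
        base_sel = (t >= onset - baseline_window) & (t < onset)
        if not base_sel.any():
            raise ValueError(f"trial {k}: no samples in baseline window")
        b = v[base_sel].mean()
        if b == 0:
            raise ValueError(f"trial {k}: zero baseline mean")
        i0 = int(np.searchsorted(t, onset - 1e-9))
        if i0 + n_epoch > v.size:
            continue  # trial epoch exceeds the run; dropped
        seg = 100.0 * (v[i0 : i0 + n_epoch] - b) / b
        out.append(SampledCurve(values=seg, dt=dt, t0=float(t[i0] - onset)))
    return out


def tsnr_map(series: BOLDSeries) -> np.ndarray:
    """Voxelwise temporal mean / temporal sd.

    The caller is responsible for applying the conventional preprocessing
    (high-pass at 100 s, spatial smoothing) first.  Voxels with zero temporal
    variance get +inf as a sentinel so map geometry is preserved.
    """
    mean = series.data.mean(axis=3)
    sd = series.data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    return tsnr


def mad(values) -> float:
    """Median absolute deviation about the median (no consistency scaling)."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("mad of an empty sequence is undefined")
    return float(np.median(np.abs(x - np.median(x))))
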