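"""Optical-trap mechanics for membrane-tension experiments.

A polystyrene bead held in an optical trap behaves as a particle in a
harmonic potential ``V(x) = k x^2 / 2``.  At thermal equilibrium the
equipartition theorem assigns ``k_B T / 2`` of energy to the x degree of
freedom, so the trap stiffness follows from the position variance alone:

    k = k_B * T / <x^2>

with ``<x^2>`` the variance of the bead position about the trap centre.
This module implements that passive calibration (variance read either from
a Gaussian fit to the position histogram or directly from the sample
variance), the linear force readout ``F = k * dx``, assembly of tether
force-extension curves from bead and stage tracks, and detection of the
first linear region of such a curve.

Units throughout: positions in μm, time in s, forces in pN, stiffness in
pN/μm, temperature in K.  The Boltzmann constant in these units is
``1.380649e-5 pN·μm/K``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import (
    DegenerateTrackError,
    InvalidParameterError,
    NoLinearRegionError,
)

#: Boltzmann constant in pN·μm/K (1.380649e-23 J/K converted).
BOLTZMANN_PN_UM = 1.380649e-5

#: Default room temperature, K (23 °C; experiments run at RT).
ROOM_TEMPERATURE_K = 296.15

VarianceMethod = Literal["gaussian_fit", "direct_variance"]


# ---------------------------------------------------------------------------
# Track containers
# ---------------------------------------------------------------------------

@dataclass
class BeadTrack:
    """Time-stamped positions of a trapped bead.

    ``x`` (and optionally ``y``) are deviations from the trap centre in μm.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray | None = None
    frame_rate: float | None = None
    exposure: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if self.times.size < 2:
            raise InvalidParameterError("a bead track needs >= 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("track times must be strictly increasing")
        if self.x.shape != self.times.shape:
            raise InvalidParameterError("times and x must have equal length")
        if self.y is not None and self.y.shape != self.times.shape:
            raise InvalidParameterError("times and y must have equal length")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def to_csv(self, path) -> None:
        cols = {"t_s": self.times, "x_um": self.x}
        if self.y is not None:
            cols["y_um"] = self.y
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BeadTrack":
        df = pd.read_csv(path)
        y = df["y_um"].to_numpy() if "y_um" in df.columns else None
        return cls(times=df["t_s"].to_numpy(), x=df["x_um"].to_numpy(), y=y)


@dataclass
class StageTrack:
    """Time-stamped piezo-stage position in μm."""

    times: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.times.size < 2:
            raise InvalidParameterError("a stage track needs >= 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("stage times must be strictly increasing")
        if self.position.shape != self.times.shape:
            raise InvalidParameterError("times and position must have equal length")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.times, "stage_um": self.position}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "StageTrack":
        df = pd.read_csv(path)
        return cls(times=df["t_s"].to_numpy(), position=df["stage_um"].to_numpy())


@dataclass
class TrapCalibration:
    """Equipartition calibration result: stiffness per axis in pN/μm."""

    k_x: float
    temperature: float
    n_frames: int
    method: str
    variance_x: float
    k_y: float | None = None
    variance_y: float | None = None

    def as_dict(self) -> dict:
        d = {
            "k_x_pn_per_um": self.k_x,
            "temperature_k": self.temperature,
            "n_frames": self.n_frames,
            "method": self.method,
            "variance_x_um2": self.variance_x,
        }
        if self.k_y is not None:
            d["k_y_pn_per_um"] = self.k_y
            d["variance_y_um2"] = self.variance_y
        return d


@dataclass
class ForceExtensionCurve:
    """Tether force vs extension, starting at the pull onset.

    ``extension`` is stage displacement from the pull onset by default
    (``axis='stage'``); with ``axis='tether'`` it is stage displacement
    minus bead deviation, i.e. the tether length change.
    """

    times: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    axis: str
    stiffness: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.times, "extension_um": self.extension, "force_pn": self.force}
        )


@dataclass
class LinearRegionFit:
    """Least-squares fit over the detected first linear region."""

    slope: float
    intercept: float
    start: int
    stop: int  # exclusive
    r_squared: float

    def as_dict(self) -> dict:
        return {
            "slope_pn_per_um": self.slope,
            "intercept_pn": self.intercept,
            "start_index": self.start,
            "stop_index": self.stop,
            "r_squared": self.r_squared,
        }


# ---------------------------------------------------------------------------
# Equipartition calibration
# ---------------------------------------------------------------------------

def thermal_energy(temperature: float) -> float:
    """k_B·T in pN·μm for an absolute temperature in K."""
    if temperature < 0:
        raise InvalidParameterError(f"negative absolute temperature: {temperature}")
    return BOLTZMANN_PN_UM * temperature


def _gaussian(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _gaussian_fit_variance(x: np.ndarray) -> float:
    """Variance from a Gaussian fit to the position histogram.

    Bins follow the Freedman–Diaconis rule; the fit is nonlinear least
    squares on bin centres.  Falls back to the unbiased sample variance
    (with a warning) if the fit does not converge.
    """
    counts, edges = np.histogram(x, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(x.mean()), float(x.std()))
    try:
        with warnings.catch_warnings():
            # only the best-fit width is used; the covariance estimate is not
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gaussian, centers, counts.astype(float), p0=p0, maxfev=20000
            )
        sigma = abs(float(popt[2]))
        if not np.isfinite(sigma) or sigma == 0.0:
            raise RuntimeError("degenerate Gaussian width")
        return sigma**2
    except (RuntimeError, ValueError):
        warnings.warn(
            "Gaussian histogram fit did not converge; falling back to the "
            "direct sample variance",
            RuntimeWarning,
            stacklevel=3,
        )
        return float(np.var(x, ddof=1))


def _axis_variance(x: np.ndarray, method: VarianceMethod) -> float:
    x = x - x.mean()  # equipartition uses the variance about the mean
    if np.ptp(x) == 0.0:
        raise DegenerateTrackError("constant positions: zero variance track")
    if method == "gaussian_fit":
        var = _gaussian_fit_variance(x)
    elif method == "direct_variance":
        var = float(np.var(x, ddof=1))
    else:
        raise InvalidParameterError(f"unknown variance method: {method!r}")
    if not np.isfinite(var) or var <= 1e-18:
        raise DegenerateTrackError(f"degenerate position variance: {var}")
    return var


def stiffness_equipartition(
    track: BeadTrack,
    temperature: float = ROOM_TEMPERATURE_K,
    method: VarianceMethod = "gaussian_fit",
) -> TrapCalibration:
    """Calibrate trap stiffness from an equilibrium bead track.

    Positions are mean-centred internally; the variance is estimated per
    axis (Gaussian fit to the histogram by default) and converted to a
    stiffness via ``k = k_B T / var``.

    Parameters
    ----------
    track
        Equilibrium bead positions; at least 100 samples.
    temperature
        Absolute temperature in K (default 296.15 K, i.e. 23 °C).
    method
        ``"gaussian_fit"`` (default) or ``"direct_variance"``.
    """
    if track.n_frames < 100:
        raise InvalidParameterError(
            f"calibration needs >= 100 samples, got {track.n_frames}"
        )
    if temperature <= 0:
        raise InvalidParameterError("calibration requires a positive temperature")
    kbt = thermal_energy(temperature)
    var_x = _axis_variance(track.x, method)
    k_x = kbt / var_x
    k_y = var_y = None
    if track.y is not None:
        var_y = _axis_variance(track.y, method)
        k_y = kbt / var_y
    return TrapCalibration(
        k_x=k_x,
        k_y=k_y,
        temperature=temperature,
        n_frames=track.n_frames,
        method=method,
        variance_x=var_x,
        variance_y=var_y,
    )


# ---------------------------------------------------------------------------
# Force and force-extension analysis
# ---------------------------------------------------------------------------

def force_from_displacement(k: float, dx):
    """Trap force F = k·dx in pN; the sign of ``dx`` is preserved."""
    if k <= 0:
        raise InvalidParameterError("trap stiffness must be positive")
    return k * np.asarray(dx, dtype=float) if np.ndim(dx) else k * float(dx)


def force_extension_curve(
    bead: BeadTrack,
    stage: StageTrack,
    calib: TrapCalibration,
    baseline_window: float = 0.5,
    onset_tol: float = 1e-9,
    axis: Literal["stage", "tether"] = "stage",
) -> ForceExtensionCurve:
    """Assemble a tether force-extension curve from bead and stage tracks.

    Stage positions are linearly interpolated onto the bead timestamps.
    The pull onset is the first sample at which the stage has moved by more
    than ``onset_tol`` from its initial position.  Bead deviation is zeroed
    against its mean over the ``baseline_window`` seconds preceding the
    onset (falling back to the first sample if no pre-onset samples exist),
    and force follows F = k·Δx.  Extension is stage displacement from the
    onset; with ``axis='tether'`` the bead deviation is subtracted so the
    axis is the tether length change.
    """
    t0 = max(bead.times[0], stage.times[0])
    t1 = min(bead.times[-1], stage.times[-1])
    if t1 <= t0:
        raise InvalidParameterError("bead and stage tracks do not overlap in time")
    sel = (bead.times >= t0) & (bead.times <= t1)
    times = bead.times[sel]
    x = bead.x[sel]
    stage_pos = np.interp(times, stage.times, stage.position)

    # onset = last still sample before the stage starts moving; a ramp that
    # starts immediately has its onset at the very first sample
    moving = np.abs(np.diff(stage_pos)) > onset_tol
    onset_idx = int(np.argmax(moving)) if moving.any() else 0
    onset_time = times[onset_idx]

    pre = (times >= onset_time - baseline_window) & (times < onset_time)
    # without pre-pull samples the track is trusted as deviation from the
    # trap centre already (x is defined that way), so the baseline is zero
    baseline = float(x[pre].mean()) if pre.any() else 0.0

    deviation = x[onset_idx:] - baseline
    force = calib.k_x * deviation
    extension = stage_pos[onset_idx:] - stage_pos[onset_idx]
    if axis == "tether":
        extension = extension - deviation
    elif axis != "stage":
        raise InvalidParameterError(f"unknown extension axis: {axis!r}")
    return ForceExtensionCurve(
        times=times[onset_idx:],
        extension=extension,
        force=force,
        axis=axis,
        stiffness=calib.k_x,
    )


def linear_region_fit(
    curve: ForceExtensionCurve,
    r2_min: float = 0.98,
    min_points: int = 10,
    n_sigma: float = 5.0,
) -> LinearRegionFit:
    """Fit the first linear part of a force-extension curve.

    The window grows from the pull onset one sample at a time and stops at
    the first structural break: a point whose deviation from the running
    prefix fit exceeds ``n_sigma`` times the prefix RMS residual (with a
    tiny absolute floor, so an exactly linear prefix rejects the first
    off-trend sample immediately).  Among the scanned prefixes, the longest
    one with coefficient of determination >= ``r2_min`` and at least
    ``min_points`` samples wins; short noisy prefixes below ``r2_min`` do
    not abort the scan.  The least-squares slope and intercept over the
    winning window are returned with its bounds.
    """
    x = np.asarray(curve.extension, dtype=float)
    y = np.asarray(curve.force, dtype=float)
    n = x.size
    if min_points < 3:
        raise InvalidParameterError("min_points must be >= 3")
    if n < min_points:
        raise NoLinearRegionError(
            f"curve has {n} samples; at least {min_points} required"
        )

    # running sums give O(1) prefix OLS statistics
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])

    resid_floor = 1e-9 * max(np.ptp(y), 1e-30)

    def prefix_fit(m: int) -> tuple[float, float, float, float]:
        sx, sy = cx[m], cy[m]
        sxx, sxy, syy = cxx[m], cxy[m], cyy[m]
        ssx = sxx - sx * sx / m
        ssy = syy - sy * sy / m
        sxy_c = sxy - sx * sy / m
        if ssx <= 0:
            return 0.0, sy / m, 1.0 if ssy <= 0 else 0.0, max(ssy, 0.0)
        slope = sxy_c / ssx
        intercept = (sy - slope * sx) / m
        sse = max(ssy - slope * sxy_c, 0.0)
        r2 = 1.0 if ssy <= 0 else 1.0 - sse / ssy
        return slope, intercept, r2, sse

    accepted: tuple[float, float, float, int] | None = None
    prev_fit: tuple[float, float, float] | None = None
    for m in range(min_points, n + 1):
        if prev_fit is not None:
            slope_p, intercept_p, sse_p = prev_fit
            sigma = np.sqrt(sse_p / max(m - 1 - 2, 1))
            resid = abs(y[m - 1] - (slope_p * x[m - 1] + intercept_p))
            if resid > n_sigma * sigma + resid_floor:
                break  # structural break: the linear prefix has ended
        slope, intercept, r2, sse = prefix_fit(m)
        # short noisy prefixes can dip below r2_min before the linear trend
        # dominates, so a low R^2 does not stop the scan; the longest prefix
        # meeting the criterion wins
        if r2 >= r2_min:
            accepted = (slope, intercept, r2, m)
        prev_fit = (slope, intercept, sse)

    if accepted is None:
        raise NoLinearRegionError(
            f"no prefix of >= {min_points} samples reaches R^2 >= {r2_min}"
        )
    slope, intercept, r2, stop = accepted
    return LinearRegionFit(
        slope=float(slope), intercept=float(intercept), start=0, stop=stop,
        r_squared=float(r2),
    )
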