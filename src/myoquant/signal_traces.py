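"""Scalar statistics on time series and intensity populations.

Covers the trace-level readouts used around myoblast experiments: the
Fura2 agonist-response magnitude (Δratio = trace maximum minus the ratio at
1 min from imaging start), pre-stimulus basal level, relative peak currents
from paired patch-clamp traces, per-timepoint median fluorescence
intensities of flow-cytometry populations, positive-fraction gating, and
the 2^-ΔΔCt fold-change estimator for relative qPCR expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError


@dataclass
class Trace:
    """A scalar time series: Fura2 ratio (F340/F380), current (pA), or
    median intensity (a.u.)."""

    times: np.ndarray
    values: np.ndarray
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size == 0:
            raise InvalidParameterError("empty trace")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("trace times must be strictly increasing")
        if self.values.shape != self.times.shape:
            raise InvalidParameterError("times and values must have equal length")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        return cls(times=df["t_s"].to_numpy(), values=df["value"].to_numpy())


@dataclass
class CtQuad:
    """Ct values for one 2^-ΔΔCt comparison: target and reference gene in
    the sample and in the calibrator condition (PCR cycles)."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for name, ct in vars(self).items():
            if not np.isfinite(ct) or ct <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {ct}")


def delta_ratio(trace: Trace, t_ref: float = 60.0) -> float:
    """Agonist-response magnitude: trace maximum minus the value at t_ref.

    ``t_ref`` defaults to 60 s (1 min from imaging initiation) and is
    resolved to the nearest sample; with 10-s sampling it falls on-grid.
    The result is non-negative because the maximum is taken over the whole
    trace, which includes the reference sample.
    """
    if t_ref < trace.times[0] or t_ref > trace.times[-1]:
        raise InvalidParameterError(
            f"trace [{trace.times[0]}, {trace.times[-1]}] s does not span "
            f"t_ref = {t_ref} s"
        )
    ref = trace.values[int(np.argmin(np.abs(trace.times - t_ref)))]
    return float(trace.values.max() - ref)


def basal_level(trace: Trace, window: tuple[float, float] = (0.0, 60.0)) -> float:
    """Mean value over a pre-stimulus window (default: first 60 s)."""
    lo, hi = window
    if hi <= lo:
        raise InvalidParameterError("window end must exceed window start")
    sel = (trace.times >= lo) & (trace.times <= hi)
    if not sel.any():
        raise InvalidParameterError("no samples inside the basal window")
    return float(trace.values[sel].mean())


def relative_peak_current(
    treated: Trace,
    control: Trace,
    direction: Literal["inward", "outward"] = "inward",
) -> float:
    """|peak(treated)| / |peak(control)|.

    Peaks are the extreme value in the stated direction: the most negative
    sample for inward currents (the patch-clamp convention for cation influx),
    the most positive for outward.  Scale-invariant by construction.
    """
    if direction == "inward":
        peak = lambda t: float(t.values.min())
    elif direction == "outward":
        peak = lambda t: float(t.values.max())
    else:
        raise InvalidParameterError(f"unknown direction: {direction!r}")
    control_peak = abs(peak(control))
    if control_peak == 0.0:
        raise InvalidParameterError("control peak current is zero")
    return abs(peak(treated)) / control_peak


def lower_median(values) -> float:
    """Median with the lower-of-the-two convention for even n.

    Integer-stable on integer data (never invents a half value), which is
    why it is used for flow-cytometry median intensities here.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise InvalidParameterError("empty population")
    return float(v[(v.size - 1) // 2])


def median_timecourse(
    populations: Sequence[tuple[float, Sequence[float]]],
) -> Trace:
    """Per-timepoint lower median of intensity populations.

    ``populations`` is a sequence of (time, intensities) pairs, e.g. the
    NBD-PS uptake assay read at several incubation times.
    """
    if len(populations) == 0:
        raise InvalidParameterError("no timepoints")
    times, medians = [], []
    for t, values in populations:
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise InvalidParameterError(f"empty population at t = {t}")
        times.append(float(t))
        medians.append(lower_median(values))
    order = np.argsort(times)
    return Trace(times=np.asarray(times)[order], values=np.asarray(medians)[order])


def fraction_positive(intensities, threshold: float) -> float:
    """Percentage of intensities strictly above the gate threshold."""
    v = np.asarray(intensities, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("empty intensity list")
    return 100.0 * float(np.count_nonzero(v > threshold)) / v.size


def negative_control_threshold(negative_intensities, percentile: float = 99.0) -> float:
    """Gate threshold as a high percentile of a negative-control population.

    The 99th percentile is the standard single-colour gate when no explicit
    gate is given.
    """
    v = np.asarray(negative_intensities, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("empty negative-control population")
    return float(np.percentile(v, percentile))


def fold_change_ddct(q: CtQuad) -> float:
    """Relative expression by the 2^-ΔΔCt method.

    ΔΔCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator;
    one extra cycle on the sample target halves the fold change.
    """
    ddct = (q.ct_target_sample - q.ct_reference_sample) - (
        q.ct_target_calibrator - q.ct_reference_calibrator
    )
    return float(2.0 ** (-ddct))
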