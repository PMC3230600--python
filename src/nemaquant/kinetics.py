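"""Staining-reaction kinetics: OD-versus-time traces and the exponential
phase within which quantification reactions must be stopped.

Stain accumulation during NADH/SDH/COX histochemistry follows a sigmoid
time course (lag, steep exponential rise, plateau).  A four-parameter
logistic

    od(t) = baseline + A / (1 + exp(-k (t - t_mid)))

is fitted by least squares, and the exponential phase is bounded by the
tangent-at-inflection construction familiar from growth-curve lag-time
analysis: the tangent at t_mid meets the baseline at t_mid - 2/k and the
plateau at t_mid + 2/k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .densitometry import mean_intensity, optical_density
from .roi import Roi

logger = logging.getLogger(__name__)


class KineticsError(ValueError):
    pass


class FitError(KineticsError):
    pass


@dataclass
class KineticsTrace:
    """Background-corrected OD time series of one staining reaction."""

    times: np.ndarray          # minutes, strictly increasing
    od_values: np.ndarray
    stain: str = "other"       # NADH | SDH | COX | other
    temperature_C: float = 20.0
    truncated: bool = False    # first part of the reaction not recorded

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od_values = np.asarray(self.od_values, dtype=float)
        if self.times.shape != self.od_values.shape:
            raise KineticsError("times and od_values lengths differ")
        if len(self.times) < 5:
            raise KineticsError("kinetics trace needs >= 5 time points")
        if not np.all(np.diff(self.times) > 0):
            raise KineticsError("times must be strictly increasing")


@dataclass
class LogisticFit:
    A: float          # asymptotic OD amplitude
    t_mid: float      # inflection time, minutes
    k: float          # rate, 1/minute
    baseline: float   # OD offset
    rss: float
    truncated: bool = False

    @property
    def onset(self) -> float:
        return self.t_mid - 2.0 / self.k


def extract_trace(stack: Sequence[np.ndarray], times: Sequence[float],
                  sample_roi: Roi, background_roi: Roi, *,
                  stain: str = "other",
                  temperature_C: float = 20.0) -> KineticsTrace:
    """Per-frame OD of a sample ROI against an adjacent background ROI."""
    if len(stack) != len(times):
        raise KineticsError(
            f"{len(stack)} frames but {len(times)} time stamps"
        )
    od = [
        optical_density(mean_intensity(frame, background_roi),
                        mean_intensity(frame, sample_roi))
        for frame in stack
    ]
    return KineticsTrace(times=np.asarray(times, dtype=float),
                         od_values=np.asarray(od), stain=stain,
                         temperature_C=temperature_C)


def _logistic(t: np.ndarray, baseline: float, A: float,
              t_mid: float, k: float) -> np.ndarray:
    return baseline + A / (1.0 + np.exp(-np.clip(k * (t - t_mid), -500, 500)))


def fit_logistic(trace: KineticsTrace, *, n_restarts: int = 5,
                 seed: int = 0) -> LogisticFit:
    """Least-squares logistic fit with heuristic initialization and seeded
    jittered restarts.

    Initial guess: baseline = min(od), A = od range, t_mid = time at which
    the trace first crosses half range, k from the steepest finite-difference
    slope (slope at inflection = A k / 4).
    """
    t = trace.times
    y = trace.od_values
    y_range = float(y.max() - y.min())
    if y_range <= 0.02:
        raise FitError(
            f"OD range {y_range:.4f} too small to constrain a sigmoid fit"
        )

    baseline0 = float(y.min())
    A0 = y_range
    half = baseline0 + A0 / 2.0
    above = np.nonzero(y >= half)[0]
    t_mid0 = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
    slopes = np.diff(y) / np.diff(t)
    max_slope = float(np.max(slopes))
    k0 = max(4.0 * max_slope / A0, 1e-3) if max_slope > 0 else 1e-3

    span = float(t[-1] - t[0])
    lower = [-np.inf, 1e-6, t[0] - 2 * span, 1e-6]
    upper = [np.inf, np.inf, t[-1] + 2 * span, np.inf]

    def residuals(p):
        return _logistic(t, *p) - y

    rng = np.random.default_rng(seed)
    best = None
    p0 = np.array([baseline0, A0, t_mid0, k0])
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            start = p0
        else:
            jitter = rng.normal(0.0, 0.2, size=4)
            start = p0 * (1.0 + jitter)
            start[2] = t_mid0 + rng.normal(0.0, 0.2) * max(span, 1.0)
        start = np.clip(start, lower, upper)
        try:
            sol = least_squares(residuals, start, bounds=(lower, upper))
        except Exception:  # singular starts
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("logistic fit failed to converge from all starts")
    baseline, A, t_mid, k = best.x
    return LogisticFit(A=float(A), t_mid=float(t_mid), k=float(k),
                       baseline=float(baseline),
                       rss=float(2.0 * best.cost),
                       truncated=trace.truncated)


def exponential_phase(trace: KineticsTrace,
                      fit: LogisticFit | None = None) -> tuple[float, float]:
    """(t_onset, t_end) of the exponential phase: the inflection tangent
    intersects the baseline at t_mid - 2/k and the plateau at t_mid + 2/k.
    Onset is floored at the first sampled time for left-truncated traces."""
    if fit is None:
        fit = fit_logistic(trace)
    t_onset = fit.t_mid - 2.0 / fit.k
    t_end = fit.t_mid + 2.0 / fit.k
    first = float(trace.times[0])
    if t_onset < first:
        if trace.truncated:
            logger.info("onset %.2f min precedes first recorded frame; "
                        "floored to %.2f (truncated trace)", t_onset, first)
        else:
            logger.warning("onset %.2f min precedes first sample; floored "
                           "to %.2f", t_onset, first)
        t_onset = first
    return (float(t_onset), float(t_end))
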