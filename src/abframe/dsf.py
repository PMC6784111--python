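"""Thermal-shift (DSF) melt-curve simulation and Tm extraction.

A two-state unfolding transition with linear pre- and post-transition
baselines is modelled as

    F(T) = (a0 + a1*T) + [(b0 + b1*T) - (a0 + a1*T)] / (1 + exp((Tm - T)/s))

where s (the slope parameter, in degC) sets the transition width. The default
midpoint estimator is the first qualifying local maximum of the smoothed
first derivative dF/dT (Savitzky-Golay smoothing, parabolic peak refinement);
a two-state sigmoid fit restricted to the first-transition window is
available as an alternative. "First unfolding transition" means the
lowest-temperature peak whose height exceeds a configurable fraction of the
global derivative maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter


class NoTransitionError(RuntimeError):
    """Raised when no qualifying unfolding transition is present."""


@dataclass
class MeltCurve:
    temperature: np.ndarray   # degC, increasing grid
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("grids must have equal length")
        dT = np.diff(self.temperature)
        if np.any(dT <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.any(dT > 1.0 + 1e-9):
            raise ValueError("temperature grid spacing must be <= 1 degC")


@dataclass
class TmResult:
    tm: float          # degC
    method: str        # "derivative" or "sigmoid-fit"
    amplitude: float   # fluorescence jump across the transition


def sigmoid_transition(temperature: np.ndarray, tm: float, slope: float) -> np.ndarray:
    """Two-state occupancy 1/(1+exp((tm-T)/slope)); 0 folded -> 1 unfolded."""
    return 1.0 / (1.0 + np.exp((tm - np.asarray(temperature, float)) / slope))


def simulate_melt_curve(
    tm: float,
    slope: float,
    pre_baseline: Tuple[float, float],
    post_baseline: Tuple[float, float],
    grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> MeltCurve:
    """Simulate a two-state melt curve with linear baselines."""
    grid = np.asarray(grid, dtype=float)
    if not grid.min() < tm < grid.max():
        raise ValueError("tm must lie inside the temperature grid")
    if slope <= 0:
        raise ValueError("slope must be positive")
    a0, a1 = pre_baseline
    b0, b1 = post_baseline
    pre = a0 + a1 * grid
    post = b0 + b1 * grid
    f = pre + (post - pre) * sigmoid_transition(grid, tm, slope)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=grid.shape)
    return MeltCurve(grid.copy(), f)


def _first_derivative_peak(curve: MeltCurve, signal_threshold: float,
                           min_width_c: float = 2.0):
    T, F = curve.temperature, curve.fluorescence
    frange = F.max() - F.min()
    if frange <= 0:
        raise NoTransitionError("flat curve: no unfolding transition")
    window = min(11, len(T) - (1 - len(T) % 2))  # odd, <= n
    smooth = savgol_filter(F, window_length=max(window, 5), polyorder=3)
    deriv = np.gradient(smooth, T)
    dmax = deriv.max()
    if dmax <= 0:
        raise NoTransitionError("no increasing fluorescence transition found")
    height = signal_threshold * dmax
    dT_med = float(np.median(np.diff(T)))
    # genuine unfolding transitions are broad; narrow spikes are noise
    peaks, props = find_peaks(deriv, height=height, prominence=height / 2,
                              width=min_width_c / dT_med)
    if len(peaks) == 0:
        raise NoTransitionError("no qualifying derivative peak")
    return T, smooth, deriv, peaks, frange


def extract_tm(
    curve: MeltCurve,
    method: str = "derivative",
    signal_threshold: float = 0.10,
    min_amplitude_frac: float = 0.05,
    min_points: int = 20,
) -> TmResult:
    """Midpoint temperature of the first unfolding transition.

    Parameters
    ----------
    method : {"derivative", "sigmoid-fit"}
        Derivative: first local maximum of the smoothed dF/dT exceeding
        `signal_threshold` x (global derivative maximum), refined by parabolic
        interpolation. Sigmoid-fit: two-state model fitted over a window
        around that peak.
    min_amplitude_frac : float
        Minimum transition amplitude, as a fraction of the full fluorescence
        range, for the transition to qualify.
    """
    if len(curve.temperature) < min_points:
        raise ValueError(f"need >= {min_points} grid points")
    if method not in ("derivative", "sigmoid-fit"):
        raise ValueError(f"unknown method {method!r}")

    T, smooth, deriv, peaks, frange = _first_derivative_peak(curve, signal_threshold)
    dT_med = float(np.median(np.diff(T)))

    first = None
    for p in peaks:  # lowest temperature first
        # transition amplitude = fluorescence jump across the peak; noise
        # spurs in the derivative carry no net jump and are rejected here
        lo = max(p - int(round(6 / dT_med)), 0)
        hi = min(p + int(round(6 / dT_med)), len(T) - 1)
        amp = float(smooth[hi] - smooth[lo])
        if amp >= min_amplitude_frac * frange:
            first = (p, amp)
            break
    if first is None:
        raise NoTransitionError("no transition above the amplitude threshold")
    p, amplitude = first

    # parabolic sub-grid refinement over ~2 degC around the peak
    half = max(2, int(round(2.0 / dT_med)))
    lo, hi = max(p - half, 0), min(p + half, len(T) - 1)
    if hi - lo >= 2:
        coef = np.polyfit(T[lo:hi + 1], deriv[lo:hi + 1], 2)
        vertex = -coef[1] / (2 * coef[0]) if coef[0] < 0 else T[p]
        tm_est = float(np.clip(vertex, T[lo], T[hi]))
    else:
        tm_est = float(T[p])

    if method == "derivative":
        return TmResult(tm=tm_est, method=method, amplitude=amplitude)

    # sigmoid fit restricted to the first-transition window
    half = max(8.0, 10 * dT_med)
    mask = (T >= tm_est - half) & (T <= tm_est + half)
    Tw, Fw = T[mask], curve.fluorescence[mask]

    def model(t, a0, a1, b0, b1, tm, slope):
        pre = a0 + a1 * t
        post = b0 + b1 * t
        return pre + (post - pre) * sigmoid_transition(t, tm, abs(slope) + 1e-6)

    p0 = [Fw[0], 0.0, Fw[-1], 0.0, tm_est, 1.0]
    try:
        popt, _ = curve_fit(model, Tw, Fw, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise NoTransitionError(f"sigmoid fit failed: {exc}") from exc
    tm_fit = float(popt[4])
    if not T.min() < tm_fit < T.max():
        raise NoTransitionError("fitted midpoint outside the temperature grid")
    return TmResult(tm=tm_fit, method=method, amplitude=amplitude)


def delta_tm(variant: TmResult, parental: TmResult) -> float:
    """Tm shift of a variant relative to the parental antibody (degC)."""
    if variant.method != parental.method:
        raise ValueError("Tm values from different extraction methods")
    return variant.tm - parental.tm
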