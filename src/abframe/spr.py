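"""1:1 Langmuir SPR sensorgram simulation and global kinetic fitting.

The binding model is the standard pseudo-first-order 1:1 interaction at
constant analyte concentration C:

    association  (t <= t_stop):  R(t) = Req * (1 - exp(-(ka*C + kd) * t)),
                                 Req  = Rmax * C * ka / (C * ka + kd)
    dissociation (t >  t_stop):  R(t) = R(t_stop) * exp(-kd * (t - t_stop))

A single (ka, kd, Rmax) triple is fitted globally across all analyte
concentrations by least squares on a log-parameter scale, initialized from a
dissociation-phase log-linear regression (kd) and an equilibrium-plateau
isotherm scan (ka, Rmax).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Raised when a kinetic fit fails; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class Sensorgram:
    time: np.ndarray            # s
    response: np.ndarray        # RU
    concentration: float        # M
    t_stop: float               # injection stop, s

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")


@dataclass
class KineticFit:
    ka: float       # 1/(M s)
    kd: float       # 1/s
    rmax: float     # RU
    kD: float       # M, = kd/ka
    rss: float

    def __post_init__(self):
        if min(self.ka, self.kd, self.rmax) <= 0:
            raise ValueError("rate constants and Rmax must be positive")
        if abs(self.kD - self.kd / self.ka) > 1e-12 * self.kD:
            raise ValueError("KD must equal kd/ka")


def langmuir_response(
    t: np.ndarray, ka: float, kd: float, rmax: float, conc: float, t_stop: float
) -> np.ndarray:
    """Noise-free 1:1 model response at times `t`."""
    t = np.asarray(t, dtype=float)
    kobs = ka * conc + kd
    req = rmax * conc * ka / kobs
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_stop)))
    r_stop = req * (1.0 - np.exp(-kobs * t_stop))
    dissoc = r_stop * np.exp(-kd * np.maximum(t - t_stop, 0.0))
    return np.where(t <= t_stop, assoc, dissoc)


def simulate_sensorgram(
    ka: float,
    kd: float,
    rmax: float,
    concentrations: Sequence[float],
    times: np.ndarray,
    t_stop: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Sensorgram]:
    """Simulate one sensorgram per analyte concentration (Gaussian noise)."""
    if min(ka, kd, rmax) <= 0:
        raise ValueError("ka, kd and Rmax must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.max() <= t_stop:
        raise ValueError("times must extend past the injection stop")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for conc in concentrations:
        resp = langmuir_response(times, ka, kd, rmax, conc, t_stop)
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=times.shape)
        out.append(Sensorgram(times.copy(), resp, float(conc), float(t_stop)))
    return out


def _initial_guess(sensorgrams: Sequence[Sensorgram]) -> np.ndarray:
    # kd from dissociation-phase log-linear regression, pooled over curves
    slopes = []
    for sg in sensorgrams:
        mask = (sg.time > sg.t_stop) & (sg.response > 0)
        if mask.sum() >= 3:
            slope = np.polyfit(sg.time[mask], np.log(sg.response[mask]), 1)[0]
            if slope < 0:
                slopes.append(-slope)
    kd0 = float(np.median(slopes)) if slopes else 1e-3

    # plateau isotherm: Req(C) = Rmax * C / (C + KD); scan KD, solve Rmax
    concs = np.array([sg.concentration for sg in sensorgrams])
    reqs = np.array([
        np.mean(sg.response[(sg.time <= sg.t_stop)][-3:]) for sg in sensorgrams
    ])
    reqs = np.maximum(reqs, 1e-9)
    best = None
    for kD in np.geomspace(concs.min() / 100, concs.max() * 100, 60):
        f = concs / (concs + kD)
        rmax = float(np.dot(reqs, f) / np.dot(f, f))
        rss = float(np.sum((reqs - rmax * f) ** 2))
        if rmax > 0 and (best is None or rss < best[0]):
            best = (rss, kD, rmax)
    _, kD0, rmax0 = best
    ka0 = kd0 / kD0
    return np.log(np.array([ka0, kd0, rmax0]))


def fit_langmuir_1to1(sensorgrams: Sequence[Sensorgram]) -> KineticFit:
    """Globally fit shared (ka, kd, Rmax) across sensorgrams; KD = kd/ka."""
    if len({sg.concentration for sg in sensorgrams}) < 2:
        raise ValueError("global fitting requires >=2 analyte concentrations")

    def residuals(logp):
        ka, kd, rmax = np.exp(logp)
        return np.concatenate([
            sg.response - langmuir_response(sg.time, ka, kd, rmax,
                                            sg.concentration, sg.t_stop)
            for sg in sensorgrams
        ])

    x0 = _initial_guess(sensorgrams)
    result = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not result.success:
        raise FitError("1:1 Langmuir fit did not converge",
                       last_iterate=np.exp(result.x))
    ka, kd, rmax = np.exp(result.x)
    return KineticFit(ka=float(ka), kd=float(kd), rmax=float(rmax),
                      kD=float(kd / ka), rss=float(np.sum(result.fun ** 2)))
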