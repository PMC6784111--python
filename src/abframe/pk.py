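"""Compartmental plasma-decay fitting and non-compartmental analysis (NCA).

Plasma concentration-time data after an intravenous bolus are fitted by
unweighted nonlinear least squares to

    mono-exponential:  C(t) = C0 * exp(-k t)                (one compartment)
    bi-exponential:    C(t) = C0a * exp(-a t) + C0b * exp(-b t),  a > b > 0

with the bi-exponential initialized by curve peeling (terminal log-linear
regression, then a residual peel for the distribution phase) and the
ordering a > b enforced by parameterization. Model choice uses the extra
sum-of-squares F-test,

    F = ((SS_mono - SS_bi) / 2) / (SS_bi / (n - 4)),  p from F(2, n-4),

choosing the two-compartment model iff p < 0.05.

NCA: AUC(0-t_end) by the trapezoidal rule over the observed (group-mean)
points with C(0) anchored by the fitted model value at t = 0; CL = D/AUC
scaled per kg; MRT model-based by default, (C0a/a^2 + C0b/b^2)/(C0a/a +
C0b/b); V_D,ss = CL * MRT; t1/2,beta = ln2 / beta. Concentrations below the
limit of quantification (LOQ) are censored and excluded from fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

DEFAULT_BODY_WEIGHT_KG = 0.030  # mouse
DEFAULT_T_END_H = 144.0


class InsufficientDataError(ValueError):
    pass


class PKFitError(RuntimeError):
    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class PKDataset:
    """Plasma time-course for one antibody x dose arm.

    `concentrations` has shape (n_animals, n_times); a 1-D array is treated
    as a single (group-mean) profile. `censored` marks below-LOQ values.
    """

    antibody_id: str
    dose_mg_per_kg: float
    times: np.ndarray                 # h
    concentrations: np.ndarray        # mg/L
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG
    loq_mg_per_l: Optional[float] = None
    censored: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.atleast_2d(
            np.asarray(self.concentrations, dtype=float)
        )
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if self.concentrations.shape[1] != len(self.times):
            raise ValueError("concentration columns must match times")
        if self.censored is None:
            self.censored = np.zeros_like(self.concentrations, dtype=bool)
        else:
            self.censored = np.atleast_2d(np.asarray(self.censored, dtype=bool))
        if np.any(self.concentrations[~self.censored] <= 0):
            raise ValueError("uncensored concentrations must be positive")

    def mean_profile(self) -> Tuple[np.ndarray, np.ndarray]:
        """Group-mean concentration per time point over uncensored animals.

        A time point where every animal is censored is dropped.
        """
        keep_t, means = [], []
        for j, t in enumerate(self.times):
            vals = self.concentrations[~self.censored[:, j], j]
            if vals.size:
                keep_t.append(t)
                means.append(float(vals.mean()))
        return np.array(keep_t), np.array(means)

    @property
    def n_uncensored_points(self) -> int:
        return len(self.mean_profile()[0])


def censor_loq(data: PKDataset, loq: float) -> PKDataset:
    """Flag concentrations below the limit of quantification as censored."""
    if loq <= 0:
        raise ValueError("LOQ must be positive")
    return replace(
        data,
        loq_mg_per_l=loq,
        censored=data.concentrations < loq,
    )


@dataclass
class ExpFit:
    model: str                    # "mono" or "bi"
    params: Dict[str, float]      # mono: c0, k; bi: c0_alpha, alpha, c0_beta, beta
    rss: float
    n_points: int
    k_at_boundary: bool = False   # mono only: decay rate pinned near zero

    def __post_init__(self):
        if self.model not in ("mono", "bi"):
            raise ValueError("model must be 'mono' or 'bi'")
        if self.model == "bi" and not (
            self.params["alpha"] > self.params["beta"] > 0
        ):
            raise ValueError("bi-exponential requires alpha > beta > 0")
        # phase amplitudes are left unconstrained: near the one-compartment
        # limit the second phase is unidentifiable and constraining its sign
        # would distort the extra-SS F-test null distribution. Downstream
        # PK parameters still demand a physically valid (positive) fit.

    @property
    def c0(self) -> float:
        """Model concentration at t = 0."""
        if self.model == "mono":
            return self.params["c0"]
        return self.params["c0_alpha"] + self.params["c0_beta"]

    @property
    def beta(self) -> float:
        """Terminal rate constant (k for the one-compartment model)."""
        return self.params["k"] if self.model == "mono" else self.params["beta"]

    @property
    def t_half_beta(self) -> float:
        return np.log(2.0) / self.beta

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "mono":
            return self.params["c0"] * np.exp(-self.params["k"] * t)
        return (
            self.params["c0_alpha"] * np.exp(-self.params["alpha"] * t)
            + self.params["c0_beta"] * np.exp(-self.params["beta"] * t)
        )


@dataclass
class ModelSelection:
    f_statistic: float
    p_value: float
    chosen: str

    def __post_init__(self):
        if self.f_statistic < 0:
            raise ValueError("F must be >= 0")


@dataclass
class PKParameters:
    antibody_id: str
    dose_mg_per_kg: float
    c0_mg_per_l: float
    t_half_beta_h: float
    auc_mg_h_per_l: float
    aumc_mg_h2_per_l: float
    mrt_h: float
    cl_ml_per_h_per_kg: float
    vdss_ml_per_kg: float

    def __post_init__(self):
        for name in ("c0_mg_per_l", "t_half_beta_h", "auc_mg_h_per_l",
                     "mrt_h", "cl_ml_per_h_per_kg", "vdss_ml_per_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # defining identities, stored consistently
        cl = 1000.0 * self.dose_mg_per_kg / self.auc_mg_h_per_l
        if abs(self.cl_ml_per_h_per_kg - cl) > 1e-9 * cl:
            raise ValueError("CL must equal dose/AUC")
        vdss = self.cl_ml_per_h_per_kg * self.mrt_h
        if abs(self.vdss_ml_per_kg - vdss) > 1e-9 * vdss:
            raise ValueError("V_D,ss must equal CL x MRT")


def _profile(data) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(data, PKDataset):
        return data.mean_profile()
    t, c = data
    return np.asarray(t, dtype=float), np.asarray(c, dtype=float)


def fit_monoexponential(data) -> ExpFit:
    """Least-squares fit of C(t) = C0 exp(-k t) on the linear scale."""
    t, c = _profile(data)
    if len(t) < 3:
        raise InsufficientDataError("mono-exponential fit needs >= 3 points")
    slope, intercept = np.polyfit(t, np.log(c), 1)
    k0 = max(-slope, 1e-10)
    x0 = np.log([np.exp(intercept), k0])

    def residuals(logp):
        c0, k = np.exp(logp)
        return c - c0 * np.exp(-k * t)

    res = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    c0, k = np.exp(res.x)
    boundary = k < 1e-8
    return ExpFit(model="mono", params={"c0": float(c0), "k": float(k)},
                  rss=float(np.sum(res.fun ** 2)), n_points=len(t),
                  k_at_boundary=bool(boundary))


def _peel(t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Curve-peeling initial values (log c0a, log c0b, log beta, log(alpha-beta))."""
    n_tail = max(3, len(t) // 2)
    bt, bc = t[-n_tail:], c[-n_tail:]
    slope, intercept = np.polyfit(bt, np.log(bc), 1)
    beta0 = max(-slope, 1e-6)
    c0b0 = float(np.exp(intercept))
    resid = c - c0b0 * np.exp(-beta0 * t)
    head = resid[: len(t) - n_tail]
    th = t[: len(t) - n_tail]
    pos = head > 0
    if pos.sum() >= 2:
        s2, i2 = np.polyfit(th[pos], np.log(head[pos]), 1)
        alpha0 = max(-s2, beta0 * 2)
        c0a0 = float(np.exp(i2))
    else:
        alpha0, c0a0 = beta0 * 10, c[0] * 0.5
    c0a0 = max(c0a0, 1e-6)
    return np.log([c0a0, c0b0, beta0, max(alpha0 - beta0, beta0)])


def _varpro_rss(t, c, alpha, beta):
    """RSS with amplitudes profiled out (linear least squares)."""
    design = np.column_stack([np.exp(-alpha * t), np.exp(-beta * t)])
    coef, *_ = np.linalg.lstsq(design, c, rcond=None)
    rss = float(np.sum((c - design @ coef) ** 2))
    return rss, coef


def fit_biexponential(data, scale: str = "linear") -> ExpFit:
    """Least-squares bi-exponential fit with alpha > beta by construction.

    On the linear scale the rate pair is optimized by variable projection
    (amplitudes solved linearly at each step) from multiple starts, so the
    global optimum is found even in the near-degenerate one-compartment
    limit. `scale` = "log" fits residuals on the log-concentration scale
    instead (appropriate for multiplicative/constant-CV error), with
    amplitudes kept positive.
    """
    t, c = _profile(data)
    if len(t) < 5:
        raise InsufficientDataError("bi-exponential fit needs >= 5 points")
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown scale {scale!r}")

    if scale == "log":
        return _fit_biexponential_log(t, c)

    from scipy.optimize import minimize

    def objective(x):
        logb, loggap = np.clip(x, -500, 50)
        beta = np.exp(logb)
        alpha = beta + np.exp(loggap)
        return _varpro_rss(t, c, alpha, beta)[0]

    x_peel = _peel(t, c)
    starts = [np.array([x_peel[2], x_peel[3]])]
    span = t.max() - t.min()
    for beta0 in (0.3 / span, 2.0 / span):
        for ratio in (3.0, 20.0):
            starts.append(np.log([beta0, beta0 * (ratio - 1.0)]))

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise PKFitError("bi-exponential fit did not converge",
                         diagnostics={"starts": len(starts)})
    logb, loggap = np.clip(best.x, -500, 50)
    beta = float(np.exp(logb))
    alpha = float(beta + max(np.exp(loggap), beta * 1e-9))
    rss, (c0a, c0b) = _varpro_rss(t, c, alpha, beta)
    return ExpFit(
        model="bi",
        params={"c0_alpha": float(c0a), "alpha": alpha,
                "c0_beta": float(c0b), "beta": beta},
        rss=rss,
        n_points=len(t),
    )


def _fit_biexponential_log(t, c) -> ExpFit:
    def unpack(x):
        with np.errstate(over="ignore"):
            c0a, c0b, beta, gap = np.exp(np.minimum(x, 500))
        return c0a, c0b, beta + max(gap, beta * 1e-9), beta

    def residuals(x):
        c0a, c0b, alpha, beta = unpack(x)
        pred = c0a * np.exp(-alpha * t) + c0b * np.exp(-beta * t)
        return np.log(c) - np.log(np.maximum(pred, 1e-300))

    res = least_squares(residuals, _peel(t, c), method="lm",
                        xtol=1e-15, ftol=1e-15, max_nfev=20000)
    if not (res.success and np.all(np.isfinite(res.x))):
        raise PKFitError("bi-exponential fit did not converge",
                         diagnostics={"x": np.exp(res.x), "status": res.status})
    c0a, c0b, alpha, beta = unpack(res.x)
    return ExpFit(
        model="bi",
        params={"c0_alpha": float(c0a), "alpha": float(alpha),
                "c0_beta": float(c0b), "beta": float(beta)},
        rss=float(np.sum(res.fun ** 2)),
        n_points=len(t),
    )


def extra_ss_f_test(mono: ExpFit, bi: ExpFit, alpha: float = 0.05) -> ModelSelection:
    """Extra sum-of-squares F-test between nested decay models."""
    if mono.n_points != bi.n_points:
        raise ValueError("fits must be to the same data")
    n = mono.n_points
    if n <= 4:
        raise InsufficientDataError("F-test requires n > 4 points")
    if bi.rss > mono.rss or mono.rss < 1e-12:
        # the simpler model already fits (to numerical precision): the extra
        # parameters cannot be justified
        f = 0.0
    else:
        f = ((mono.rss - bi.rss) / 2.0) / (bi.rss / (n - 4))
    p = float(stats.f.sf(f, 2, n - 4))
    return ModelSelection(f_statistic=float(f), p_value=p,
                          chosen="bi" if p < alpha else "mono")


def select_decay_model(data) -> Tuple[ExpFit, Optional[ModelSelection]]:
    """Fit mono and bi models and choose by F-test, with mono fallback.

    Falls back to the one-compartment model when fewer than five uncensored
    points remain (the below-LOQ case) or when the bi-exponential fit fails.
    """
    t, _ = _profile(data)
    mono = fit_monoexponential(data)
    if len(t) < 5:
        return mono, None
    try:
        bi = fit_biexponential(data)
    except (PKFitError, InsufficientDataError):
        return mono, None
    selection = extra_ss_f_test(mono, bi)
    if selection.chosen == "bi" and min(bi.params["c0_alpha"],
                                        bi.params["c0_beta"]) <= 0:
        # statistically preferred but physically degenerate: keep mono
        return mono, selection
    return (bi if selection.chosen == "bi" else mono), selection


def model_based_mrt(fit: ExpFit) -> float:
    """MRT from the fitted exponential moments, AUMC(0-inf)/AUC(0-inf)."""
    if fit.model == "mono":
        return 1.0 / fit.params["k"]
    c0a, a = fit.params["c0_alpha"], fit.params["alpha"]
    c0b, b = fit.params["c0_beta"], fit.params["beta"]
    return (c0a / a**2 + c0b / b**2) / (c0a / a + c0b / b)


def nca(
    data: PKDataset,
    fit: ExpFit,
    t_end: float = DEFAULT_T_END_H,
    mrt_method: str = "model",
) -> PKParameters:
    """Non-compartmental parameters from observed points anchored by the fit.

    AUC(0-t_end) and AUMC by the trapezoidal rule over the group-mean
    uncensored points, with C(0) taken from the fitted model (no t = 0 sample
    exists); CL = dose/AUC per kg; V_D,ss = CL x MRT.
    """
    t, c = data.mean_profile()
    mask = t <= t_end + 1e-9
    t, c = t[mask], c[mask]
    if len(t) == 0:
        raise InsufficientDataError("no uncensored points within [0, t_end]")
    if t[-1] < t_end:
        warnings.warn(
            f"last uncensored point at {t[-1]:g} h precedes t_end={t_end:g} h; "
            "AUC truncated at the last uncensored point", stacklevel=2,
        )
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[fit.c0], c])
    auc = float(np.trapezoid(c, t))
    aumc = float(np.trapezoid(t * c, t))
    if mrt_method == "model":
        mrt = model_based_mrt(fit)
    elif mrt_method == "trapezoid":
        mrt = aumc / auc
    else:
        raise ValueError(f"unknown mrt_method {mrt_method!r}")
    cl = 1000.0 * data.dose_mg_per_kg / auc  # mL/h/kg
    return PKParameters(
        antibody_id=data.antibody_id,
        dose_mg_per_kg=data.dose_mg_per_kg,
        c0_mg_per_l=fit.c0,
        t_half_beta_h=fit.t_half_beta,
        auc_mg_h_per_l=auc,
        aumc_mg_h2_per_l=aumc,
        mrt_h=mrt,
        cl_ml_per_h_per_kg=cl,
        vdss_ml_per_kg=cl * mrt,
    )
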