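"""Relaxation-model fitting for dwell-stage force curves.

Under a ramp-and-hold indentation by a spherical punch, the normalized
contact force of a linear viscoelastic half-space is the convolution

    F(t) = int_0^t R(t - t') d/dt' [ (delta(t')/delta_max)^(3/2) ] dt'

with the relaxation function R.  The two canonical materials are

    R_P(t) = E_inf + dE * t^(-beta)        (power law)
    R_E(t) = E_inf + dE * exp(-t / tau)    (exponential / standard
                                            linear solid)

whose dwell-stage (t > tau_l) closed forms are

    F_P(t) = E_inf + a t^(-beta),    a ~ dE * Gamma(1 - beta)
    F_E(t) = E_inf + b e^(-(t - tau_l)/tau) - c e^(-t/tau)

with b = (3 tau / 2 tau_l) dE and
c = (3 sqrt(pi) / 4) (tau/tau_l)^(3/2) dE erfi(sqrt(tau_l / tau)).
b and c are deterministic functions of (dE, tau, tau_l), never free fit
parameters.  Times are measured from the start of loading, the clock on
which both models are defined and compared.

The goodness of fit is the mean squared error over the N_p dwell
samples,  chi_M = (1/N_p) sum_i [F(t_i) - F_M(t_i)]^2 , the feature on
which rheological regimes are classified.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares
from scipy.special import dawsn, erfi, gamma as gamma_fn

from .indentation import ForceCurve, hertz_constant

__all__ = [
    "PowerLawFit", "ExponentialFit", "HertzFit",
    "fit_power_law", "fit_exponential", "chi_stat", "hertz_exponent",
    "convolve_relaxation", "generate_synthetic_curve",
    "power_law_dwell", "exponential_dwell",
]

MIN_DWELL_SAMPLES = 10
BETA_MAX = 5.0


@dataclasses.dataclass
class PowerLawFit:
    """F_P(t) = E_inf + a t^(-beta) on the dwell window."""

    E_inf: float
    a: float
    beta: float
    chi: float
    n_points: int
    window: tuple[float, float]
    converged: bool = True

    @property
    def dE(self) -> float:
        """Amplitude mapped back through a ~ dE * Gamma(1 - beta).

        The mapping is an expansion valid for beta < 1; outside that
        range it is reported as nan.
        """
        if 0 < self.beta < 1:
            return self.a / gamma_fn(1.0 - self.beta)
        return float("nan")


@dataclasses.dataclass
class ExponentialFit:
    """F_E(t) = E_inf + b e^(-(t-tau_l)/tau) - c e^(-t/tau); free
    parameters (E_inf, dE, tau) only."""

    E_inf: float
    dE: float
    tau: float
    b: float
    c: float
    chi: float
    n_points: int
    window: tuple[float, float]
    converged: bool = True


@dataclasses.dataclass
class HertzFit:
    """Loading-stage contact law f ~ delta^lam."""

    lam: float
    prefactor: float
    r2: float
    n_points: int


# ------------------------------------------------------------- models

def power_law_dwell(t: np.ndarray, E_inf: float, a: float, beta: float) -> np.ndarray:
    return E_inf + a * np.asarray(t, dtype=float) ** (-beta)


def _exp_b_c(dE: float, tau: float, tau_l: float) -> tuple[float, float]:
    with np.errstate(over="ignore"):
        b = 1.5 * tau / tau_l * dE
        c = 0.75 * np.sqrt(np.pi) * (tau / tau_l) ** 1.5 * dE * erfi(
            np.sqrt(tau_l / tau))
    return float(b), float(c)


def exponential_dwell(t: np.ndarray, E_inf: float, dE: float, tau: float,
                      tau_l: float) -> np.ndarray:
    """Evaluate F_E stably for any tau/tau_l ratio.

    b e^(-(t-tau_l)/tau) - c e^(-t/tau) is regrouped through the Dawson
    function D(x) = (sqrt(pi)/2) e^(-x^2) erfi(x), avoiding the overflow
    of erfi at tau << tau_l.
    """
    t = np.asarray(t, dtype=float)
    x = np.sqrt(tau_l / tau)
    # c e^(-tau_l/tau) = (3/2)(tau/tau_l)^(3/2) dE D(x), so the dwell force
    # is a single decaying exponential with amplitude:
    amp = 1.5 * dE * ((tau / tau_l) - (tau / tau_l) ** 1.5 * dawsn(x))
    return E_inf + amp * np.exp(-(t - tau_l) / tau)


# ------------------------------------------------------------- fitting

def chi_stat(observed: np.ndarray, model_values: np.ndarray) -> float:
    """Mean squared error over the N_p samples."""
    observed = np.asarray(observed, dtype=float)
    model_values = np.asarray(model_values, dtype=float)
    if observed.shape != model_values.shape:
        raise ValueError(
            f"length mismatch: {observed.shape} vs {model_values.shape}")
    if observed.size < 1:
        raise ValueError("need at least one sample")
    return float(np.mean((observed - model_values) ** 2))


def _dwell_arrays(curve: ForceCurve) -> tuple[np.ndarray, np.ndarray]:
    td, fd = curve.dwell()
    if td.size < MIN_DWELL_SAMPLES:
        raise ValueError(
            f"need at least {MIN_DWELL_SAMPLES} dwell samples, got {td.size}")
    return td, fd


def _init_levels(td: np.ndarray, fd: np.ndarray) -> tuple[float, float]:
    tail = fd[-max(3, td.size // 10):]
    E0 = float(tail.mean())
    dE0 = float(max(fd[0] - E0, 1e-6 * max(abs(E0), 1.0)))
    return max(E0, 0.0), dE0


def fit_power_law(curve: ForceCurve) -> PowerLawFit:
    """Bounded least-squares fit of F_P over the dwell window."""
    td, fd = _dwell_arrays(curve)
    E0, dE0 = _init_levels(td, fd)
    window = (float(td[0]), float(td[-1]))

    def resid(p):
        return power_law_dwell(td, *p) - fd

    best = None
    for beta0 in (0.5, 1.0, 2.0):
        p0 = [E0, dE0 * td[0] ** beta0, beta0]
        try:
            sol = least_squares(
                resid, p0, bounds=([0.0, 0.0, 1e-3], [np.inf, np.inf, BETA_MAX]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return PowerLawFit(np.nan, np.nan, np.nan, np.inf, td.size, window,
                           converged=False)
    E, a, beta = best.x
    chi = chi_stat(fd, power_law_dwell(td, E, a, beta))
    return PowerLawFit(float(E), float(a), float(beta), chi, td.size, window)


def fit_exponential(curve: ForceCurve) -> ExponentialFit:
    """Bounded least-squares fit of F_E; b, c derived, not free."""
    td, fd = _dwell_arrays(curve)
    tau_l = curve.tau_l
    if tau_l <= 0:
        raise ValueError("curve has no loading duration (tau_l <= 0)")
    E0, dE0 = _init_levels(td, fd)
    window = (float(td[0]), float(td[-1]))
    T = td[-1] - tau_l

    def resid(p):
        return exponential_dwell(td, p[0], p[1], p[2], tau_l) - fd

    best = None
    for tau0 in (T / 50.0, T / 5.0, T):
        p0 = [E0, dE0, tau0]
        try:
            sol = least_squares(
                resid, p0, bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return ExponentialFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf,
                              td.size, window, converged=False)
    E, dE, tau = best.x
    b, c = _exp_b_c(dE, tau, tau_l)
    chi = chi_stat(fd, exponential_dwell(td, E, dE, tau, tau_l))
    return ExponentialFit(float(E), float(dE), float(tau), b, c, chi,
                          td.size, window)


def hertz_exponent(curve: ForceCurve, window: tuple[float, float] = (0.2, 1.0)
                   ) -> HertzFit:
    """Loading exponent lambda from a log-log fit of f_norm vs delta.

    The fit uses loading samples with delta in ``window * delta_max``
    (default the upper 80% of the ramp, where the contact is developed).
    Intended for elastic reference runs (gamma = 0).
    """
    delta_max = curve.meta.get("delta_max", float(curve.delta.max()))
    loading = curve.t <= curve.tau_l
    m = loading & (curve.delta >= window[0] * delta_max) \
        & (curve.delta <= window[1] * delta_max)
    d = curve.delta[m]
    f = curve.f_norm[m]
    if d.size < 2:
        raise ValueError("not enough loading samples in the fit window")
    if np.any(f <= 0):
        raise ValueError("non-positive forces in the Hertz fit window")
    X = np.log(d)
    Y = np.log(f)
    lam, logA = np.polyfit(X, Y, 1)
    pred = lam * X + logA
    ss_res = float(np.sum((Y - pred) ** 2))
    ss_tot = float(np.sum((Y - Y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HertzFit(float(lam), float(np.exp(logA)), r2, int(d.size))


# ----------------------------------------------------- oracle & fixtures

def convolve_relaxation(t: np.ndarray, R: np.ndarray, delta: np.ndarray,
                        delta_max: float | None = None) -> np.ndarray:
    """Trapezoidal evaluation of the hereditary convolution integral.

    Computes ``F(t_i) = int_0^{t_i} R(t_i - t') g'(t') dt'`` with
    ``g = (delta/delta_max)^(3/2)`` (or ``delta^(3/2)`` when
    ``delta_max`` is None), all sampled on the common, strictly
    increasing grid ``t``.  Serves as the independent quadrature oracle
    for the closed-form dwell models.
    """
    t = np.asarray(t, dtype=float)
    R = np.asarray(R, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    if not (t.shape == R.shape == delta.shape):
        raise ValueError("t, R, delta must share one grid")
    g = delta ** 1.5 if delta_max is None else (delta / delta_max) ** 1.5
    dg = np.gradient(g, t)
    n = t.size
    F = np.zeros(n)
    # R is sampled on t (starting at t[0] = first lag); interpolate lags
    for i in range(1, n):
        lag = t[i] - t[: i + 1]
        Rl = np.interp(lag, t - t[0], R)
        F[i] = np.trapezoid(Rl * dg[: i + 1], t[: i + 1])
    return F


def generate_synthetic_curve(model: str, params: dict, tau_l: float,
                             dwell_time: float, n_samples: int = 2000,
                             noise_sd: float = 0.0, seed: int | None = None,
                             sigma_s: float = 11.0, delta_max: float = 0.8
                             ) -> ForceCurve:
    """Sample a dwell-stage curve from F_P or F_E plus Gaussian noise.

    Dwell-only by construction (t starts just above tau_l), which keeps
    F_P finite for any beta > 0.  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if tau_l <= 0 or dwell_time <= 0:
        raise ValueError("tau_l and dwell_time must be > 0")
    t = tau_l + np.linspace(dwell_time / n_samples, dwell_time, n_samples)
    model = model.upper()
    if model in ("PL", "P"):
        f = power_law_dwell(t, params["E_inf"], params["a"], params["beta"])
    elif model in ("EXP", "E"):
        f = exponential_dwell(t, params["E_inf"], params["dE"], params["tau"],
                              tau_l)
    else:
        raise ValueError(f"unknown model {model!r}; use 'PL' or 'EXP'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    const = hertz_constant(sigma_s, delta_max)
    meta = {"model": model, "params": dict(params), "tau_l": tau_l,
            "sigma_s": sigma_s, "delta_max": delta_max, "nu": 0.5,
            "noise_sd": noise_sd, "seed": seed, "synthetic": True}
    return ForceCurve(t=t, delta=np.full_like(t, delta_max), f_raw=f * const,
                      f_norm=f, tau_l=tau_l, meta=meta)
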