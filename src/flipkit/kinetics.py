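"""Kinetic modelling of recombinase flipping profiles.

A flipping profile is the time course of the fraction of flipped
discriminators for one RBS variant after induction.  Because recombination
is irreversible the underlying curve is non-decreasing on the observation
window [0, 720] min.  Profiles are fitted with a generalized logistic
(Richards) curve and, when that optimization fails, with a saturating
exponential; fitted curves are integrated over a window (by default
0-480 min) and normalized by the window length to give the integral
fraction flipped (IFP), the scalar activity readout in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import OptimizeWarning, curve_fit

T_MAX = 720.0
#: observation grid: 5 min is the smallest spacing between two samples
IMPUTE_STEP = 5.0

__all__ = [
    "T_MAX",
    "IMPUTE_STEP",
    "FlippingProfile",
    "KineticFit",
    "SummaryStatistic",
    "generalized_logistic",
    "exponential_rise",
    "fit_profile",
    "impute",
    "ifp",
    "ifp_trz",
]


def generalized_logistic(t, L, k, t0, nu):
    """Richards curve L / (1 + exp(-k (t - t0)))**nu.

    Non-decreasing for k >= 0, nu > 0; bounded by L.
    """
    t = np.asarray(t, dtype=float)
    z = np.clip(-k * (t - t0), -500.0, 500.0)
    # L * (1 + exp(z))**-nu evaluated in log space for stability
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    return L * np.exp(np.clip(-nu * softplus, -700.0, 700.0))


def exponential_rise(t, a, b):
    """Saturating exponential a (1 - exp(-b t)); the fallback family."""
    t = np.asarray(t, dtype=float)
    return a * (1.0 - np.exp(-np.clip(b, 0.0, None) * t))


@dataclass(frozen=True)
class FlippingProfile:
    """Observed fraction-flipped time series for one variant."""

    times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fractions must be 1-D and aligned")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > T_MAX):
            raise ValueError(
                f"times must be strictly increasing within [0, {T_MAX:g}]"
            )
        if np.any((f < -1e-9) | (f > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", np.clip(f, 0.0, 1.0))


@dataclass
class KineticFit:
    """Parametric fit of a flipping profile.

    ``family`` is ``"generalized_logistic"`` (params L, k, t0, nu) or
    ``"exponential_rise"`` (params a, b).  ``diagnostics`` records the
    residual RMSE and whether the primary (logistic) optimization converged.
    """

    family: str
    params: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def predict(self, t):
        if self.family == "generalized_logistic":
            return np.clip(generalized_logistic(t, *self.params), 0.0, 1.0)
        if self.family == "exponential_rise":
            return np.clip(exponential_rise(t, *self.params), 0.0, 1.0)
        raise ValueError(f"unknown curve family {self.family!r}")


@dataclass(frozen=True)
class SummaryStatistic:
    """Normalized integral of a flipping curve over a time window."""

    name: str
    window: tuple[float, float]
    value: float

    def __post_init__(self):
        if not -1e-9 <= self.value <= 1 + 1e-9:
            raise ValueError("normalized integral must lie in [0, 1]")
        object.__setattr__(self, "value", float(np.clip(self.value, 0.0, 1.0)))


def _logistic_inits(t, f):
    """Multi-start initial guesses for the Richards fit."""
    L0 = max(float(f.max()), 1e-3)
    half = L0 / 2.0
    above = np.nonzero(f >= half)[0]
    t0 = float(t[above[0]]) if above.size else float(t[-1])
    return [(L0, k0, t0, 1.0) for k0 in (0.005, 0.02, 0.08)]


def _in_bounds(params):
    L, k, t0, nu = params
    return 0.0 <= L <= 1.0 + 1e-6 and k >= 0.0 and nu > 0.0


def fit_profile(profile: FlippingProfile) -> KineticFit:
    """Fit a profile with the Richards family, falling back to exponential.

    The logistic optimization is unconstrained; it counts as failed when the
    optimizer does not converge from any start or when the solution leaves
    the admissible region (L in [0, 1], k >= 0, nu > 0), in which case the
    bounded exponential-rise family is fitted instead.  Requires at least 3
    observations.
    """
    t, f = profile.times, profile.fractions
    if t.size < 3:
        raise ValueError("need at least 3 observations to fit a profile")

    # degenerate flat profile: the logistic family represents a constant
    # exactly in its saturated limit; return that closed form directly
    if f.max() - f.min() < 1e-9:
        c = float(f.mean())
        params = np.array([c, 1.0, -50.0, 1.0])
        return KineticFit(
            "generalized_logistic",
            params,
            {"rmse": 0.0, "logistic_converged": True, "degenerate_flat": True},
        )

    best = None
    for p0 in _logistic_inits(t, f):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    generalized_logistic, t, f, p0=p0, method="lm",
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = generalized_logistic(t, *popt) - f
        rmse = float(np.sqrt(np.mean(resid**2)))
        if _in_bounds(popt) and (best is None or rmse < best[1]):
            best = (popt, rmse)
    if best is not None:
        popt, rmse = best
        return KineticFit(
            "generalized_logistic",
            np.asarray(popt, dtype=float),
            {"rmse": rmse, "logistic_converged": True},
        )

    # fallback: bounded saturating exponential
    a0 = float(np.clip(f[-1], 1e-3, 1.0))
    try:
        popt, _ = curve_fit(
            exponential_rise,
            t,
            f,
            p0=(a0, 0.005),
            bounds=([0.0, 0.0], [1.0, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        popt = np.array([float(np.mean(f)), 0.0])
    resid = exponential_rise(t, *popt) - f
    return KineticFit(
        "exponential_rise",
        np.asarray(popt, dtype=float),
        {
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "logistic_converged": False,
        },
    )


def impute(fit: KineticFit, step: float = IMPUTE_STEP) -> FlippingProfile:
    """Evaluate a fitted curve on the dense grid {0, step, ..., 720}."""
    if step <= 0 or T_MAX % step:
        raise ValueError(f"step must be positive and divide {T_MAX:g}")
    times = np.arange(0.0, T_MAX + step / 2, step)
    return FlippingProfile(times, np.clip(fit.predict(times), 0.0, 1.0))


def ifp(fit: KineticFit, t_start: float = 0.0, t_end: float = 480.0) -> SummaryStatistic:
    """Normalized integral of the fitted curve over [t_start, t_end]."""
    if not 0.0 <= t_start < t_end <= T_MAX:
        raise ValueError(f"window must satisfy 0 <= t_start < t_end <= {T_MAX:g}")
    val, _ = quad(lambda t: float(fit.predict(t)), t_start, t_end,
                  epsabs=1e-6, limit=200)
    return SummaryStatistic("IFP_window", (t_start, t_end), val / (t_end - t_start))


def ifp_trz(profile: FlippingProfile,
            window: tuple[float, float] = (0.0, 480.0)) -> SummaryStatistic:
    """Trapezoidal-rule integral of the raw profile, normalized by window.

    Window endpoints not among the observed times are linearly interpolated;
    a window extending beyond the observations is rejected.
    """
    t0, t1 = window
    t, f = profile.times, profile.fractions
    if t.size < 2:
        raise ValueError("need at least 2 points to integrate")
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9 or t0 >= t1:
        raise ValueError("window must lie within the observed time range")
    inner = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inner], [t1]))
    ff = np.interp(tt, t, f)
    val = float(np.trapezoid(ff, tt)) / (t1 - t0)
    return SummaryStatistic("IFP_trz", (t0, t1), val)
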