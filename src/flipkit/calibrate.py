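"""Internal standards, cross-replicate normalization, and calibration.

A small panel of internal-standard RBSs (selected as k-medoid
representatives of the library's kinetic behaviors) anchors two analyses:

* cross-replicate normalization with the one-parameter quadratic family
  f(x) = A x + (1 - A) x**2, the degree-two polynomial pinned by
  f(0) = 0 and f(1) = 1; monotonicity on [0, 1] bounds the free
  parameter to 0 <= A <= 2.  Either the forward map or its inverse is
  fitted, whichever gives the lower mean-squared error on the standards.
* calibration of the DNA-recorded flipping readout against fluorescence:
  integral summaries of flipping profiles are paired with slope summaries
  of fluorescence curves over candidate time windows, fitted with linear,
  log-linear or logistic links, and ranked by leave-one-out R^2; the
  diversity of each flipping summary is scored by differential entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar
from scipy.special import digamma

from .kinetics import FlippingProfile, ifp_trz

__all__ = [
    "A_MIN",
    "A_MAX",
    "ReplicateMap",
    "CalibrationFit",
    "admissible_A_bounds",
    "k_medoids",
    "select_standards",
    "quadratic_map",
    "fit_replicate_map",
    "apply_map",
    "differential_entropy_knn",
    "fluorescence_slope",
    "evaluate_summary_pairs",
]

# monotonicity of f(x) = A x + (1 - A) x^2 on [0, 1]: f'(x) = A + 2(1-A)x
# is linear in x, so it suffices that f'(0) = A >= 0 and f'(1) = 2 - A >= 0
A_MIN, A_MAX = 0.0, 2.0


def admissible_A_bounds() -> tuple[float, float]:
    """Derive the admissible range of A from the monotonicity constraint.

    f'(x) = A + 2 (1 - A) x is affine in x, so f' >= 0 on [0, 1] holds
    iff it holds at both endpoints.  Each endpoint condition is linear in
    A; the bounds are the roots of the two endpoint derivatives.
    """
    # f'(0) = A            -> root at A = 0  (lower bound)
    # f'(1) = 2 - A        -> root at A = 2  (upper bound)
    lower = float(np.roots([1.0, 0.0])[0])       # A = 0
    upper = float(np.roots([-1.0, 2.0])[0])      # 2 - A = 0
    # sanity: the derivative is non-negative at both endpoints inside the
    # bounds and violated just outside
    for A, ok in ((lower, True), (upper, True),
                  (lower - 1e-6, False), (upper + 1e-6, False)):
        fp = min(A, 2.0 - A)
        assert (fp >= -1e-12) == ok
    return lower, upper


@dataclass
class ReplicateMap:
    """Fitted normalization map between two replicates."""

    A: float
    direction: str            # "forward" or "inverse"
    fit_mse: float

    def __post_init__(self):
        if not A_MIN <= self.A <= A_MAX:
            raise ValueError(f"A must lie in [{A_MIN:g}, {A_MAX:g}]")
        if self.direction not in ("forward", "inverse"):
            raise ValueError("direction must be 'forward' or 'inverse'")


@dataclass
class CalibrationFit:
    """One scored (flipping summary, fluorescence summary, link) triple."""

    flipping_window: tuple
    fluorescence_window: tuple
    fit_family: str
    params: np.ndarray
    R2: float
    R2_v: float
    entropy: float
    n_standards: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# internal standards
# ---------------------------------------------------------------------------

def k_medoids(X: np.ndarray, k: int, seed: int = 0,
              max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Plain alternating k-medoids (Euclidean) on row vectors.

    Returns (medoid_indices, labels).  Medoids are actual data rows.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n profiles")
    D = np.sqrt(
        np.maximum(
            (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2 * X @ X.T,
            0.0,
        )
    )
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            medoids = new
            break
        medoids = new
    labels = np.argmin(D[:, medoids], axis=1)
    return medoids, labels


def select_standards(profiles: np.ndarray, k: int = 25,
                     seed: int = 0) -> np.ndarray:
    """Indices of k representative profiles (cluster medoids).

    ``profiles`` is (n, m), kinetic profiles on a common (5-min) grid,
    already cropped at 720 min and quality-filtered by the caller.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < k:
        raise ValueError(
            f"need at least k={k} profiles, got {profiles.shape[0]}"
        )
    medoids, _ = k_medoids(profiles, k, seed=seed)
    return np.sort(medoids)


# ---------------------------------------------------------------------------
# replicate normalization
# ---------------------------------------------------------------------------

def quadratic_map(x, A: float):
    """f(x) = A x + (1 - A) x**2; satisfies f(0) = 0 and f(1) = 1."""
    x = np.asarray(x, dtype=float)
    return A * x + (1.0 - A) * x**2


def _inverse_quadratic(y, A: float):
    """Monotone inverse of the quadratic map on [0, 1]."""
    y = np.asarray(y, dtype=float)
    if abs(1.0 - A) < 1e-12:
        return y.copy()
    disc = A**2 + 4.0 * (1.0 - A) * y
    return (-A + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * (1.0 - A))


def fit_replicate_map(x, y) -> ReplicateMap:
    """Optimize A in [0, 2] for both map directions, keep the lower MSE.

    ``x`` are IFP values of the replicate to normalize, ``y`` of the
    reference replicate; both must lie in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x < 0) | (x > 1) | (y < 0) | (y > 1)):
        raise ValueError("summary pairs must lie in [0, 1]")

    def mse(A, func):
        return float(np.mean((func(x, A) - y) ** 2))

    best = None
    for direction, func in (
        ("forward", quadratic_map),
        ("inverse", _inverse_quadratic),
    ):
        res = minimize_scalar(
            mse, bounds=(A_MIN, A_MAX), args=(func,), method="bounded",
            options={"xatol": 1e-9},
        )
        cand = ReplicateMap(float(res.x), direction, float(res.fun))
        if best is None or cand.fit_mse < best.fit_mse:
            best = cand
    return best


def apply_map(rep_map: ReplicateMap, values):
    """Normalize values onto the reference replicate's scale."""
    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("values must lie in [0, 1]")
    if rep_map.direction == "forward":
        out = quadratic_map(values, rep_map.A)
    else:
        out = _inverse_quadratic(values, rep_map.A)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# differential entropy and calibration
# ---------------------------------------------------------------------------

def differential_entropy_knn(samples, k: int = 1) -> float:
    """Kozachenko-Leonenko nearest-neighbor entropy estimate (nats, 1-D)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < k + 1:
        raise ValueError("need more samples than neighbors")
    # distance to the k-th nearest neighbor via the sorted order
    eps = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - k), min(n - 1, i + k)
        d = np.abs(x[lo:hi + 1] - x[i])
        eps[i] = np.sort(d)[k]
    eps = np.maximum(eps, 1e-300)
    return float(digamma(n) - digamma(k) + np.mean(np.log(2.0 * eps)))


def fluorescence_slope(times, values, window) -> float:
    """OLS slope of a fluorescence curve over the window."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = (times >= window[0]) & (times <= window[1])
    if sel.sum() < 2:
        raise ValueError("window must contain at least 2 fluorescence points")
    return float(np.polyfit(times[sel], values[sel], 1)[0])


def _fit_family(x, y, family):
    """Fit one link family; returns (params, predict)."""
    if family == "linear":
        p = np.polyfit(x, y, 1)
        return p, lambda v: np.polyval(p, v)
    if family == "log_linear":
        lx = np.log(np.asarray(x) + 1e-6)
        p = np.polyfit(lx, y, 1)
        return p, lambda v: np.polyval(p, np.log(np.asarray(v) + 1e-6))

    def logistic(v, c, k, x0):
        return c / (1.0 + np.exp(-np.clip(k * (np.asarray(v) - x0),
                                          -500, 500)))

    if family == "generalized_logistic":
        span = max(y.max() - y.min(), 1e-9)
        p0 = (float(y.max()), 4.0 / max(x.max() - x.min(), 1e-9),
              float(np.median(x)))
        p, _ = curve_fit(logistic, x, y, p0=p0, maxfev=20000)
        return p, lambda v: logistic(v, *p)
    raise ValueError(f"unknown fit family {family!r}")


def _r2(y, yhat):
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def _loo_r2(x, y, family):
    n = x.size
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        try:
            _, predict = _fit_family(x[mask], y[mask], family)
            preds[i] = predict(x[i])
        except (RuntimeError, ValueError):
            preds[i] = np.nan
    if np.any(~np.isfinite(preds)):
        return -np.inf
    return _r2(y, preds)


def evaluate_summary_pairs(
    flipping_profiles: list[FlippingProfile],
    fluorescence_curves: list[tuple],
    flipping_windows: list[tuple],
    fluorescence_windows: list[tuple],
    families: tuple = ("linear", "log_linear", "generalized_logistic"),
) -> list[CalibrationFit]:
    """Score every (flipping window x fluorescence window x link family).

    Flipping summaries are trapezoidal integrals of the profiles; the
    fluorescence summary is the OLS slope over its window.  Combinations
    are ranked by leave-one-out R^2 (descending); each fit also reports
    the differential entropy of the flipping-summary sample as a
    diversity score.  A degenerate (constant) fluorescence summary is
    flagged rather than rejected.
    """
    if len(flipping_profiles) != len(fluorescence_curves):
        raise ValueError("need matched flipping and fluorescence standards")
    results = []
    for fw in flipping_windows:
        x = np.array([ifp_trz(p, fw).value for p in flipping_profiles])
        entropy = differential_entropy_knn(x)
        for gw in fluorescence_windows:
            y = np.array(
                [fluorescence_slope(t, v, gw) for t, v in fluorescence_curves]
            )
            degenerate = bool(np.ptp(y) < 1e-12)
            for family in families:
                try:
                    params, predict = _fit_family(x, y, family)
                    r2 = _r2(y, predict(x))
                    r2v = _loo_r2(x, y, family)
                except (RuntimeError, ValueError):
                    continue
                results.append(
                    CalibrationFit(
                        flipping_window=tuple(fw),
                        fluorescence_window=tuple(gw),
                        fit_family=family,
                        params=np.asarray(params, dtype=float),
                        R2=r2,
                        R2_v=r2v,
                        entropy=entropy,
                        n_standards=x.size,
                        degenerate=degenerate,
                    )
                )
    results.sort(key=lambda c: -c.R2_v)
    return results
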