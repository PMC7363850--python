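"""Sampling-schedule optimization and NGS-loading simulation.

The schedule optimizer greedily selects sampling times from the candidate
grid T = {0, 5, ..., 720} min so that piecewise-linear interpolation of
each (imputed) flipping profile at the selected times reconstructs the
dense profile with minimal cumulative absolute error.  The first and last
samples are fixed at 0 and 720 min.  Optimization can be restricted to
the strongest profiles (strength = last-minus-first observed fraction) to
counter the weak-variant skew of fully randomized libraries.

The loading simulation estimates how many variants survive a minimal
read-count threshold when per-variant coverage is reduced (binomial
thinning by 1/r_c) and sampling times are reduced (factor r_t), assuming
total valid NGS reads are the fixed resource.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import IMPUTE_STEP, T_MAX

__all__ = [
    "time_grid",
    "SamplingSchedule",
    "ScheduleEvaluation",
    "LoadingScenario",
    "greedy_select",
    "evaluate_schedule",
    "simulate_loading",
]


def time_grid(step: float = IMPUTE_STEP) -> np.ndarray:
    return np.arange(0.0, T_MAX + step / 2, step)


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered subset of the candidate grid, always containing 0 and 720."""

    times: tuple

    def __post_init__(self):
        t = tuple(float(x) for x in self.times)
        if sorted(set(t)) != list(t):
            raise ValueError("schedule times must be sorted and unique")
        if t[0] != 0.0 or t[-1] != T_MAX:
            raise ValueError(f"schedule must contain 0 and {T_MAX:g}")
        object.__setattr__(self, "times", t)


@dataclass
class ScheduleEvaluation:
    """Per-profile approximation error and its box-plot summary."""

    errors: np.ndarray
    quartiles: tuple          # (q1, median, q3)
    whiskers: tuple           # (low, high) at 1.5 IQR
    outliers: np.ndarray


@dataclass
class LoadingScenario:
    theta: int
    r_c: float
    r_t: float
    n_total: int
    n_simul: int
    n_input: float
    n_output: float


def _interp_matrix(grid: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """W (|grid| x |knots|) with (W @ v) the piecewise-linear interpolation
    of knot values v evaluated on the grid."""
    W = np.zeros((grid.size, knots.size))
    j = np.clip(np.searchsorted(knots, grid, side="right") - 1, 0,
                knots.size - 2)
    span = knots[j + 1] - knots[j]
    w = (grid - knots[j]) / span
    rows = np.arange(grid.size)
    W[rows, j] = 1.0 - w
    W[rows, j + 1] = w
    return W


def _reconstruction_error(profiles, grid, knot_idx) -> float:
    """Summed (1/|T|) sum_t |p - l| over profiles for knots at knot_idx."""
    knots = grid[knot_idx]
    W = _interp_matrix(grid, knots)
    recon = profiles[:, knot_idx] @ W.T
    return float(np.abs(profiles - recon).sum() / grid.size)


def rank_by_strength(profiles: np.ndarray, ids=None) -> np.ndarray:
    """Indices sorted by strength (last minus first value), strongest
    first; ties broken by id (lexicographic) or by index."""
    strength = profiles[:, -1] - profiles[:, 0]
    if ids is None:
        keys = np.arange(profiles.shape[0])
    else:
        keys = np.argsort(np.argsort(ids, kind="stable"))
    order = np.lexsort((keys, -strength))
    return order


def greedy_select(
    imputed_profiles: np.ndarray,
    n_points: int,
    subset_fraction: float = 1.0,
    grid: np.ndarray | None = None,
    ids=None,
) -> SamplingSchedule:
    """Greedy schedule construction.

    Starting from S = {0, 720}, repeatedly add the candidate time s* that
    minimizes the cumulative reconstruction error, over the strongest
    ``subset_fraction`` of profiles; ties go to the earliest candidate.
    ``imputed_profiles`` is (n_profiles, |grid|) on the 5-min grid.
    """
    grid = time_grid() if grid is None else np.asarray(grid, dtype=float)
    P = np.asarray(imputed_profiles, dtype=float)
    if P.ndim != 2 or P.shape[1] != grid.size:
        raise ValueError("profiles must be (n, |grid|) on the candidate grid")
    if not 2 <= n_points <= grid.size:
        raise ValueError(f"n_points must be in [2, {grid.size}]")
    if not 0 < subset_fraction <= 1:
        raise ValueError("subset_fraction must be in (0, 1]")
    n_top = max(1, int(round(subset_fraction * P.shape[0])))
    P = P[rank_by_strength(P, ids)[:n_top]]

    selected = [0, grid.size - 1]
    while len(selected) < n_points:
        best_s, best_err = None, np.inf
        for s in range(grid.size):
            if s in selected:
                continue
            knot_idx = np.array(sorted(selected + [s]))
            err = _reconstruction_error(P, grid, knot_idx)
            if err < best_err - 1e-12:
                best_s, best_err = s, err
        selected.append(best_s)
        selected.sort()
    return SamplingSchedule(tuple(grid[selected]))


def evaluate_schedule(
    raw_profiles: np.ndarray,
    schedule: SamplingSchedule,
    grid: np.ndarray | None = None,
) -> ScheduleEvaluation:
    """Approximation error r_i = (1/|T|) sum_t |p_t - l_t| per profile,
    plus a box-plot summary (quartiles, 1.5-IQR whiskers, outliers)."""
    grid = time_grid() if grid is None else np.asarray(grid, dtype=float)
    P = np.asarray(raw_profiles, dtype=float)
    knots = np.asarray(schedule.times)
    knot_idx = np.searchsorted(grid, knots)
    if not np.allclose(grid[knot_idx], knots):
        raise ValueError("schedule times must lie on the candidate grid")
    W = _interp_matrix(grid, knots)
    recon = P[:, knot_idx] @ W.T
    errors = np.abs(P - recon).mean(axis=1)
    q1, med, q3 = np.percentile(errors, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = errors[(errors >= lo) & (errors <= hi)]
    whiskers = (
        float(inside.min()) if inside.size else float(q1),
        float(inside.max()) if inside.size else float(q3),
    )
    outliers = errors[(errors < lo) | (errors > hi)]
    return ScheduleEvaluation(errors, (q1, med, q3), whiskers, outliers)


def simulate_loading(
    read_counts: np.ndarray,
    theta: int,
    r_c: float,
    r_t: float,
    seed: int = 0,
) -> LoadingScenario:
    """Binomial downsampling of per-variant, per-time read counts.

    Each count is thinned with probability 1/r_c; n_simul counts the
    variants still meeting >= theta reads at every time point, and the
    projected library sizes scale by r_c * r_t (fixed total valid reads).
    """
    counts = np.asarray(read_counts)
    if counts.ndim != 2:
        raise ValueError("read_counts must be (n_variants, n_times)")
    if r_c < 1 or r_t < 1:
        raise ValueError("reduction factors must be >= 1")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(counts, 1.0 / r_c) if r_c > 1 else counts
    n_total = counts.shape[0]
    n_simul = int(np.sum(np.all(thinned >= theta, axis=1)))
    return LoadingScenario(
        theta=theta,
        r_c=r_c,
        r_t=r_t,
        n_total=n_total,
        n_simul=n_simul,
        n_input=n_total * r_c * r_t,
        n_output=n_simul * r_c * r_t,
    )
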