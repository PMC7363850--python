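"""Degenerate RBS library design.

Two routes to a degenerate (IUPAC) sequence enriched for a target
activity range:

* PPM matching: bin a characterized library into 10 linear activity bins,
  compute a position probability matrix (PPM) per bin, and pick, per
  position, the IUPAC code whose implied uniform base distribution has
  minimal mean-squared error to the target bin's column.
* Genetic algorithm + KS matching: hill-climb a pool of sequences under a
  scorer (accepting only score-increasing 1-2 point mutations), then
  greedily edit a degenerate candidate one position at a time to minimize
  the two-sample Kolmogorov-Smirnov distance between the score
  distribution sampled from the candidate and that of the evolved pool.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ks_2samp

from .synthdata import IUPAC

__all__ = [
    "BASES",
    "ppm_from_sequences",
    "validate_ppm",
    "bin_by_activity",
    "design_degenerate_from_ppm",
    "implied_ppm",
    "sample_from_degenerate",
    "genetic_evolve",
    "design_degenerate_ks",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: IUPAC codes ordered by base-set size then alphabetically -- the
#: tie-break order for degenerate design
_CODES_BY_SIZE = sorted(IUPAC, key=lambda c: (len(IUPAC[c]), c))


def validate_ppm(ppm: np.ndarray) -> np.ndarray:
    ppm = np.asarray(ppm, dtype=float)
    if ppm.ndim != 2 or ppm.shape[1] != 4:
        raise ValueError("PPM must be (n_positions, 4)")
    if np.any((ppm < -1e-9) | (ppm > 1 + 1e-9)):
        raise ValueError("PPM entries must lie in [0, 1]")
    if np.any(np.abs(ppm.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each PPM position must sum to 1")
    return ppm


def ppm_from_sequences(sequences: list[str]) -> np.ndarray:
    """Per-position nucleotide frequencies of a sequence set."""
    if not sequences:
        raise ValueError("need at least one sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must share one length")
    mat = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    mat = mat.reshape(len(sequences), L)
    ppm = np.empty((L, 4))
    for i, b in enumerate(BASES):
        ppm[:, i] = (mat == ord(b)).mean(axis=0)
    return validate_ppm(ppm)


def bin_by_activity(sequences: list[str], activities,
                    n_bins: int = 10) -> dict[int, np.ndarray]:
    """Per-bin PPMs over linear activity bins of [0, 1].

    Bin b (1-based) covers [(b-1)/n, b/n), with the last bin closed at 1.
    Empty bins are omitted (with a warning via the returned dict simply
    lacking the key).
    """
    act = np.asarray(activities, dtype=float)
    if np.any((act < 0) | (act > 1)):
        raise ValueError("activities must lie in [0, 1]")
    if len(sequences) != act.size:
        raise ValueError("sequences and activities must align")
    idx = np.minimum((act * n_bins).astype(int), n_bins - 1) + 1
    out = {}
    for b in range(1, n_bins + 1):
        members = [s for s, i in zip(sequences, idx) if i == b]
        if members:
            out[b] = ppm_from_sequences(members)
    return out


def implied_ppm(design: str) -> np.ndarray:
    """The PPM a degenerate sequence implies: uniform over each symbol's
    base set."""
    ppm = np.zeros((len(design), 4))
    for p, sym in enumerate(design.upper()):
        bases = IUPAC.get(sym)
        if bases is None:
            raise ValueError(f"non-IUPAC symbol {sym!r} at position {p}")
        for b in bases:
            ppm[p, _BASE_IDX[b]] = 1.0 / len(bases)
    return ppm


def _code_column(code: str) -> np.ndarray:
    col = np.zeros(4)
    for b in IUPAC[code]:
        col[_BASE_IDX[b]] = 1.0 / len(IUPAC[code])
    return col


_CODE_COLUMNS = {c: _code_column(c) for c in _CODES_BY_SIZE}


def design_degenerate_from_ppm(target: np.ndarray) -> str:
    """IUPAC string minimizing per-position MSE to the target PPM.

    Positions are designed independently (the MSE objective decomposes
    positionwise); ties prefer the smaller base set, then alphabetical.
    """
    target = validate_ppm(target)
    out = []
    for col in target:
        best_code, best_mse = None, np.inf
        for code in _CODES_BY_SIZE:      # size-then-alphabetical tie order
            mse = float(np.mean((_CODE_COLUMNS[code] - col) ** 2))
            if mse < best_mse - 1e-15:
                best_code, best_mse = code, mse
        out.append(best_code)
    return "".join(out)


def sample_from_degenerate(design: str, n: int,
                           rng: np.random.Generator) -> list[str]:
    """Sample sequences positionwise-uniformly from a degenerate string."""
    cols = [IUPAC[sym] for sym in design.upper()]
    draws = [rng.integers(len(c), size=n) for c in cols]
    return [
        "".join(cols[p][draws[p][i]] for p in range(len(cols)))
        for i in range(n)
    ]


def genetic_evolve(
    seed_pool: list[str],
    scorer,
    n_iter: int = 200,
    muts_per_iter: tuple = (1, 2),
    seed: int = 0,
) -> list[str]:
    """Independent per-sequence hill climbing.

    Each iteration proposes 1-2 random substitutions per sequence and
    keeps the mutant only when the score strictly increases.  ``scorer``
    maps a list of sequences to an array of predicted activities.
    """
    rng = np.random.default_rng(seed)
    pool = list(seed_pool)
    if not pool:
        return pool
    L = len(pool[0])
    scores = np.asarray(scorer(pool), dtype=float)
    lo, hi = muts_per_iter
    for _ in range(n_iter):
        proposals = []
        for s in pool:
            m = int(rng.integers(lo, hi + 1))
            pos = rng.choice(L, size=m, replace=False)
            arr = list(s)
            for p in pos:
                arr[p] = BASES[
                    (_BASE_IDX[arr[p]] + 1 + int(rng.integers(3))) % 4
                ]
            proposals.append("".join(arr))
        new_scores = np.asarray(scorer(proposals), dtype=float)
        accept = new_scores > scores
        pool = [p if a else s for s, p, a in zip(pool, proposals, accept)]
        scores = np.where(accept, new_scores, scores)
    return pool


def design_degenerate_ks(
    evolved_pool: list[str],
    scorer,
    n_sample: int = 20000,
    n_eval: int = 2000,
    seed: int = 0,
    max_rounds: int = 50,
) -> str:
    """Greedy KS-distance matching of a degenerate sequence to a pool.

    The reference score distribution comes from ``n_sample`` sequences
    drawn from the evolved pool's PPM.  Starting from the PPM-matched
    degenerate sequence, single-position IUPAC edits are accepted while
    they reduce the two-sample KS statistic against the reference; each
    greedy round reuses one evaluation seed so candidate comparisons are
    paired.  Positions are scanned left to right; the incumbent is kept
    on equality.
    """
    if not evolved_pool:
        raise ValueError("evolved pool must be non-empty")
    rng = np.random.default_rng(seed)
    ppm = ppm_from_sequences(evolved_pool)
    # reference sample: draw positionwise from the pool PPM itself
    ref_seqs = _sample_from_ppm(ppm, n_sample, rng)
    ref_scores = np.asarray(scorer(ref_seqs), dtype=float)

    candidate = design_degenerate_from_ppm(ppm)
    L = len(candidate)

    def ks_of(design, eval_seed):
        r = np.random.default_rng(eval_seed)
        seqs = sample_from_degenerate(design, n_eval, r)
        return float(ks_2samp(ref_scores, scorer(seqs)).statistic)

    for round_i in range(max_rounds):
        eval_seed = int(rng.integers(2**31 - 1))
        best_ks = ks_of(candidate, eval_seed)
        improved = False
        for p in range(L):
            for code in _CODES_BY_SIZE:
                if code == candidate[p]:
                    continue
                cand = candidate[:p] + code + candidate[p + 1:]
                ks = ks_of(cand, eval_seed)
                if ks < best_ks - 1e-12:
                    candidate, best_ks, improved = cand, ks, True
        if not improved:
            break
    return candidate


def _sample_from_ppm(ppm: np.ndarray, n: int,
                     rng: np.random.Generator) -> list[str]:
    cum = np.cumsum(ppm, axis=1)
    u = rng.random((n, ppm.shape[0]))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    idx = np.minimum(idx, 3)
    return ["".join(BASES[i] for i in row) for row in idx]
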