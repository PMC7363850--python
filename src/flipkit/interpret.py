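"""Data- and model-interpretation suite.

Positional motif statistics on the fully degenerate sub-library
(Shine-Dalgarno-like motifs and alternative start codons), correlation
profiling and clustering of first-layer convolutional filters,
integrated-gradients attribution with an all-zeros one-hot baseline,
k-means clustering of attribution profiles with medoid summaries, and
greedy in silico sequence evolution under a predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "START_CODONS",
    "MotifEffectReport",
    "AttributionMatrix",
    "EvolutionTrace",
    "motif_effect",
    "start_codon_effect",
    "filter_correlations",
    "integrated_gradients",
    "cluster_attributions",
    "in_silico_evolve",
    "mutation_neighbors",
]

START_CODONS = ("ATG", "GTG", "TTG")
_BASES = "ACGT"
RBS_LEN = 17


@dataclass
class MotifEffectReport:
    """IFP statistics of the sequences carrying a motif at one anchor.

    ``position`` is the anchor in -17..-1 coordinates (position -1 is
    adjacent to the A of the downstream start codon).
    """

    motif: str
    position: int
    group_size: int
    median: float
    q25: float
    q75: float
    p20: float
    p80: float
    overall_median: float
    in_frame: bool | None = None


@dataclass
class AttributionMatrix:
    """Signed per-position, per-base contributions to the prediction."""

    scores: np.ndarray            # (17, 4)
    prediction: float
    baseline_prediction: float

    @property
    def completeness_residual(self) -> float:
        return float(
            abs(self.scores.sum()
                - (self.prediction - self.baseline_prediction))
        )


@dataclass
class EvolutionTrace:
    """Greedy mutation trajectory under a predictor."""

    rounds: list                  # (sequence, score, mutated_positions)
    direction: str

    @property
    def sequences(self):
        return [r[0] for r in self.rounds]

    @property
    def scores(self):
        return np.array([r[1] for r in self.rounds])


def _anchor_index(position: int, motif_len: int) -> int:
    """Map a -17..-1 anchor to a 0-based index; validate bounds."""
    if position > -motif_len or position < -RBS_LEN:
        raise ValueError(
            f"motif of length {motif_len} cannot sit at position {position}"
        )
    return RBS_LEN + position


def _has_other_start(seq: str, anchor: int | None) -> bool:
    """True if the sequence carries a start codon at any anchor other than
    the queried one."""
    for off in range(RBS_LEN - 2):
        if off == anchor:
            continue
        if seq[off:off + 3] in START_CODONS:
            return True
    return False


def motif_effect(sequences, values, motif: str,
                 position: int) -> MotifEffectReport | None:
    """IFP statistics for sequences carrying ``motif`` at ``position``.

    Sequences containing a start codon anywhere (other than a queried
    start-codon anchor, see :func:`start_codon_effect`) are excluded so
    spurious translation starts do not confound the motif's effect.
    Returns None when the group is empty.
    """
    values = np.asarray(values, dtype=float)
    idx = _anchor_index(position, len(motif))
    sel = [
        i for i, s in enumerate(sequences)
        if s[idx:idx + len(motif)] == motif and not _has_other_start(s, None)
    ]
    return _report(sequences, values, motif, position, sel)


def start_codon_effect(sequences, values, codon: str,
                       position: int) -> MotifEffectReport | None:
    """As :func:`motif_effect` for an alternative start codon; sequences
    with a start codon at any other anchor are excluded, and the report
    carries an in-frame flag (anchor a multiple of 3 upstream of the
    native start codon)."""
    if codon not in START_CODONS:
        raise ValueError(f"codon must be one of {START_CODONS}")
    values = np.asarray(values, dtype=float)
    idx = _anchor_index(position, 3)
    sel = [
        i for i, s in enumerate(sequences)
        if s[idx:idx + 3] == codon and not _has_other_start(s, idx)
    ]
    rep = _report(sequences, values, codon, position, sel)
    if rep is not None:
        rep.in_frame = position % 3 == 0
    return rep


def _report(sequences, values, motif, position, sel):
    if not sel:
        return None
    grp = values[sel]
    q25, med, q75 = np.percentile(grp, [25, 50, 75])
    p20, p80 = np.percentile(grp, [20, 80])
    return MotifEffectReport(
        motif=motif,
        position=position,
        group_size=len(sel),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        p20=float(p20),
        p80=float(p80),
        overall_median=float(np.median(values)),
    )


def filter_correlations(
    net,
    X,
    y,
    n_clusters: int = 12,
    mode: str = "hamming",
    binarize_threshold: float = 0.05,
) -> dict:
    """Correlation profiles of first-layer filters, clustered.

    Each filter of the first convolutional layer is represented by the
    vector of Pearson correlations between its activation at each of the
    17 positions and the activity readout.  Profiles are clustered by
    complete linkage into ``n_clusters`` groups; in ``"hamming"`` mode
    (default) correlations are first sign-binarized at
    |r| > binarize_threshold (ternary -1/0/+1), in ``"euclidean"`` mode
    the raw vectors are used.  For each cluster the medoid filter's
    weight matrix (kernel x 4) is reported as its logo.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    acts = net.model.first_conv_activations(X)       # (n, L, F)
    n, L, F = acts.shape
    yc = y - y.mean()
    ysd = y.std()
    corr = np.zeros((F, L))
    zero_variance = np.zeros((F, L), dtype=bool)
    for pos in range(L):
        a = acts[:, pos, :]
        ac = a - a.mean(axis=0)
        sd = a.std(axis=0)
        dead = sd < 1e-12
        zero_variance[dead, pos] = True
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ac * yc[:, None]).mean(axis=0) / (sd * ysd)
        corr[:, pos] = np.where(dead | (ysd < 1e-12), 0.0, r)

    if mode == "hamming":
        feat = np.sign(corr) * (np.abs(corr) > binarize_threshold)
        dist = pdist(feat, metric="hamming")
    elif mode == "euclidean":
        feat = corr
        dist = pdist(feat, metric="euclidean")
    else:
        raise ValueError("mode must be 'hamming' or 'euclidean'")
    if F > 1:
        Z = linkage(dist, method="complete")
        labels = fcluster(Z, t=min(n_clusters, F), criterion="maxclust")
    else:
        labels = np.ones(1, dtype=int)

    weights = net.model.first_conv_weights()          # (k, 4, F)
    clusters = {}
    sq = squareform(dist) if F > 1 else np.zeros((1, 1))
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        within = sq[np.ix_(members, members)].sum(axis=1)
        medoid = int(members[np.argmin(within)])
        clusters[int(c)] = {
            "members": members,
            "medoid_filter": medoid,
            "medoid_logo": weights[:, :, medoid],
        }
    return {
        "correlations": corr,
        "zero_variance": zero_variance,
        "labels": labels,
        "clusters": clusters,
    }


def integrated_gradients(value_and_grad, x: np.ndarray,
                         baseline: np.ndarray | None = None,
                         steps: int = 64) -> AttributionMatrix:
    """Path-integral attribution from a baseline to the input.

    ``value_and_grad(batch)`` must return (values, gradients) of the
    scalar prediction for a batch of inputs.  The integral is a midpoint
    Riemann sum over ``steps`` points on the straight path, multiplied
    elementwise by (x - baseline).  The default baseline is the all-zeros
    one-hot array (a blank sequence).
    """
    if steps < 16:
        raise ValueError("need at least 16 integration steps")
    x = np.asarray(x, dtype=float)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline,
                                                             dtype=float)
    alphas = (np.arange(steps) + 0.5) / steps
    path = b[None] + alphas[:, None, None] * (x - b)[None]
    values, grads = value_and_grad(path)
    if not (np.all(np.isfinite(grads)) and np.all(np.isfinite(values))):
        raise FloatingPointError("non-finite gradients along the path")
    avg_grad = grads.mean(axis=0)
    scores = (x - b) * avg_grad
    fx, _ = value_and_grad(x[None])
    fb, _ = value_and_grad(b[None])
    return AttributionMatrix(
        scores=scores,
        prediction=float(np.asarray(fx).ravel()[0]),
        baseline_prediction=float(np.asarray(fb).ravel()[0]),
    )


def ensemble_value_and_grad(ensemble):
    """Adapter: ensemble mean prediction and its input gradient."""

    def fn(batch):
        batch = np.asarray(batch, dtype=float)
        mu = ensemble.predict_mu(batch)
        grad = ensemble.mean_input_gradient(batch)
        return mu, grad

    return fn


def cluster_attributions(attributions, sequences, k: int = 5,
                         seed: int = 0) -> list[dict]:
    """k-means over flattened attribution profiles; medoid summaries.

    Returns one record per cluster with the medoid (the pool member
    closest to the centroid; ties broken by dataset order), its sequence
    and attribution matrix.
    """
    from sklearn.cluster import KMeans

    A = np.asarray([np.asarray(a, dtype=float).ravel()
                    for a in attributions])
    if A.shape[0] < k:
        raise ValueError(f"pool of {A.shape[0]} is smaller than k={k}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(A)
    out = []
    for c in range(k):
        members = np.nonzero(km.labels_ == c)[0]
        d = np.linalg.norm(A[members] - km.cluster_centers_[c], axis=1)
        medoid = int(members[np.argmin(d)])   # argmin: first = dataset order
        out.append({
            "cluster": c,
            "members": members,
            "medoid_index": medoid,
            "medoid_sequence": sequences[medoid],
            "medoid_attribution": A[medoid].reshape(RBS_LEN, 4),
        })
    return out


def mutation_neighbors(seq: str, max_mutations: int = 2) -> list[str]:
    """All sequences within 1..max_mutations substitutions (distinct
    positions; for a 17-mer and 2 mutations: 51 + 1224 = 1275)."""
    out = []
    L = len(seq)
    for pos in range(L):
        for b in _BASES:
            if b != seq[pos]:
                out.append(seq[:pos] + b + seq[pos + 1:])
    if max_mutations >= 2:
        for p1, p2 in combinations(range(L), 2):
            for b1, b2 in product(_BASES, _BASES):
                if b1 != seq[p1] and b2 != seq[p2]:
                    out.append(
                        seq[:p1] + b1 + seq[p1 + 1:p2] + b2 + seq[p2 + 1:]
                    )
    return out


def in_silico_evolve(scorer, seq: str, direction: str = "maximize",
                     max_rounds: int = 200) -> EvolutionTrace:
    """Greedy evolution: evaluate all 1-2 substitution neighbors each
    round, accept the best strictly improving candidate, stop when none
    improves.  ``scorer`` maps a list of sequences to predicted values."""
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    sign = 1.0 if direction == "maximize" else -1.0
    current = seq
    score = float(np.asarray(scorer([seq]))[0])
    rounds = [(current, score, ())]
    for _ in range(max_rounds):
        neigh = mutation_neighbors(current)
        vals = np.asarray(scorer(neigh), dtype=float)
        best = int(np.argmax(sign * vals))
        if sign * vals[best] <= sign * score:
            break
        new = neigh[best]
        muts = tuple(
            i for i, (a, b) in enumerate(zip(current, new)) if a != b
        )
        current, score = new, float(vals[best])
        rounds.append((current, score, muts))
    return EvolutionTrace(rounds, direction)
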