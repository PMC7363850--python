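"""Sequence-to-activity prediction with a beta-likelihood ResNet ensemble.

One-hot encoded 17-nt RBS sequences are mapped to the two shape
parameters (alpha, beta) of a beta distribution over the activity
readout (IFP in (0, 1)); networks are trained by minimizing the beta
negative log-likelihood, a proper scoring rule.  An ensemble of M
hyperparameter configurations x K seeds yields, per sequence, a uniform
mixture of beta distributions whose mean is the predicted activity and
whose standard deviation is the uncertainty estimate (aleatoric spread
within members plus epistemic spread across members, by the law of total
variance).

Splits are stratified so that the proportion of strong sequences (the
top ``strong_percentile`` percent of the activity distribution) is
preserved across train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import betaln, digamma
from scipy.stats import beta as beta_dist

from .nn import Adam, BetaResNet

__all__ = [
    "one_hot_encode",
    "one_hot_decode",
    "beta_nll",
    "NetConfig",
    "SplitSpec",
    "stratified_split",
    "TrainedNet",
    "build_and_train",
    "Ensemble",
    "EnsemblePrediction",
    "train_ensemble",
    "ensemble_predict",
    "metrics",
    "mixture_quantile",
    "reliability_diagram",
    "threshold_sweep",
    "fit_baseline",
]

_BASE_ORDER = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASE_ORDER)}
_Y_EPS = 1e-6


def one_hot_encode(seq: str) -> np.ndarray:
    """17 x 4 binary matrix, channel order A, C, G, T, position -17 first."""
    if len(seq) != 17:
        raise ValueError("RBS sequences must be 17 nt")
    out = np.zeros((17, 4))
    for i, b in enumerate(seq.upper()):
        j = _BASE_IDX.get(b)
        if j is None:
            raise ValueError(f"invalid base {b!r} at position {i}")
        out[i, j] = 1.0
    return out


def one_hot_decode(mat: np.ndarray) -> str:
    return "".join(_BASE_ORDER[j] for j in np.argmax(mat, axis=1))


def encode_batch(seqs) -> np.ndarray:
    return np.stack([one_hot_encode(s) for s in seqs])


def beta_nll(y: float, alpha: float, beta: float) -> float:
    """Negative log beta density at y (y clamped to (eps, 1-eps))."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shape parameters must be positive")
    y = float(np.clip(y, _Y_EPS, 1.0 - _Y_EPS))
    return float(
        betaln(alpha, beta)
        - (alpha - 1.0) * np.log(y)
        - (beta - 1.0) * np.log1p(-y)
    )


def _batch_nll_and_grads(y, alpha, beta):
    y = np.clip(y, _Y_EPS, 1.0 - _Y_EPS)
    nll = betaln(alpha, beta) - (alpha - 1) * np.log(y) \
        - (beta - 1) * np.log1p(-y)
    dig_ab = digamma(alpha + beta)
    da = digamma(alpha) - dig_ab - np.log(y)
    db = digamma(beta) - dig_ab - np.log1p(-y)
    n = y.size
    return float(nll.mean()), da / n, db / n


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimizer settings of one ensemble member."""

    n_blocks: int = 3
    filters: int = 64
    kernel_sizes: tuple = (9, 1)
    fc_units: int = 64
    weight_decay: float = 1e-6
    learning_rate: float = 0.01
    batch_size: int = 128
    max_epochs: int = 60
    patience: int = 8
    seed: int = 0

    def __post_init__(self):
        if min(self.n_blocks, self.filters, self.fc_units,
               self.batch_size, *self.kernel_sizes) <= 0:
            raise ValueError("all architecture counts must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test index sets."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    strong_percentile: float = 15.0

    def __post_init__(self):
        sets = [set(self.train.tolist()), set(self.val.tolist()),
                set(self.test.tolist())]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("split index sets must be disjoint")


def stratified_split(y, fractions=(0.7, 0.15, 0.15), strong_percentile=15.0,
                     seed=0) -> SplitSpec:
    """Split preserving the proportion of strong sequences.

    Strong sequences are the top ``strong_percentile`` percent of the
    activity distribution.
    """
    y = np.asarray(y, dtype=float)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    cut = np.percentile(y, 100.0 - strong_percentile)
    strong = y >= cut
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for mask in (strong, ~strong):
        idx = np.nonzero(mask)[0]
        rng.shuffle(idx)
        n = idx.size
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        tr.append(idx[:n_tr])
        va.append(idx[n_tr:n_tr + n_va])
        te.append(idx[n_tr + n_va:])
    return SplitSpec(
        np.sort(np.concatenate(tr)),
        np.sort(np.concatenate(va)),
        np.sort(np.concatenate(te)),
        strong_percentile,
    )


def _r2(y, yhat):
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss == 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss


@dataclass
class TrainedNet:
    model: BetaResNet
    config: NetConfig
    history: list = field(default_factory=list)
    best_val_r2: float = -np.inf

    def predict_shapes(self, X, batch=1024):
        if X.shape[0] == 0:
            return np.empty(0), np.empty(0)
        alphas, betas = [], []
        for i in range(0, X.shape[0], batch):
            a, b = self.model.forward(X[i:i + batch], train=False)
            alphas.append(a)
            betas.append(b)
        return np.concatenate(alphas), np.concatenate(betas)

    def predict_mean(self, X):
        a, b = self.predict_shapes(X)
        return a / (a + b)


def _snapshot(model):
    return [p.value.copy() for p in model.params()]


def _restore(model, snap):
    for p, v in zip(model.params(), snap):
        p.value[...] = v


def build_and_train(X, y, config: NetConfig,
                    split: SplitSpec | None = None,
                    verbose: bool = False) -> TrainedNet:
    """Train one network with early stopping on validation R^2.

    ``X`` is (n, 17, 4) one-hot, ``y`` the activity in (0, 1).  When a
    split is given, training uses split.train and early stopping monitors
    split.val; otherwise all data are used for both (overfit checks).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    tr = split.train if split is not None else np.arange(X.shape[0])
    va = split.val if split is not None else tr
    Xtr, ytr = X[tr], y[tr]
    Xva, yva = X[va], y[va]

    model = BetaResNet(
        seq_len=X.shape[1], n_channels=X.shape[2],
        n_blocks=config.n_blocks, filters=config.filters,
        kernels=config.kernel_sizes, fc_units=config.fc_units,
        seed=config.seed,
    )
    opt = Adam(model.params(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 101)
    net = TrainedNet(model, config)
    best_snap = _snapshot(model)
    best_r2, stale = -np.inf, 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(Xtr.shape[0])
        epoch_loss = 0.0
        for i in range(0, order.size, config.batch_size):
            sel = order[i:i + config.batch_size]
            if sel.size < 2:
                continue            # batch norm needs > 1 sample
            model.zero_grad()
            a, b = model.forward(Xtr[sel], train=True)
            loss, da, db = _batch_nll_and_grads(ytr[sel], a, b)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.backward(da, db)
            opt.step()
            epoch_loss += loss * sel.size
        val_r2 = _r2(yva, net.predict_mean(Xva))
        net.history.append(
            {"epoch": epoch, "train_nll": epoch_loss / order.size,
             "val_r2": val_r2}
        )
        if verbose:
            print(f"epoch {epoch}: nll={epoch_loss / order.size:.4f} "
                  f"val_r2={val_r2:.4f}")
        if val_r2 > best_r2:
            best_r2, stale = val_r2, 0
            best_snap = _snapshot(model)
        else:
            stale += 1
            if stale > config.patience:
                break
    _restore(model, best_snap)
    net.best_val_r2 = best_r2
    return net


@dataclass
class EnsemblePrediction:
    """Uniform beta-mixture prediction for a batch of sequences."""

    shape_pairs: np.ndarray   # (n, N, 2)
    mu: np.ndarray            # (n,)
    sigma: np.ndarray         # (n,)


class Ensemble:
    """Uniformly weighted ensemble of trained networks."""

    def __init__(self, members: list[TrainedNet]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    def predict(self, X) -> EnsemblePrediction:
        return ensemble_predict(self.members, X)

    def predict_mu(self, X) -> np.ndarray:
        return self.predict(X).mu

    def mean_input_gradient(self, X) -> np.ndarray:
        """Gradient of the ensemble mean prediction w.r.t. the input."""
        total = np.zeros_like(np.asarray(X, dtype=float))
        for net in self.members:
            a, b = net.model.forward(X, train=False)
            s = a + b
            dmu_da = b / s**2
            dmu_db = -a / s**2
            total += net.model.input_gradient(X, dmu_da, dmu_db)
        return total / len(self.members)


def mixture_moments(shape_pairs: np.ndarray):
    """Mean and s.d. of uniform beta mixtures, (n, N, 2) -> ((n,), (n,)).

    mu is the average of member means; sigma**2 combines the mean member
    variance and the variance of member means (law of total variance).
    """
    shape_pairs = np.asarray(shape_pairs, dtype=float)
    a = shape_pairs[..., 0]
    b = shape_pairs[..., 1]
    means = a / (a + b)
    variances = a * b / ((a + b) ** 2 * (a + b + 1.0))
    mu = means.mean(axis=1)
    var = variances.mean(axis=1) + (means**2).mean(axis=1) - mu**2
    return mu, np.sqrt(np.maximum(var, 0.0))


def ensemble_predict(members, X) -> EnsemblePrediction:
    """Mixture prediction of a uniformly weighted ensemble."""
    X = np.asarray(X, dtype=float)
    pairs = []
    for net in members:
        a, b = net.predict_shapes(X)
        pairs.append(np.stack([a, b], axis=1))
    shape_pairs = np.stack(pairs, axis=1)            # (n, N, 2)
    mu, sigma = mixture_moments(shape_pairs)
    return EnsemblePrediction(shape_pairs, mu, sigma)


def train_ensemble(X, y, configs, seeds_per_config=2,
                   split: SplitSpec | None = None) -> Ensemble:
    """M configurations x K seeds ensemble (desk default 2 x 2)."""
    members = []
    for ci, cfg in enumerate(configs):
        for s in range(seeds_per_config):
            member_cfg = replace(cfg, seed=cfg.seed + 1000 * ci + s)
            members.append(build_and_train(X, y, member_cfg, split))
    return Ensemble(members)


def metrics(predictions, truths, fold_floor: float = 1e-3) -> dict:
    """R^2, MAE, RMSE and the percentage within 2-fold error.

    Pairs with truth below ``fold_floor`` are excluded from the fold
    metric (fold error is undefined at 0) and counted separately; a
    prediction exactly at 2-fold counts as within.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.size == 0 or p.shape != t.shape:
        raise ValueError("predictions and truths must be non-empty, aligned")
    ok = t >= fold_floor
    fold = np.maximum(p[ok] / t[ok], t[ok] / np.maximum(p[ok], 1e-300))
    return {
        "r2": _r2(t, p),
        "mae": float(np.mean(np.abs(p - t))),
        "rmse": float(np.sqrt(np.mean((p - t) ** 2))),
        "pct_within_2fold": float(100.0 * np.mean(fold <= 2.0))
        if ok.any() else np.nan,
        "n_fold_excluded": int((~ok).sum()),
    }


def mixture_quantile(shape_pairs: np.ndarray, q, tol: float = 1e-6):
    """Quantiles of uniform beta mixtures by bisection on the mean CDF.

    ``shape_pairs`` is (n, N, 2); ``q`` scalar; returns (n,) quantiles.
    """
    a = shape_pairs[..., 0]
    b = shape_pairs[..., 1]
    lo = np.zeros(a.shape[0])
    hi = np.ones(a.shape[0])
    for _ in range(int(np.ceil(np.log2(1.0 / tol)))):
        mid = 0.5 * (lo + hi)
        cdf = beta_dist.cdf(mid[:, None], a, b).mean(axis=1)
        below = cdf < q
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def reliability_diagram(shape_pairs: np.ndarray, y, levels=None) -> dict:
    """Empirical coverage of central predictive intervals.

    For each confidence level x, the central x% interval of each
    sequence's predictive mixture is inverted from the mixture CDF and
    the fraction of observed values falling inside is reported.
    """
    y = np.asarray(y, dtype=float)
    if levels is None:
        levels = np.arange(10.0, 100.0, 10.0)
    levels = np.asarray(levels, dtype=float)
    coverage = np.empty(levels.size)
    for i, lv in enumerate(levels):
        if lv <= 0:
            coverage[i] = 0.0
            continue
        if lv >= 100:
            coverage[i] = 1.0
            continue
        alpha_tail = (1.0 - lv / 100.0) / 2.0
        lo = mixture_quantile(shape_pairs, alpha_tail)
        hi = mixture_quantile(shape_pairs, 1.0 - alpha_tail)
        coverage[i] = float(np.mean((y >= lo) & (y <= hi)))
    return {"levels": levels, "coverage": coverage}


def threshold_sweep(X, y, read_counts, thetas, config: NetConfig,
                    fractions=(0.7, 0.15, 0.15), seed=0) -> dict:
    """Nested minimal-read-threshold sweep.

    ``read_counts`` is (n, n_times).  The loosest threshold's dataset is
    split once; stricter datasets inherit the split by intersection, so
    each high-quality train/val/test set is contained in every
    lower-quality one.  One network per threshold is trained with
    identical hyperparameters; validation R^2 is reported per theta.
    """
    thetas = sorted(thetas)
    counts = np.asarray(read_counts)
    eligible = {th: np.all(counts >= th, axis=1) for th in thetas}
    base = eligible[thetas[0]]
    base_idx = np.nonzero(base)[0]
    split0 = stratified_split(y[base_idx], fractions, seed=seed)
    split_sets = {
        part: base_idx[getattr(split0, part)]
        for part in ("train", "val", "test")
    }
    out = {}
    prev_train = None
    for th in thetas:
        el = np.nonzero(eligible[th])[0]
        tr = np.intersect1d(split_sets["train"], el)
        va = np.intersect1d(split_sets["val"], el)
        te = np.intersect1d(split_sets["test"], el)
        if prev_train is not None and not np.all(np.isin(tr, prev_train)):
            raise ValueError("threshold nesting violated")
        prev_train = tr
        split = SplitSpec(tr, va, te)
        net = build_and_train(X, y, config, split)
        out[th] = {
            "n_train": int(tr.size),
            "n_val": int(va.size),
            "val_r2": net.best_val_r2,
        }
    return out


def fit_baseline(model_name: str, X, y, split: SplitSpec,
                 seed: int = 0) -> dict:
    """Classical regression baselines on flattened one-hot features.

    Hyperparameters are tuned on the validation split only; test metrics
    are reported in the same format as :func:`metrics`.
    """
    from sklearn.ensemble import (
        GradientBoostingRegressor,
        RandomForestRegressor,
    )
    from sklearn.linear_model import Ridge
    from sklearn.neighbors import KNeighborsRegressor

    X = np.asarray(X, dtype=float).reshape(len(X), -1)
    y = np.asarray(y, dtype=float)
    grids = {
        "ridge": [("alpha", a, lambda a: Ridge(alpha=a))
                  for a in (0.01, 0.1, 1.0, 10.0, 100.0)],
        "knn": [("k", k, lambda k: KNeighborsRegressor(n_neighbors=k))
                for k in (3, 5, 10, 20)],
        "random_forest": [
            ("n_estimators", n,
             lambda n: RandomForestRegressor(
                 n_estimators=n, random_state=seed, n_jobs=1))
            for n in (50, 100)],
        "gradient_boosting": [
            ("max_depth", d,
             lambda d: GradientBoostingRegressor(
                 max_depth=d, random_state=seed))
            for d in (2, 3, 4)],
    }
    if model_name not in grids:
        raise ValueError(f"unknown baseline {model_name!r}")
    best = None
    for _, val, make in grids[model_name]:
        est = make(val)
        est.fit(X[split.train], y[split.train])
        r2 = _r2(y[split.val], est.predict(X[split.val]))
        if best is None or r2 > best[0]:
            best = (r2, est)
    _, est = best
    report = metrics(est.predict(X[split.test]), y[split.test])
    report["val_r2"] = best[0]
    report["model"] = model_name
    return report
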