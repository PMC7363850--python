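"""Seeded synthetic experiment generator.

Emulates the statistical structure of a recombinase-flipping NGS
experiment: a library of 17-nt RBS variants with ground-truth logistic
flipping kinetics, log-normally distributed per-variant read depth,
binomial flipped/unflipped draws per sampling time (each read flipped
independently with probability p(t)), dual 6-bp sample indices, a 10-bp
constant region, attP/attR discriminator sites, i.i.d. substitution
errors, and an optional fraction of corrupted reads (long ambiguous runs
or off-target CDS mutations) to exercise the downstream filters.

The kinetic prior is a mixture skewed toward weak variants, mirroring the
strong weak-RBS skew of a fully randomized library; the ``strong_fraction``
knob enriches the strong component to mimic designed sub-libraries.  The
prior is a stand-in for realistic curve shapes, not an estimate from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from . import readproc
from .kinetics import T_MAX, generalized_logistic

__all__ = [
    "IUPAC",
    "GroundTruthVariant",
    "SimConfig",
    "ReadPairRecord",
    "default_index_pairs",
    "sample_library",
    "simulate_reads",
    "write_fastq",
]

#: IUPAC nucleotide degeneracy codes
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GroundTruthVariant:
    """One library member with known kinetics.

    ``kinetic_params`` is (L, k, t0, nu) of the generalized logistic curve;
    the curve is non-decreasing on [0, 720] because k >= 0 and nu > 0.
    """

    rbs_sequence: str
    kinetic_params: tuple
    mean_depth: float

    def __post_init__(self):
        if len(self.rbs_sequence) != 17:
            raise ValueError("rbs_sequence must be exactly 17 nt")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        L, k, t0, nu = self.kinetic_params
        if not (0.0 <= L <= 1.0 and k >= 0.0 and nu > 0.0):
            raise ValueError("kinetic parameters outside admissible region")

    def p(self, t):
        """Fraction flipped at time t (minutes)."""
        return generalized_logistic(np.asarray(t, dtype=float),
                                    *self.kinetic_params)


def default_index_pairs(n: int, rng: np.random.Generator) -> list:
    """n distinct (6-nt, 6-nt) index pairs."""
    pairs = []
    seen = set()
    while len(pairs) < n:
        pair = (
            "".join(rng.choice(_BASES, 6)),
            "".join(rng.choice(_BASES, 6)),
        )
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pairs


@dataclass
class SimConfig:
    """Configuration of one synthetic experiment."""

    n_variants: int = 100
    sampling_times: tuple = (0, 30, 60, 120, 180, 240, 360, 480, 720)
    index_pairs: list | None = None
    substitution_error_rate: float = 0.001
    depth_lognormal_params: tuple = (np.log(100.0), 0.5)
    corrupt_fraction: float = 0.0
    strong_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > T_MAX:
            raise ValueError(
                f"sampling_times must be sorted, unique, within [0, {T_MAX:g}]"
            )
        if not 0.0 <= self.substitution_error_rate < 0.25:
            raise ValueError("substitution_error_rate must be in [0, 0.25)")
        if self.index_pairs is None:
            rng = np.random.default_rng(self.seed + 917)
            self.index_pairs = default_index_pairs(len(t), rng)
        if len(self.index_pairs) != len(t):
            raise ValueError("need one index pair per sampling time")
        if len(set(map(tuple, self.index_pairs))) != len(self.index_pairs):
            raise ValueError("index pairs must be unique per time sample")

    def sample_labels(self) -> list[str]:
        return [f"t{int(t)}" for t in self.sampling_times]

    def index_table(self) -> dict:
        return {
            tuple(pair): label
            for pair, label in zip(self.index_pairs, self.sample_labels())
        }


@dataclass(frozen=True)
class ReadPairRecord:
    """One simulated read pair (amplicon sense orientation, see readproc)."""

    read_id: str
    forward_seq: str
    reverse_seq: str
    qualities: str | None = None


def _draw_kinetics(rng: np.random.Generator, strong_fraction: float):
    """Kinetic prior: weak-skewed plateau mixture with a strong component."""
    if rng.random() < strong_fraction:
        L = rng.beta(4.0, 1.5)          # strong: plateau near 1
    else:
        L = rng.beta(1.2, 4.0)          # weak-skewed bulk
    k = float(np.exp(rng.normal(np.log(0.012), 0.5)))
    t0 = float(rng.uniform(60.0, 600.0))
    nu = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    return (float(L), k, t0, nu)


def sample_library(config: SimConfig,
                   design: str | None = None) -> list[GroundTruthVariant]:
    """Draw a library of ground-truth variants.

    ``design`` is an optional 17-symbol IUPAC string; each position is drawn
    i.i.d. uniformly over the symbol's base set (plain N17 when omitted).
    """
    if design is None:
        design = "N" * 17
    if len(design) != 17:
        raise ValueError("design must have exactly 17 symbols")
    for pos, sym in enumerate(design.upper()):
        if sym not in IUPAC:
            raise ValueError(
                f"non-IUPAC symbol {sym!r} at position {pos} of design"
            )
    rng = np.random.default_rng(config.seed)
    mu, sigma = config.depth_lognormal_params
    variants = []
    for _ in range(config.n_variants):
        seq = "".join(
            rng.choice(list(IUPAC[sym])) for sym in design.upper()
        )
        params = _draw_kinetics(rng, config.strong_fraction)
        depth = float(rng.lognormal(mu, sigma))
        variants.append(GroundTruthVariant(seq, params, depth))
    return variants


def _apply_substitutions(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    chars = arr.view()
    for i in hits:
        alts = [b for b in b"ACGT" if b != chars[i]]
        chars[i] = alts[rng.integers(3)]
    return arr.tobytes().decode()


def _corrupt(fwd: str, rev: str, rng) -> tuple[str, str]:
    """Inject a >6-nt ambiguous run or off-target CDS mutations."""
    if rng.random() < 0.5:
        run = 7 + int(rng.integers(4))
        start = int(rng.integers(0, len(fwd) - run))
        fwd = fwd[:start] + "N" * run + fwd[start + run:]
    else:
        cds_start = len(readproc.FWD_PAD) + 17 + 3
        pos = rng.choice(
            np.arange(cds_start, len(fwd)), size=5, replace=False
        )
        arr = list(fwd)
        for i in pos:
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        fwd = "".join(arr)
    return fwd, rev


def simulate_reads(variants: list[GroundTruthVariant],
                   config: SimConfig) -> Iterator[ReadPairRecord]:
    """Emit read pairs: Poisson(mean_depth) pairs per variant and time,
    each flipped independently with probability p(t)."""
    sites = readproc.SiteDefinitions()
    rng = np.random.default_rng(config.seed + 1)
    times = np.asarray(config.sampling_times, dtype=float)
    rate = config.substitution_error_rate
    serial = 0
    for vi, var in enumerate(variants):
        fwd_tpl = readproc.FWD_PAD + var.rbs_sequence + readproc.CDS_REF
        p_t = var.p(times)
        for ti, t in enumerate(times):
            i1, i2 = config.index_pairs[ti]
            rev_prefix = i1 + sites.constant_region + i2 + readproc.REV_SPACER
            n_reads = int(rng.poisson(var.mean_depth))
            if n_reads == 0:
                continue
            flips = rng.random(n_reads) < p_t[ti]
            for flip in flips:
                att = sites.attR_site if flip else sites.attP_site
                fwd = fwd_tpl
                rev = rev_prefix + att + readproc.REV_PAD
                if rate > 0:
                    fwd = _apply_substitutions(fwd, rate, rng)
                    rev = _apply_substitutions(rev, rate, rng)
                if config.corrupt_fraction > 0 and (
                    rng.random() < config.corrupt_fraction
                ):
                    fwd, rev = _corrupt(fwd, rev, rng)
                yield ReadPairRecord(
                    f"sim:{vi}:{int(t)}:{serial}", fwd, rev
                )
                serial += 1


def synthetic_sequence_activity(
    n: int,
    seed: int = 0,
    interaction_weight: float = 1.5,
    label_concentration: float = 100.0,
    weight_scale: float = 0.45,
):
    """Recoverable synthetic sequence-activity map for predictor studies.

    Activity is a sigmoid of an additive per-position, per-base logit plus
    one pairwise interaction term (positions 5 and 11 both purine-rich),
    so a linear model on one-hot features cannot represent it exactly.
    Observed labels are beta draws around the true mean with the given
    concentration (aleatoric noise shrinking as concentration grows).

    Returns (sequences, y_observed, y_true_mean).
    """
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, weight_scale, (17, 4))
    idx = rng.integers(0, 4, size=(n, 17))
    seqs = ["".join(_BASES[j] for j in row) for row in idx]
    additive = W[np.arange(17)[None, :], idx].sum(axis=1)
    purine = np.isin(idx, [0, 2])                   # A or G
    inter = interaction_weight * (purine[:, 5] & purine[:, 11])
    logit = additive + inter - additive.mean()
    mu = 1.0 / (1.0 + np.exp(-logit))
    mu = np.clip(mu, 1e-4, 1.0 - 1e-4)
    y = rng.beta(mu * label_concentration, (1.0 - mu) * label_concentration)
    return seqs, np.clip(y, 1e-6, 1.0 - 1e-6), mu


def write_fastq(records, forward_path, reverse_path) -> None:
    """Write mate-paired 4-line FASTQ files with placeholder qualities."""
    try:
        fh1 = open(forward_path, "w")
    except OSError as exc:
        raise OSError(f"cannot write forward FASTQ {forward_path}: {exc}")
    try:
        fh2 = open(reverse_path, "w")
    except OSError as exc:
        fh1.close()
        raise OSError(f"cannot write reverse FASTQ {reverse_path}: {exc}")
    with fh1, fh2:
        for rec in records:
            q1 = rec.qualities or "I" * len(rec.forward_seq)
            q2 = rec.qualities or "I" * len(rec.reverse_seq)
            fh1.write(f"@{rec.read_id}\n{rec.forward_seq}\n+\n{q1}\n")
            fh2.write(f"@{rec.read_id}\n{rec.reverse_seq}\n+\n{q2}\n")


def simulate_to_fastq(config: SimConfig, out_dir, design=None):
    """Convenience: library + reads + index table written under out_dir."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    variants = sample_library(config, design)
    r1 = os.path.join(out_dir, "R1.fastq")
    r2 = os.path.join(out_dir, "R2.fastq")
    write_fastq(simulate_reads(variants, config), r1, r2)
    idx_path = os.path.join(out_dir, "indexes.tsv")
    with open(idx_path, "w") as fh:
        fh.write("sample\tindex1\tindex2\n")
        for pair, label in zip(config.index_pairs, config.sample_labels()):
            fh.write(f"{label}\t{pair[0]}\t{pair[1]}\n")
    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("rbs\tL\tk\tt0\tnu\tmean_depth\n")
        for v in variants:
            L, k, t0, nu = v.kinetic_params
            fh.write(
                f"{v.rbs_sequence}\t{L:.6g}\t{k:.6g}\t{t0:.6g}\t{nu:.6g}"
                f"\t{v.mean_depth:.6g}\n"
            )
    return variants, r1, r2, idx_path
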