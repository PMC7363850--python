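# flipkit

Tools for **DNA-based phenotypic recording** of ribosome binding site (RBS)
activity.  A recombinase reporter couples the translational output of a
17-nt RBS to an irreversible DNA inversion: each sequencing read carries
both the RBS variant and the state of a discriminator site (attP =
unflipped, attR = flipped), so deep sequencing of a pooled library at
several times after induction yields, per variant, a *flipping profile* —
the fraction of flipped discriminators over time.  flipkit implements the
full computational workflow around this readout:

- **`synthdata`** — seeded simulator of ground-truth libraries and paired-end
  reads (logistic flipping kinetics, log-normal depth, binomial
  flipped/unflipped draws, dual 6-bp indices, substitution errors).
- **`readproc`** — FASTQ pair → per-variant counts: pairing, ambiguity filter
  (> 6 consecutive N), 10-bp constant-region anchoring (≤ 3 mismatches),
  dual-index demultiplexing, attP/attR state call (≤ 3 mismatches),
  extraction of the 17 nt upstream of the start codon, CDS-mismatch filter
  (> 8 % of reads) and minimal read threshold (≥ θ reads at every time).
- **`kinetics`** — generalized-logistic fits p(t) = L / (1 + e^(−k(t−t₀)))^ν
  (exponential-rise fallback) and the activity readout
  IFP₀₋₄₈₀ = (1/480) ∫₀⁴⁸⁰ p(t) dt ∈ [0, 1], plus its trapezoidal proxy
  IFP_trz on raw profiles.
- **`schedule`** — greedy selection of sampling times minimizing the
  piecewise-linear reconstruction error of dense profiles, and an NGS
  loading simulation (binomial read thinning, threshold survival,
  n_output = n_simul · r_c · r_t).
- **`calibrate`** — k-medoid internal-standard selection, cross-replicate
  normalization with the constrained quadratic f(x) = A·x + (1 − A)·x²
  (f(0) = 0, f(1) = 1, monotone ⇒ 0 ≤ A ≤ 2), and flipping↔fluorescence
  calibration ranked by leave-one-out R² with differential-entropy
  diversity scores.
- **`libdesign`** — degenerate (IUPAC) library design by position
  probability matrix matching, and by genetic-algorithm enrichment followed
  by greedy Kolmogorov–Smirnov distribution matching.
- **`predictor`** — a residual convolutional network over one-hot 17 × 4
  inputs whose two outputs parametrize a beta distribution over IFP,
  trained by beta negative log-likelihood; ensembles (M configurations ×
  K seeds) give a predicted mean and a mixture-standard-deviation
  uncertainty, with reliability diagrams, threshold sweeps and classical
  baselines (ridge, kNN, random forest, gradient boosting).
- **`interpret`** — positional motif/start-codon statistics, first-layer
  filter correlation clustering, integrated-gradients attribution with an
  all-zeros baseline, attribution clustering, and greedy in silico
  evolution over all 1–2-substitution neighbors (1,275 per round).

The network engine (`flipkit.nn`) is a compact numpy layer stack
(convolution, batch norm, LeakyReLU, dense, softplus) with hand-written
backward passes and Adam, which also provides the input gradients used by
integrated gradients.

## Worked example

```python
import numpy as np, tempfile
from flipkit import synthdata, readproc, kinetics, calibrate

cfg = synthdata.SimConfig(
    n_variants=50,
    sampling_times=(0, 30, 60, 120, 180, 240, 360, 480, 720),
    substitution_error_rate=0.001,
    depth_lognormal_params=(np.log(150.0), 0.3),
    seed=7,
)
with tempfile.TemporaryDirectory() as tmp:
    variants, r1, r2, idx = synthdata.simulate_to_fastq(cfg, tmp)
    profiles, stats = readproc.build_profiles(r1, r2, idx, min_reads=20)

print(f"read pairs in: {stats.total_pairs}, aggregated: {stats.aggregated}, "
      f"variants kept: {stats.variants_final}")

prof = profiles[0]
times = np.array(cfg.sampling_times, float)
frac = np.array([prof.counts[l][1] / sum(prof.counts[l])
                 for l in cfg.sample_labels()])
fit = kinetics.fit_profile(kinetics.FlippingProfile(times, frac))
act = kinetics.ifp(fit)
print(f"{prof.rbs_sequence}  family={fit.family}  IFP_0-480 = {act.value:.3f}")

rng = np.random.default_rng(0)
x = np.sort(rng.random(31))
rep_map = calibrate.fit_replicate_map(x, calibrate.quadratic_map(x, 1.7))
print(f"replicate map: A = {rep_map.A:.3f} ({rep_map.direction}), "
      f"MSE = {rep_map.fit_mse:.2e}")
```

prints

```
read pairs in: 68165, aggregated: 67319, variants kept: 50
AAACCAAACCCCGACGA  family=generalized_logistic  IFP_0-480 = 0.095
replicate map: A = 1.700 (forward), MSE = 1.09e-32
```

68,165 simulated read pairs survive the filters almost completely (the
846 dropped reads carry substitution errors in the constant region or
index), all 50 variants clear the 20-read threshold, the first variant is
a weak RBS (only 9.5 % of the 0–480 min window spent flipped), and the
cross-replicate map recovers a planted curvature parameter A = 1.7
exactly from noiseless standard pairs.

A `flipkit` console script wraps the same steps
(`flipkit simulate | process | fit | schedule | load-sim | normalize |
design | train | evolve`); run `flipkit --help` for details.

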