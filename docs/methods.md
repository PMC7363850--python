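# Methods

## The measurement model

A recombinase reporter records the activity of a 17-nt RBS as an
irreversible DNA inversion: the stronger the RBS, the more recombinase is
made, and the sooner a cell's discriminator cassette flips from the attP
to the attR configuration.  Sequencing a pooled library at several times
after induction gives, per variant i and time t, counts of unflipped and
flipped reads whose ratio estimates the fraction flipped p_i(t).  Because
recombination is irreversible, p_i is non-decreasing on the observation
window [0, 720] min.  The scalar activity readout is the normalized
integral

    IFP_0–480 = (1/480) ∫_0^480 p(t) dt  ∈ [0, 1],

computed on a fitted curve, or by the trapezoidal rule on raw
observations (IFP_trz).

## Synthetic experiments

The simulator is the package's source of ground truth; every downstream
stage is tested against it.  Per variant it draws

- a 17-nt sequence, positionwise uniform over an optional IUPAC design
  (plain N17 otherwise);
- generalized-logistic kinetic parameters from a prior skewed toward weak
  variants — plateau L ~ Beta(1.2, 4) with probability 1 − s and
  ~ Beta(4, 1.5) with probability s (the `strong_fraction` knob,
  default 0.2, mimicking designed sub-libraries), rate
  k ~ logNormal(log 0.012, 0.5) min⁻¹, midpoint t₀ ~ U(60, 600) min,
  shape ν ~ logU(0.5, 2).  This prior is a documented stand-in for
  realistic curve shapes, not an estimate from data;
- a mean depth from a log-normal law (default median 100 reads, log-sd
  0.5), the across-variant read-count model; within a variant, the count
  per time point is Poisson around that mean (the within-variant
  dispersion is a modelling choice — only the across-variant law is
  specified by the measurement design).

Each read pair follows a fixed documented layout (forward: 20-nt pad,
RBS, ATG + 30-nt CDS reference; reverse: index1, 10-nt constant region
GAGCTCGCAT, index2, 4-nt spacer, 17-nt attP/attR site, 7-nt pad).  Reads
are flipped independently with probability p_i(t), substitution errors
are i.i.d. per base, and an optional corrupt fraction injects ≥ 7-nt N
runs or 5-base off-target CDS mutations to exercise the filters.
Quality scores are constant placeholders; the processing pipeline does
not use them.  What the simulator does **not** emulate: PCR amplification
bias, position-dependent instrument error profiles, chimeric reads, and
cross-talk between index pairs.  Green tests therefore certify the
algorithmic pipeline, not robustness to those artifacts in real data.

## Read processing

Stage order: mate pairing → ambiguity filter (drop pairs with a run of
more than six consecutive N in either mate) → constant-region anchoring
→ dual-index demultiplexing → attP/attR state call → RBS extraction
(17 nt immediately 5′ of the start codon) → aggregation by RBS →
CDS-mismatch filter (drop variants with mismatched CDS in more than 8 %
of reads; exactly 8 % is kept — "more than" is read strictly) → minimal
read threshold (≥ θ at every time point).  All matching is Hamming
distance on aligned windows — no indels, since the tolerance is stated
as mismatches — scanning every window and keeping the minimum-distance,
leftmost hit.  The attP/attR references are 13 mismatches apart, so with
tolerance 3 a simultaneous match is impossible (enforced as a
`SiteDefinitions` invariant).  Reads matching neither site are excluded
from the fraction-flipped denominator and logged separately; reads whose
extracted RBS contains an ambiguous base are dropped.  A conservation
identity (reads in = dropped per stage + aggregated) is checked in
tests.  Uniform-length inputs take a vectorized numpy path; mixed
lengths fall back to an equivalent per-read path (the two are
cross-checked in tests).

## Kinetic fitting

Primary family: the Richards curve p(t) = L / (1 + e^(−k(t−t₀)))^ν with
admissible region 0 ≤ L ≤ 1, k ≥ 0, ν > 0.  The least-squares fit runs
unconstrained (Levenberg–Marquardt, three starts varying the initial
rate); it is declared failed when no start converges or the solution
leaves the admissible region — e.g. decreasing profiles drive k < 0 —
in which case the bounded saturating exponential a(1 − e^(−bt)) is
fitted instead.  Exactly flat profiles are represented in closed form by
the logistic family's saturated limit.  Imputation evaluates the fitted
curve on the 5-min grid {0, 5, …, 720} (145 points), the smallest
spacing between two samples.  Integration uses adaptive quadrature with
absolute tolerance 10⁻⁶.

## Sampling-schedule optimization

Given profiles imputed on the grid T, the greedy optimizer starts from
S = {0, 720} and repeatedly adds the candidate time minimizing

    Σ_i (1/|T|) Σ_{t∈T} | p̂_i(t) − l̂_i^{S∪{s}}(t) |,

where l̂ is the piecewise-linear interpolation at the selected times;
ties go to the earliest candidate, so the construction is deterministic
and the schedules are nested by design.  The summation is taken over the
fixed grid T (the reconstruction-error form also used for the final
per-profile error r_i), which makes the objective comparable across
rounds.  Optimization may be restricted to the strongest profiles
(strength = last minus first observed fraction; ties broken by sequence
identity) to counter the weak-variant skew of random libraries.  The
loading simulation thins each read count binomially with probability
1/r_c (the thinning mechanism is a seeded modelling choice), counts
variants surviving θ, and projects library sizes by the conservation of
total valid reads: n_input = n_total · r_c · r_t.

## Normalization and calibration

A degree-two polynomial pinned at f(0) = 0 and f(1) = 1 leaves one free
parameter: f(x) = A·x + (1 − A)·x².  Since f′(x) = A + 2(1 − A)x is
affine, monotonicity on [0, 1] reduces to the endpoint conditions
f′(0) = A ≥ 0 and f′(1) = 2 − A ≥ 0, giving 0 ≤ A ≤ 2.  Both the
forward map and its inverse are fitted by bounded 1-D minimization
(the objective is smooth in A for a fixed direction) and the lower-MSE
direction kept.  Internal standards are selected as k-medoids (k = 25
by default) of kinetic profiles under Euclidean distance on the 5-min
grid — the metric is a documented choice.  Calibration against
fluorescence grids over (flipping window × fluorescence window × link
family {linear, log-linear, 3-parameter logistic}), scores each cell by
leave-one-out R², and reports the differential entropy of the flipping
summary as a diversity score, estimated with the Kozachenko–Leonenko
nearest-neighbor estimator (pluggable; k = 1).

## Library design

PPM route: activities are binned into 10 linear bins of [0, 1] (last bin
closed), a position probability matrix computed per bin, and for each
position independently the IUPAC code with minimal mean-squared error to
the target column is chosen (the MSE objective decomposes positionwise;
ties prefer the smaller base set, then alphabetical order — making the
design idempotent).  GA route: each pool sequence hill-climbs under a
scorer, accepting only strictly score-increasing proposals of 1–2
substitutions per iteration (200 by default).  The degenerate candidate
then starts from the PPM-matched string and greedily accepts
single-position IUPAC edits that reduce the two-sample KS statistic
against scores of 20,000 sequences drawn from the evolved pool's PPM;
each greedy round fixes one evaluation seed so that candidate
comparisons are paired (variance reduction), positions are scanned left
to right, and the incumbent is kept on ties.

## Prediction model

One-hot 17 × 4 inputs (channel order A, C, G, T) pass through residual
blocks — conv(k) → BN → LeakyReLU(0.1) → conv(1) → BN, added to an
identity (or 1 × 1-projected) skip, then activated — and are flattened
into two parallel stacks of two fully connected layers (64 → 1 by
default) ending in softplus (+10⁻³ offset), yielding the shape
parameters (α, β) of a beta distribution over IFP.  Training minimizes
the beta negative log-likelihood (a proper scoring rule; targets clamped
to (10⁻⁶, 1 − 10⁻⁶)) with Adam, L2 weight decay 10⁻⁶, global
gradient-norm clipping at 10, and early stopping at the epoch with the
best validation R².  Splits preserve the proportion of strong sequences
(top 15 % of the activity distribution — the percentile defines the
strong tail).  The ensemble is M configurations × K seeds with uniform
weights; the predicted activity is the mixture mean and the uncertainty
the mixture standard deviation via the law of total variance.  Mixture
quantiles for reliability diagrams are obtained by bisection on the
average member CDF (tolerance 10⁻⁶).  Desk-scale defaults are M = 2
configurations × 2 seeds, two residual blocks and 16–24 filters,
trained on ~10⁴ sequences — sizes chosen so the whole evaluation runs
comfortably on a single CPU while preserving the configurations × seeds
ensemble structure; the architecture scales to the full 3-block,
64/512-filter, 2 × 5-member layout through `NetConfig`.

The engine is written directly in numpy with hand-derived backward
passes (verified against numerical differentiation in tests); this also
provides exact input gradients for attribution and exposes first-layer
activations for filter analysis.

## Interpretation

Motif statistics group sequences carrying a motif at an anchor
(−17 … −1; −1 abuts the A of the native ATG) and report median,
quartiles and 20/80 percentiles of activity; sequences containing a
start codon anywhere other than the queried anchor are excluded.  A
start-codon anchor is in frame when its position is a multiple of 3.
Filter analysis correlates each first-layer filter's linear activation
per position with activity and clusters the 17-long correlation vectors
by complete linkage into 12 groups; because Hamming distance is not
defined on real vectors, the default mode sign-binarizes correlations at
|r| > 0.05 (ternary −1/0/+1) before Hamming linkage, with a Euclidean
mode available.  Integrated gradients uses an all-zeros one-hot baseline
and a midpoint Riemann sum (≥ 16 steps; completeness residual reported
on every matrix).  Attribution pools (top/bottom 5 % after trimming
beyond 3 robust z-scores) are clustered with seeded k-means and
summarized by medoids (nearest member to the centroid; ties by dataset
order).  In silico evolution exhaustively scores all 1,275 one- and
two-substitution neighbors per round (two mutations always at distinct
positions), accepts the best strictly improving candidate, and stops at
a local optimum.

## Numerical choices and degenerate inputs

- Logistic curves are evaluated in log space and exponent-clipped, so
  extreme optimizer iterates cannot overflow.
- Batch norm requires ≥ 2 samples; trailing 1-sample batches are
  skipped during training, and inference always uses running statistics.
- Zero-variance filter activations get correlation 0 with a flag;
  degenerate (constant) fluorescence summaries are flagged, not
  rejected.
- Empty att-site matches ("unknown" state) never enter the
  fraction-flipped denominator.
- All stochastic components (simulation, thinning, splits, k-means,
  initialization, shuffling) are seeded; identical configurations
  produce byte-identical FASTQ and identical training trajectories.

## Known limitations

The kinetic prior and read layout are stand-ins: amplicon coordinates,
error spectra and the true distribution of curve shapes in a real
library are not reproduced.  Indel errors are not handled (Hamming
matching only).  The desk-scale ensemble demonstrates the method's
behavior on a recoverable synthetic map; absolute accuracies on real
libraries depend on data volumes and training budgets outside this
package's defaults.
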