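# Methods

## Circuit model

The antennal lobe is modelled as a two-layer feed-forward network of
glomerular channels with one shared lateral pathway.  All neurons are
inhomogeneous Poisson units; synapses are linear exponential filters with
time constant τ.

**ORNs.**  Each glomerulus g holds `n_orn` ORNs firing independently at the
time-independent rate r_g(s) of that receptor type for the presented odor
s.  ORN responses are treated as purely excitatory driven rates;
spontaneous activity and response dynamics are not modelled.

**Synaptic filtering and drive normalization.**  A spike at time t′
contributes exp(−(t−t′)/τ) to its target's input.  Every drive is
*averaged over its presynaptic population*: the feed-forward drive of a
glomerulus is the mean filtered activity of its own `n_orn` ORNs times
`w_ff`, the LN drive is the mean filtered activity of *all* ORNs times
`g_ln`, and the lateral input is the mean filtered activity of the `n_ln`
LNs times `w_lat`.  With this convention the operating point depends only
on rates and the weight *ratios*, not on population sizes — population
sizes only set noise levels — and a glomerulus at rate r contributes a mean
feed-forward drive of exactly r·τ·w_ff.

**LNs.**  LN firing is linear in its drive, floored at zero (the floor
never binds because ORN input is non-negative).  LNs spike as Poisson
processes by default; `deterministic_ln=True` replaces their spike trains
with the expected per-step count, which removes lateral pathway noise and
makes the g_ln·w_lat scale invariance exact.  Only the product g_ln·w_lat
sets the lateral operating point; g_ln defaults to 400 so that LN rates on
the default synthetic ensemble span the tens-of-Hz range of real
interneurons.  At much lower LN rates the pooled 10-LN spike train would
deliver lateral input as rare large pulses rather than a graded signal — a
granularity artifact of the population-averaged normalization, not a
feature of the biology being modelled.

**PNs.**  Each PN receives its glomerulus's feed-forward drive plus the
shared lateral input and fires at

    ν(x) = 0                                   for x ≤ θ
         = r_max ((x − θ)/(x_max − θ))^β       for θ < x < x_max
         = r_max                               for x ≥ x_max.

The power form is the one-parameter family interpolating between concave
(β < 1, weak inputs preferentially amplified) and convex (β > 1) shapes;
it is the central modelling assumption of the package.  Defaults:
θ = 0, x_max = 0.4, r_max = 200 Hz, so saturation onsets at an ORN rate
near x_max/τ = 200 Hz and a saturated PN emits on average
r_max·t_bin = 2 spikes per 10 ms counting bin.

**Discretization.**  Time step dt = 0.2 ms (τ/10).  Per-step spike counts
are drawn Poisson with mean rate·dt (so bin counts are exactly Poisson for
a constant rate and the Fano factor is exactly 1).  The filter recursion
uses a within-step increment c = τ(1 − e^(−dt/τ))/dt per spike — the
step-averaged kernel value for a spike falling uniformly inside its step —
which makes the stationary filtered mean of a rate-r source exactly r·τ at
any dt.  Given the rate path, a PN's bin count is drawn once from the
integrated intensity over the bin (exact, and much faster than per-step
thinning).  Each trial starts from empty filters and warms up for
t_warmup = 20 ms (10 τ) before the single 10 ms counting bin; one bin per
trial keeps trials independent, as the information estimators assume.

**Seeding.**  Ensembles spawn one `numpy` `SeedSequence` substream per
odor from the master seed; the same master seed therefore yields bitwise
identical spike-count tables, and sweeps reuse one master seed across grid
cells (common random numbers) so parameter effects are not masked by
simulation noise.

## Odor ensembles

Measured ORN rate matrices (receptor types × odors, Hz) load from
TSV/CSV.  The synthetic surrogate draws each entry independently from a
two-component exponential mixture truncated to [0, max_rate]: weak with
probability 0.85 (mean 20 Hz) or strong (mean 120 Hz), ceiling 300 Hz.
These defaults reproduce the signature of the published 24-receptor ×
110-odor dataset — a response histogram with its mode at the weak end and
a minority of strong responses — and are configuration, not constants.
The surrogate deliberately omits structure present in real data:
correlations between receptors sharing ligand affinities, odor-specific
response patterns, and concentration series.  Passing tests on synthetic
ensembles therefore establish properties of the *mechanism* (how concavity
and inhibition shape information), not quantitative predictions for any
particular measured matrix.

## Information estimation

Responses are capped PN count vectors; the cap of 5 bounds the pattern
space at (cap+1)^N with negligible probability mass above it (a saturated
PN exceeds 5 spikes in ~1.7 % of bins).  All information quantities are in
bits.

**Plug-in enumeration.**  P(r|s) is the empirical distribution over
`n_trials` (default 400) simulated trials per odor.  The default stores
one marginal per PN and treats PNs as conditionally independent given the
odor: a joint table over 6^8 ≈ 1.7 M patterns cannot be populated by 400
trials, and the factorization is exact when the lateral pathway carries no
shared noise (w_lat = 0 or deterministic LNs) and a mild approximation
otherwise.  Joint-table estimation is retained for small instances and
used to validate the factorized path.  Entropy requires enumerating the
pattern mixture; enumeration is refused above 10⁷ patterns with a pointer
to the decoding estimator.  No bias correction is applied — the plug-in MI
is biased upward at finite trials, and the convergence of that bias is
itself tested.  The tractable exact configuration mirrors 8 glomeruli ×
1 PN with 40 ORNs per glomerulus; 24-glomerulus ensembles are split into
three disjoint 8-glomerulus groups for exact analysis, by default keeping
all odors.

**Decoding bound.**  For larger populations (e.g. 24 glomeruli × 3 PNs), a
one-against-one ensemble of K(K−1)/2 binary linear SVMs (regularization
C = 1, raw counts, no standardization) classifies held-out trials by
majority vote; ties break to the lowest class index (a summed-margin
tie-break is available).  Train and test sizes default to 200 trials per
odor each.  The confusion-matrix MI is a lower bound on the response MI by
the data-processing inequality and increases with training data toward a
plateau below the exact value.

## Sweeps and peaks

Default grids: β ∈ {0.3, 0.5, 0.7, 1.0, 1.4, 2.0} and w_lat ∈ {−2, −1, 0,
1, 2}; the lateral grid is symmetric and scaled so its strongest
inhibition roughly halves mean PN output on the default synthetic
ensemble.  Peaks are read off the grid (no continuous optimization):
peak i is the argmax over {β < 1, w_lat < 0}, peak e over {β > 1,
w_lat > 0}, point n over the w_lat = 0 line, with ties broken toward
smaller |w_lat| then smaller β.  The realized ORN→PN transformation at an
operating point is summarized by the per-(glomerulus, odor) trial-mean PN
rate against the driving ORN rate, a least-squares saturating-exponential
fit a(1 − e^(−r/b)), and a 10-Hz-bin response histogram; "flatness" of a
histogram is its normalized entropy (binned entropy / log₂ n_bins, 20
bins over the signal's dynamic range).  Static-threshold experiments
re-run either a decoded-MI curve over θ at fixed (β, w_lat) or a full
grid per θ.

## Pairwise discrimination

For every unordered odor pair, the package compares an inhibitory
operating point against the same circuit with w_lat = 0: held-out accuracy
of a binary linear SVM, the Euclidean distance between trial-mean count
vectors, and the mean distance of trial vectors from their odor's mean
(1000 trials per odor per condition for the metrics; 200/200 train/test
for the classifier).  Pairs are categorized by the joint signs of the
accuracy, distance, and variability changes; "no change" is reserved for
exactly equal held-out accuracies (near-ties are not coerced).  The PCA
view fits two principal components on the pooled with+without trial set of
one pair (shared axes across conditions), projects held-out trials, the
all-silent corner, and the all-maximal corner (count r_max·t_bin per PN),
and projects each condition's full-dimensional SVM decision hyperplane
into the component plane.

## Problem sizes and numerical choices

Bundled analyses and tests run on scaled-down ensembles chosen to keep the
full pipeline fast while preserving every qualitative contrast: 8
glomeruli × 20 odors for landscape sweeps (400 trials per odor per cell),
8 × 8 for exact-vs-decoded comparisons, 8 × 12 (66 pairs) for the pairwise
analysis.  Probability tables must sum to 1 within 1e-9; the entropy
decomposition identity I = H − H_noise holds to 1e-9 by construction and
is asserted, as are 0 ≤ I ≤ log₂ S.  Degenerate inputs (zero-variance PCA
data, empty odor groups, thresholds at or above saturation) are rejected
with explicit errors rather than silently handled.

## Known limitations

* The power-law intraglomerular transformation is an assumption; real
  transformations arise from synaptic depression and refractory dynamics
  that are not modelled.
* LN wiring is homogeneous and all-to-all; realistic heterogeneous,
  glomerulus-specific lateral connectivity is out of scope.
* The factorized conditional underlies the default exact-MI path; with
  spiking LNs and strong lateral input it slightly misstates the joint
  structure (shared lateral noise correlates PNs).
* Synthetic ensembles share no statistical structure across receptors, so
  absolute MI values are not comparable to analyses of measured matrices —
  only the shape of the landscape and the direction of the mechanism are.
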