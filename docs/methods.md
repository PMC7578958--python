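# Methods

## Scope and data model

`emodrive` analyses how a driver's emotional state shifts the generation and
transition of driving intentions in a car-following scene. The unit of
analysis is a 10-s window of a following-car trajectory, summarized by nine
variables: following speed v1 (km/h), lead speed v2 (km/h), both
accelerations ac1, ac2 (m/s²), gap d (m), relative speed Δv = v1 − v2,
relative acceleration Δac = ac1 − ac2, and the two expectation deviators
Δve = v1 − ve and Δde = d − de, where ve (expected speed, km/h) and de
(expected distance, m) are per-driver constants measured before the runs.
Raw traces are aggregated per window by the arithmetic mean (median or
endpoint sampling would also be defensible; the mean is the standard choice
and is robust at this window length), and a trailing partial window is
dropped.

Two typographic conventions are fixed in the discretization table: the
relative-acceleration lower bound is taken symmetric to its upper bound
(−0.15 / 0.15 m/s²), and Δac is treated as an acceleration (m/s²), not a
length. Class boundaries are assigned to the middle class, making the coding
a total, single-valued map.

## Intention labels and the HMM

Intentions are the latent next-step behaviour choices: decelerate (Int1),
keep speed (Int2), accelerate (Int3). The realized acceleration class of
window *t* + 1 names the intention held at window *t*; a run of T windows
therefore yields T − 1 labels, and the observation at the final window is
unused.

Per condition, the intention process is a discrete HMM λ = (π, A, B) with
three hidden states and 27 observation symbols — the packed levels of
(Δde, d, Δve), index (Δde−1)·9 + (d−1)·3 + Δve. Assumptions: first-order
Markov intentions, emissions conditionally independent given the intention,
and independence across driver × condition runs.

Estimation offers three modes:

* `supervised` (pipeline default): smoothed relative frequencies of the
  labeled intentions, labeled transitions, and (intention, symbol) pairs.
  Laplace smoothing κ = 1 per cell; a state never observed receives a
  uniform row.
* `supervised+em`: the same estimate refined by multi-sequence Baum–Welch.
* `em`: Baum–Welch from a seeded random stochastic initialization.

Baum–Welch uses per-step scaling, accumulates expected counts (γ/ξ) over all
sequences per iteration (sequences grouped by length and processed as
batches), stops when the relative total log-likelihood gain falls below
1e−6 or after 500 iterations, and floors emissions at 1e−10 after each
M-step so unseen symbols remain predictable. The supervised mode is the
pipeline default because, on data whose intention chain is exogenous (see
the generator below), the observation–intention coupling is weak and
unsupervised EM re-estimation drifts the hidden states away from their
behavioural identity, which would invalidate intention-level comparisons;
EM remains first-class, fully tested machinery (monotonicity, stochasticity
after every iteration, parameter recovery on well-separated models, and a
cross-check of the forward pass against an independent implementation).

One-step prediction from intention *i* and next symbol *o* is
argmax_j a_ij · b_j(o), ties broken toward the lower intention index; if all
candidate weights vanish the transition row alone decides. Held-out accuracy
is grouped by the true label with a normal-approximation 95% CI
p̂ ± 1.96·√(p̂(1−p̂)/n), clamped to [0, 1]. Viterbi decoding is deliberately
out of scope — prediction here is one-step, not sequence decoding.

## Observable selection

The eight candidate observables (Δve, Δde, v1, v2, ac2, d, Δv, Δac; ac1 is
the behaviour being explained and is excluded) are factor-analyzed by
principal-component extraction on the correlation matrix with varimax
rotation (Kaiser row normalization; SVD-based fixed-point iteration; column
signs fixed so each factor's largest-|loading| entry is positive). Three
factors are retained by default, with an eigenvalue > 1 auto mode. Each
factor's representative is the variable with the largest absolute rotated
loading, ties broken by the canonical variable order. The pipeline's
observation triple (Δde, d, Δve) is fixed by the study design; the factor
stage reports the selection so a user can verify it on their data.

## PAD measurement and gating

Emotions live in the PAD cube [−1, 1]³; reports on the 0–100 scale map by
x = score/50 − 1. Each emotion has fixed reference coordinates (shipped as a
data file, overridable). A per-minute report is *effective* iff its
Euclidean distance to the reference, in the original cube, is strictly below
0.25 (one step of the pictorial scale). A report at minute m governs the six
10-s windows of that minute; windows of ineffective minutes are excluded,
and each remaining contiguous run of windows becomes its own sequence, so
gating never fabricates transitions across a gap. Natural-state data bypass
the filter (no reference point exists).

## Environment states and the comparison

Satisfaction degree: Sd1 = Δve level − 1 (0 = speed need unmet);
Sd2 = 0/1/2 for Δde levels 3/2/1 (a large gap means the distance need is
unmet); Sd = 1 for component sums 0–1, 2 for sum 2, 3 for sums 3–4. Risk
degree: Rd = 4 − d level. The 27 symbols partition into the nine W_n
states, exactly three symbols each.

Intention posteriors use Bayes' rule per symbol,
P(q_i | O) ∝ P(q_i) · b_i(O), and a W_n posterior mixes its three member
symbols weighted by their model mass P(O) = Σ_j P(q_j) b_j(O). The prior
P(q_i) is the model's expected time-averaged state occupancy by default;
the initial-state distribution π is a switch. Occupancy is the default
because it is the quantity the comparison is about (how much time a driver
spends intending each action) and because it pools all ~3.7k windows of a
condition, whereas π is identified only by the ~62 sequence starts and is
too noisy to support ratio comparisons. The change rate
Gr = (P(Int|W_n, Em) − P(Int|W_n)) / P(Int|W_n) × 100% is undefined (and
reported absent) when the natural probability is zero.

Significance machinery mirrors a per-driver design: each driver's runs are
merged into one sample (occupancy vector and 3×3 transition table of
smoothed relative frequencies), emotions are compared to the natural state
by two-sided paired t-tests (62 drivers → df 61), the eight emotions are
compared jointly per transition cell by one-way ANOVA, and pairwise by
studentized-range (Tukey HSD) q-tests with pooled within-group variance
(verified against an independent Tukey implementation). Stars mark
p < 0.01 / 0.05 / 0.1; no multiple-testing correction is applied, matching
the raw-star reporting convention of this literature.

## The synthetic study generator

No public deposit of such human car-following data exists, so the package
generates studies with the statistical structure the analysis assumes:

* 62 drivers; ve ~ U(58, 72) km/h and de ~ U(8, 14) m (no empirical
  distribution is available for these; the ranges straddle the lead speed
  and the gap-class boundaries so all discretization classes occur);
* a lead car at 60 ± 5 km/h (AR(1) wobble, coefficient 0.8, innovation SD
  1.2 km/h, clipped to the band);
* per condition, a 3-state intention chain with stationary occupancy set by
  the condition preset and transition matrix
  A = 0.7·1·occᵀ + 0.3·I — its stationary law is exactly the preset
  occupancy and transitions into higher-occupancy intentions are uniformly
  larger, reproducing the occupancy/transition coupling seen in trained
  models;
* window acceleration ac1 at window t drawn uniformly inside the
  discretization class interval of the intention at t − 1 (open intervals
  truncated at ±2 m/s²), so behaviour-based labeling recovers the simulated
  chain exactly — a designed round-trip invariant;
* kinematics with first-order relaxation: v1 relaxes toward the lead speed
  (gain 0.5 per window) and responds to ac1 at 4 km/h per m/s²; the gap
  relaxes toward de (gain 0.3) and integrates 40% of the relative-speed
  displacement per window; v1 clipped to [20, 90] km/h, gap to [2, 80] m.
  Pure integration of class-level mean accelerations over 10-s windows
  (v1 += 3.6·ac1·Δt) diverges within minutes under any occupancy-biased
  chain, saturating every discretized class; the relaxation terms are the
  minimal regulator that keeps trajectories in the realistic regime while
  leaving the labeling round-trip untouched;
* per-minute PAD reports: a Bernoulli(effective_rate = 0.8, in line with
  reported induction success rates above 75%) choice between an isotropic
  Gaussian (SD 0.12) rejection-sampled inside the 0.25 ball and a wider
  displacement rejection-sampled outside it;
* one random stream per (seed, driver, condition), so episodes are
  reproducible under parallel generation and conditions are mutually
  independent.

Emotion presets encode the directional findings this analysis is designed
to detect: anger and contempt raise acceleration and depress deceleration;
fear raises deceleration and depresses acceleration; helplessness depresses
both extremes; anxiety and (more mildly) surprise depress speed-keeping in
favour of both extremes; relief is essentially unchanged; pleasure raises
deceleration slightly. The numeric occupancies are editable configuration,
not measurements.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: intentions are exogenous to the environment
(real drivers accelerate *because* they are below their expected speed, so
real emissions are far more informative); within-window dynamics are
constant; there are no intersections, lane changes or other traffic; PAD
report noise is isotropic and minute-to-minute independent; and emotion
induction/decay dynamics are reduced to a single effective rate.

## Study sizes used in validation

The validation suite runs the design at its native size — 62 drivers ×
60 windows (10 min) per condition — for the null-calibration, directional
and gating checks, and uses 500–5000 sequences of length 50 from a sharply
separated model for EM recovery checks. The null (identity) check has two
parts: with the same dataset entering the comparison under both labels the
change rates vanish identically (< 1e−9, limited only by float accumulation
order), and across independently regenerated null studies the paired
t-tests fire at their nominal 10% rate. A bound worth knowing when
interpreting change rates on independent data at this n: P(Int|W_n)
estimated from m windows carries relative sampling noise of order
√(2p(1−p)/m)/p, so thinly populated environment cells can show spurious
|Gr| of tens of percent; the per-driver t-tests, which pool all windows,
are the calibrated inferential instrument, and Gr is the effect-size
readout.

## Known limitations

* The supervised default makes the per-condition models as good as the
  behaviour-derived labels; label noise in real data would propagate.
* The minute-to-window alignment of PAD reports is a convention (report at
  minute m governs minute m); other alignments are plausible.
* The q-test is Tukey HSD; Newman–Keuls-style step-down variants would give
  smaller p-values for adjacent means.
* Environment-state posteriors inherit emission-floor behaviour: a W_n
  whose symbols never occur in training collapses to the prior, which is
  the intended conservative behaviour but should be kept in mind when
  reading Gr maps for rare states.
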