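# Methods

## Overview

`pcsm` decodes recurring latent brain states from trial-aligned task fMRI
and derives interpretable cognitive-processing metrics from the posterior
structure of that decoding.  The pipeline is:

1. **FIR deconvolution** — estimate trial- and delay-specific BOLD
   amplitudes without assuming a haemodynamic response shape.
2. **Constrained GMM-HMM** — model the FIR amplitude sequence with a
   3-state hidden Markov model whose per-state emissions are 2-component
   diagonal Gaussian mixtures (responding vs non-responding), fitted
   globally and then per subject with frozen covariances and template
   alignment.
3. **Diagnostics** — per-frame decoding-quality metrics (response
   probability, temporal reliability, Mahalanobis model discrepancy) with
   frame/trial flagging rules.
4. **Emergent metrics** — node response posteriors, the Poisson-binomial
   serial-parallel deviation index, cognitive demand, a leaky-integrator
   resource level, and a per-subject serial-bottleneck scalar.
5. **Thresholding** — data-driven decision boundaries (Gaussian-mixture
   density intersections with quality gates, boundary-corrected KDE
   valleys, robust quartile bootstraps, adaptive posterior-FDR node
   selection).
6. **Validation** — a generative stop-signal-task simulator with known
   ground truth, plus state/transition recovery and cross-validated
   stability evaluation.

## FIR model

With `T` volumes, `R` trials, `D` delays (default 5, spanning 0–8 s at
TR = 2 s) and `N` nodes, the design `X ∈ {0,1}^{T×K}` (K = R·D) holds one
stick regressor per (trial, delay); `β = (X'X)⁻¹X'Y` is solved jointly by
an SVD pseudo-inverse with relative singular-value cutoff `1e-10`, so
overlapping trials are handled by the same least-squares system and
rank-deficient designs degrade gracefully.  A run intercept is appended
during estimation and discarded afterwards so constant offsets cannot leak
into the amplitudes.  Onsets map to their nearest volume.  Sticks falling
beyond the run produce all-zero columns, zero amplitudes and a warning.

## State model

Emissions per state `c` are `P(y_t|C_t=c) = Σ_m w_{c,m} N(y_t; μ_{c,m},
diag σ²_{c,m})` with `C = 3`, `M = 2`.  Three adaptations tailor the HMM to
trial-aligned data:

* **Trial segmentation.**  Each trial's D delay bins form an independent
  sequence re-initialised from the start distribution; transitions never
  bridge inter-trial gaps.  All forward/backward/Viterbi recursions are
  vectorised across the equal-length segments, which is what makes
  cohort-scale fits (tens of thousands of 5-frame sequences per EM
  iteration) run in seconds rather than hours.
* **Template alignment.**  EM labels states arbitrarily.  Within each
  state the larger-mean-magnitude mixture is labelled *responding* (ties
  broken toward the larger weight); states are ranked by a salience score
  (mean BOLD intensity plus responding-mixture weight) and matched to the
  template by rank.  The salience components are combined on their native
  scales — z-scored amplitude units and a probability — rather than
  re-standardised across states: with only three states, a z-score across
  states amplifies the noise of near-degenerate responding weights (which
  collapse toward 0 whenever a state's emission is close to unimodal)
  enough to scramble the ranking, while the native-scale sum is dominated
  by the stable intensity ordering.  Because two states can still sit
  within each other's salience margin, the rank pairing is checked
  against a Hungarian assignment on a mixture-order-invariant state
  *signature distance* (mixture-weighted state means stacked with
  mixture-averaged sd profiles); when the two disagree, the pairing with
  the smaller total distance wins.  The signature keeps the level
  information a Pearson correlation would centre away, and for
  frozen-covariance subject fits the sd block identifies the inherited
  template state exactly.  Relabelling is likelihood-preserving by
  construction.
* **Frozen covariances.**  Subject-level EM updates start, transition,
  weight and mean parameters only; the variances stay bit-identical to the
  global template, which stabilises subject fits and keeps subjects
  comparable.

Posteriors are *filtered* by default — `π_{t,c} = P(C_t = c | y_{0:t})`
from the forward pass — matching the causal conditioning of the
downstream metrics; smoothed (forward-backward) posteriors are available
by flag.  Viterbi decoding runs per trial segment in log space.

Numerical choices: variance floor `1e-6`; EM convergence on the change in
per-frame log likelihood (tol `1e-4`); `n_init` random k-means-based
initialisations (default 5 for standalone fits, 3 in the study driver)
with the best final likelihood kept; probabilities below `1e-300` treated
as zero in log space.  A separate full `N×N` spatial covariance for
discrepancy scoring is estimated from the concatenated data by
Ledoit-Wolf shrinkage.

**Model-order selection** uses subject-level k-fold cross-validation of
held-out log likelihood per observation.  States are accepted in
ascending order while the gain exceeds 2 per observation and 2 fold
standard errors, the larger model wins ≥ 70% of folds, and (beyond the
first step) the gain is at least 10% of the previous gain; mixtures are
accepted while the gain is at least max(5, 2 SE) per observation.  The
state scan runs at the smallest mixture count and the mixture scan at the
selected state count — a hierarchical sequence that keeps each comparison
one-dimensional.

## Diagnostics

* `P_t = Σ_c π_{t,c} a_{c,1}` with `a_{c,1}` the responding-mixture
  weight; bounded in [0, 1].
* `ρ_t = 1 − ½ Σ_c |π_{t,c} − π_{t−1,c}|` (one minus total variation);
  `ρ_0 = 1` by convention.  An optional exponential moving average
  (half-life = D bins) smooths the ρ series only; it is off by default.
* `D_t^Maha = (y_t − ŷ_t)' Σ⁻¹ (y_t − ŷ_t)` with
  `ŷ_t = Σ_c π_{t,c} μ̄_c`, `μ̄_c` the mixture-weighted state mean and Σ
  the shrinkage spatial covariance, solved by Cholesky with escalating
  jitter rather than an explicit inverse.  The raw quadratic form is
  unbounded; the bounded version used for thresholding is the
  within-subject empirical-CDF (mid-rank) transform, which is uniform on
  (0, 1) by construction.  Both series are exported.
* Flagging: a frame is removal-flagged when the normalised discrepancy is
  at or above its threshold *and* both `P_t` and `ρ_t` fall below theirs;
  a trial with more than half of its bins flagged (≥ 3 of 5) is
  recommended for removal.  Sub-flags are exported so users can recompose
  the rule.

## Emergent metrics

* **Node response posterior** `B_{t,n} = Σ_c π_{t,c} γ_{t,c,1}(n)`, with
  `γ` the per-node responding-mixture responsibility from univariate
  Gaussian Bayes rule.  Nodes where all component densities underflow
  fall back to the mixture weights.
* **Serial-parallel deviation** `D_t^SP = (2/N) E|K_t − N/2|` where `K_t`
  is the responding-node count with success probabilities `B_{t,·}`.  The
  Poisson-binomial PMF is computed exactly by an O(N²) dynamic-programming
  convolution (the subset-sum definition is exponential and survives only
  as a test oracle).  Values near 0 mean distributed/parallel processing,
  near 1 polarised/serial processing.
* **Cognitive demand** `L_t = −⅓(ΔU_t + ΔH_t + ΔJ_t) − ω_syn S_t`, where
  `U` is the per-subject min-max normalisation of `D^SP` (the
  "processing-mode potential"), `H` the posterior entropy normalised by
  ln C, `J` the Jensen-Shannon divergence between successive posteriors
  (natural log, normalised by ln 2) centred at its subject median,
  `S_t = |ΔU_t|·|ΔJ_t|` centred at its median (the synergy term), and
  `ω_syn` the mean absolute unweighted demand.  All differences at t = 0
  are 0.  Negative values mean rising demand.  The exact normalisation
  and centring of these components is a genuinely open design choice;
  the choices above (subject-level min-max and median centring) are
  pinned by the hand-computed example in the test suite.
* **Resource level** `R_t = (1−λ)R_{t−1} + αL_t`, `R_0 = 0`, with
  half-life `h = max(3, 2·Dwell_med)` (median dwell time in processing
  modes), `λ = 1 − 2^{−1/h}`, and gain `α = sqrt((1−(1−λ)²)/Var(L))`,
  chosen so the integrator's stationary variance matches unit-scaled
  demand (verified against a white-noise simulation in the test suite).
* **Serial bottleneck** multiplies mean serial-episode length by the mean
  rectified post-exit demand cost `max(0, −mean(L) over the next
  pe_delta = 3 bins)`, over episodes with a complete post-exit window.
  No episodes → 0 with a flag.  Cross-subject comparability uses a cohort
  median/MAD scaling manifest before the tanh squash; single-subject use
  falls back to `tanh(raw)`.

Unbounded series are robust-standardised, `z = (x − median)/(1.4826·MAD)`,
and squashed by tanh into [−1, 1].  A zero MAD yields a zero vector with a
warning.

## Thresholding

* **Gaussian-mixture intersections** solve the two-component log-density
  equality quadratic and keep the root between the component means,
  gated on both weights > 20% and a Cohen's-d-style separation
  `d = |m₂−m₁|/sqrt((s₁²+s₂²)/2) ≥ 1`; gate failure falls back to a KDE
  valley.
* **KDE valleys** smooth a high-resolution histogram (default 512 bins,
  Silverman bandwidth) after reflecting mass at both support boundaries,
  then take local density minima ranked by topographic prominence — the
  prominence ranking ignores spurious near-zero minima in empty tails.  A
  sensitivity sweep over {0.5×, 1×, 2×} bandwidth and {256, 512, 1024}
  bins reports the maximum drift.
* **Quartile bootstrap** robust-standardises the pooled metric and takes
  the 25th/75th percentiles, with 2000 subject-level bootstrap resamples
  for 95% CIs; acceptance requires the high–low CI to exclude 0 and
  separation d > 1 between the tails.
* **Adaptive posterior FDR** retains, per frame, the largest
  descending-`B` prefix whose mean posterior error (mean of 1−B) stays at
  or below α — a local-false-discovery prefix rule whose realised error is
  conservative by construction.  Benjamini-Hochberg on 1−B is available as
  an alternate mode.  The serial-parallel index never uses this
  selection; it always consumes the full `B` distribution.

In the study driver, the serial-parallel boundaries combine both
estimators: the mixture intersection provides the upper (mixed/serial)
boundary and a boundary-corrected KDE valley refines the lower
(parallel/mixed) boundary inside a configurable window, defaulting to
(0.45, 0.58).  When no valley exists there, the window widens to
everything below the upper boundary, then falls back to the lower mixture
root; the method actually used is recorded in the threshold manifest.

## Simulator

The generator emulates an event-related stop-signal task: 132 trials at
60% go / 40% stop (53 stop trials — at least the 50 the task design
requires), ISIs uniform in 2–6 s rescaled to the nominal run length, go
RTs uniform in 0.35–0.65 s, SSDs uniform in 0.10–0.40 s, and a fixed
SSRT of 0.25 s deciding stop success (`rt > ssd + ssrt`).  Per trial a
3-state Markov chain runs over the D delay bins with a trial-type-
conditioned initial distribution (go favours the low-positive state 1,
stop the salient state 0) and a regime-dependent stay probability —
0.90 / 0.70 / 0.50 for the low / medium / high *transition* regimes.
Observations are generated directly in the FIR domain: per subject, each
(state, node) amplitude is drawn once — state 0 ~ U(0.8, 1.2), state 1 ~
U(0.2, 0.5), state 2 ~ U(−0.8, 0.8) — and Gaussian noise with sd
{0.1, 0.2, 0.3, 0.4} (low → very high; multiples of the state-0 amplitude
half-width) is added per frame before per-node z-scoring.

What it does *not* emulate: voxel-level volumes, haemodynamic
convolution, physiological noise spectra, scanner drift, motion, or
spatial autocorrelation between nodes.  Within a subject and state the
emission is a single Gaussian around a fixed pattern, so the two-mixture
structure the model fits is driven by cross-subject amplitude diversity
in the global fit; at the subject level the responding/non-responding
split can become weight-degenerate.  Passing recovery tests on this
generator therefore demonstrates identifiability and alignment of the
state process under matched model and generator — not predictive
performance on empirical data, and not the empirical shape of the
metric distributions, which under these study conditions are more
polarised (posteriors close to one-hot, `ρ_t` nearly binary, `D^SP`
concentrated near its upper end) than real data would be.

## Study driver and problem sizes

`pipeline.run_simulation_study` balances the cohort over 3 transition
regimes × 4 noise levels.  The acceptance script uses 9 subjects per cell
(108 subjects) and 2000 bootstrap resamples; the test suite uses 4 per
cell (48) with 500 resamples.  These scales keep the full study in the
minutes range on a single core while the pooled frame counts (≥ 31,000)
make the threshold estimates stable.  All randomness flows from one seed
through spawned child streams, so identical seeds reproduce bit-identical
cohorts and fits.

## Known limitations

* Per-trial segmentation is the simplest way to keep the state process
  trial-aligned; delay-indexed transition matrices are a noted but
  unimplemented alternative.
* The bounded discrepancy uses a rank transform; any strictly monotone
  alternative would change the threshold location but not the flag
  ordering.
* With cohort-level median/MAD scaling of the bottleneck, the sign of the
  squashed value is relative to the cohort median, so roughly half of any
  cohort sits below zero by construction.
* Empirical-data ingestion expects pre-parcellated node time series; no
  NIfTI or preprocessing support.
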