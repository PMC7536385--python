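# Methods

`brainstates` analyses the temporal dynamics of whole-brain states in
network-averaged fMRI time series. The pipeline decodes a shared set of
discrete brain states from a multi-subject, multi-session cohort with a
Gaussian-emission hidden Markov model, then quantifies how the decoded
state dynamics differ between unconstrained rest and naturalistic (movie)
viewing, how consistent they are across participants and sessions, how
they couple to the stimulus and to autonomic physiology, and whether
individual differences in dynamics track individual differences in
subjective ratings. A synthetic-cohort generator with known ground truth
drives all tests.

## The model

Each run is reduced to a T x D matrix: one column per canonical brain
network (D = 14 by default), one row per TR (2.2 s). Runs from all
subjects, sessions and conditions are concatenated row-wise and modelled
by a single K-state HMM. Hidden state k emits a multivariate Gaussian
N(mu_k, Sigma_k) over the D networks with a full covariance; state
sequences follow a time-invariant K x K transition matrix. Fitting one
model to the concatenated cohort gives every run the same state
vocabulary, so dynamics can be compared across conditions.

Inference is maximum-likelihood EM (Baum-Welch). The forward-backward
recursion is segment-aware: each run is an independent observation
sequence that re-uses the shared initial-state distribution, and no
probability flows across run boundaries. The recursion is scaled per
timepoint, with emission log-densities shifted by their per-timepoint
maximum before exponentiation, so likelihoods cannot underflow. Decoding
uses the Viterbi algorithm in log space, with ties broken toward the
lowest state index (applied consistently during backtracking).

A variational-Bayes treatment of the same model exists in the literature;
this package deliberately uses maximum-likelihood point estimates because
every downstream quantity (state means, Viterbi paths, occupancies,
transition matrices) is defined on point estimates, and EM makes the fit
deterministic given a seed.

### Fitting choices

- **Restarts.** EM is restarted from several seeded initializations and the
  restart with the highest final log-likelihood wins. Each restart seeds a
  k-means clustering of a 2000-row subsample for the state means. Initial
  covariances are the pooled within-cluster covariance, shared across
  states: pooling matters because the raw global covariance mixes the
  between-state spread into the noise model, making the initial emission
  densities so flat that EM can collapse every state onto the grand mean
  when states are well separated. Initial transitions are sticky (0.9
  self, uniform off-diagonal); initial state probabilities are uniform.
- **Regularization.** Every M-step adds a ridge delta*I to each covariance
  with delta = 1e-6 tr(Sigma)/D, guarding against singular estimates when
  a state's occupancy gets small.
- **Convergence.** Relative log-likelihood change below 1e-6, or 500
  iterations. The stored trace always ends with the log-likelihood of the
  returned parameters, so an independent forward pass reproduces it
  exactly. The trace is non-decreasing up to the ridge's perturbation
  (tolerance 1e-6), and the test suite asserts this on every fit.

### Model-order selection

`select_states` fits each candidate K and recommends the AIC minimum,
AIC = 2k - 2 lnL with k = K·D + K·D(D+1)/2 + K(K-1) + (K-1), restricted to
candidates whose every state keeps a Viterbi fractional occupancy above an
occupancy floor (default 0.5%; models with effectively empty states are
over-parameterized regardless of their AIC).

Two practical caveats are documented because they shaped the defaults.
First, for Gaussian mixtures and HMMs the likelihood-ratio gain of a
spurious extra state is non-regular: empirically it runs near 2.5x the
extra parameter count, uncomfortably close to AIC's 2x penalty, and it
grows with the optimization effort spent on the over-parameterized
candidate because restarts search the space of spurious splits. The
selection study in the test suite therefore uses a single k-means-seeded
fit per candidate — a like-for-like comparison in which each candidate
gets the same optimization effort — at D = 14, where the per-state penalty
(2 x 126) has the most headroom. Second, AIC-based selection is most
reliable when the emission geometry is well separated; with heavily
overlapping states the recommendation degrades gracefully toward
neighbouring K.

### State alignment

Different fits label states arbitrarily. `align_states` matches two
parameter sets by maximizing the total Pearson correlation between paired
state-mean vectors via the Hungarian assignment, and the permutation is
applied consistently to means, covariances, transition matrices and
decoded paths.

## Dynamics, consistency, coupling, IS-RSA

- **Fractional occupancy** is the fraction of a run's TRs assigned to each
  state; **dwell time** is the mean duration of maximal same-state visit
  runs (reported in seconds). The figure-caption reading of dwell time as
  *total* time per state was rejected in favour of the procedural
  definition (mean visit duration); the conservation identity
  FO_k x T = sum of visit lengths ties the two together and is asserted in
  tests. **Empirical transition matrices** count consecutive pairs within a
  run only — concatenation boundaries contribute no pairs — and rows
  without outgoing transitions are masked, not zero-filled.
- **Group transition thresholding** keeps the top 20% of off-diagonal
  edges by group-mean weight, ties included.
- **Rest-vs-movie contrasts** use paired two-sided t-tests per state with
  Bonferroni correction over K. The transition-graph contrast is a
  network-based statistic: paired t per directed edge, threshold at a
  primary t (exposed as a parameter; no canonical value exists), weakly
  connected components scored by edge count, and family-wise error from a
  within-subject sign-flip null of maximum component sizes. When 2^n does
  not exceed the permutation budget the null is enumerated exactly, which
  makes small-n results reproducible against brute force.
- **Inter-subject consistency** re-expresses each path as K binary
  expression vectors. In a centred 9-volume window (19.8 s at TR 2.2 s,
  truncated at run edges) each state counts the subjects expressing it at
  least once; consistency is the maximal count as a percentage and the
  modal state breaks ties toward the lowest index. **Cross-session
  agreement** is the per-state Jaccard overlap of expression vectors,
  averaged over states present in at least one session; the multi-class
  path dissimilarity used for subject pairs is 1 minus the same average.
- **Stimulus coupling** binarizes half-open annotation intervals onto the
  TR grid (a TR is set if its window intersects any interval) and scores
  each state x category pair with the Szymkiewicz-Simpson overlap
  |a & b| / min(|a|, |b|) averaged over subjects. The null shuffles the
  annotation vector uniformly (one shared shuffle per iteration across
  subjects, since the statistic is the subject mean); a circular-shift
  mode is available as an autocorrelation-preserving alternative but is
  off by default. One-sided p = (1 + #{null >= obs}) / (n_perm + 1), a z
  score from the null moments, and Bonferroni control over the
  K x categories family (0.05 / 60 = 8.3e-4 at K = 10 with 6 categories).
- **Physiology** is segmented by the state path: delta_k is the state-mean
  minus the run-mean of the trace, so occupancy-weighted deltas sum to
  zero per subject exactly; the group test is a one-sample two-sided t
  against zero with Bonferroni over K.
- **IS-RSA** represents individual differences as subject-pairwise
  distance matrices: Euclidean for questionnaire ratings, correlation
  distance 1 - r (not 1 - |r|) for FO profiles and flattened off-diagonal
  transition profiles, Jaccard path dissimilarity for Viterbi paths.
  Correspondence is the Pearson correlation of strictly-lower triangles
  with a Mantel permutation test (joint row/column relabelling of the
  second matrix; exhaustive enumeration when n! fits the budget; one-sided
  toward positive association). Questionnaires are embedded by classical
  (Torgerson) MDS with a deterministic sign convention (largest-magnitude
  coordinate positive per axis).

## The synthetic cohort

The generator emulates the study design the analysis assumes: by default
14 subjects x 2 sessions, each session one rest run (220 volumes) and one
movie run (535 volumes) at TR 2.2 s over D = 14 networks, K = 10
generating states.

- **Emission geometry.** State means are near-orthogonal +/- pattern
  vectors (Hadamard rows truncated to D channels, orthonormalized when
  K <= D) scaled by `mean_separation` (default 2.0): each mean has norm
  `mean_separation` in units of the emission SD, so orthogonal pairs sit
  sqrt(2) x separation apart. Covariances are isotropic
  (`cov_scale` x I).
- **Rest regime.** Per-subject, per-session independent Markov chains
  concentrated on a small dominant set (states 5 and 9 by default,
  self-probability 0.9); 90% of the switching mass moves between dominant
  states and non-dominant states are brief transients. This reproduces
  bistable, subject-idiosyncratic rest dynamics: long dwells, two states
  above 5% occupancy, low inter-subject consistency.
- **Movie regime.** One master state sequence per cohort (sticky uniform
  chain, self-probability 0.75) shared by both sessions, degraded per
  subject and session by a circular shift of at most `jitter_tr` TRs and
  by per-TR flips with probability `flip_prob` (default 0.05). A flip is a
  momentary lapse: half land on a rest-dominant state, half deviate
  uniformly. Engagement couples to fidelity: a subject's flip rate is
  multiplied by (1 + 6 x `engagement_coupling` x (1 - engagement)), so
  disengaged subjects drift toward rest-like occupancy profiles. This is
  what makes occupancy distances track rating distances in the IS-RSA
  recovery tests; the multiplicative form preserves the exact noise-free
  limit (flip_prob = 0 and jitter = 0 give every subject the master path).
- **Physiology.** HR (baseline 70 bpm) and pupil diameter (baseline
  3.0 a.u.) are baseline + per-state offset + stationary AR(1) noise at
  TR resolution. Default offsets plant +5/-3 bpm on states 2/3 and
  +0.3/-0.4 a.u. on states 1/4. Pupil diameter additionally couples
  negatively to a shared slowly varying luminance track
  (PD = a - b x luminance + noise), reproducing the sign of the
  pupil-luminance association.
- **Questionnaire.** Four 1-5 ratings per subject; the latent is
  coupling x engagement + (1 - coupling) x independent uniform noise,
  discretized and clipped, with boredom inverted. Coupling 1 is
  deterministic and monotone; coupling 0 makes ratings independent of
  engagement (a null construction for calibration).

What the generator does **not** emulate: haemodynamic convolution and
autocorrelation of the BOLD signal, gradual state transitions or mixed
states, scanner drift and motion artefacts, voxel-level structure, eyeblink
artefacts, and annotation categories that only partially overlap their
states. Passing tests therefore demonstrate correctness of the machinery
and recoverability under the model's own assumptions, not robustness to
real-fMRI violations of them.

## Preprocessing

`prepare_run` applies, in fixed order: drop the first `drop_n` volumes
(default 5), zero-phase 4th-order Butterworth band-pass (default
0.01-0.15 Hz; the literature names only the band, the filter family is
this package's choice and is recorded in provenance), OLS confound
regression with an intercept, and per-column z-scoring to zero mean and
unit population SD. Each stage is recorded in the run's provenance.

One interaction matters for synthetic cohorts: per-run z-scoring is
state-dependent when a run expresses few states — a bistable rest run is
recentred by the mean of its two dominant states, shifting the same
generating state to different locations in different runs and breaking the
shared emission model. The orchestrated pipeline therefore defaults to no
re-standardization (the generator already emits standardized data), while
`prepare_run` keeps z-scoring on by default for externally supplied runs.

## Problem sizes and numerics

The test suite and the acceptance script scale their simulations to run on
a single CPU: parameter recovery uses K = 4, D = 6, 14 segments x 750 TRs;
the model-selection study uses K_true = 3, D = 14, 4 x 250 TRs, 20
replicates; calibration suites use 1000 replicates with 500 permutations;
the end-to-end acceptance run uses the full study dimensions (20,860 x 14
concatenated rows, K = 10, 15 EM restarts). Permutation p-values always
include the +1 correction in sampled mode and switch to exact enumeration
when the permutation group fits the budget (n! for Mantel, 2^n for
sign-flip nulls). Degenerate inputs (empty overlap vectors, unvisited
states, constant columns, zero-variance features) are reported as missing
or raised as errors naming the offending entity, never silently coerced.

## Known limitations

- AIC state-number selection is knife-edge against non-regular overfitting
  (above); on real data a variational or cross-validated criterion would
  be preferable.
- The NBS primary threshold is a free parameter; results should be
  reported across a small range of thresholds.
- Mean-correlation state alignment can mismatch states whose mean
  patterns are nearly collinear and differ mainly in covariance.
- The generator's engagement mechanism is one-dimensional; real rating
  structure is richer than a single latent engagement score.
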