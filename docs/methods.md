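# Methods

## Sequences and elementary statistics

A choice sequence is an ordered list of responses over a two-symbol alphabet
(default A/S), internally coded 0/1 by alphabet order. Text input accepts
whitespace, commas and semicolons as separators and is case-sensitive; CSV
input requires `subject_id, trial_index, response` with strictly increasing
trial indices per subject. Three scalar benchmarks are computed directly:
the response bias max(f_A, f_S) (accuracy of the best constant predictor,
never below 0.5), the alternation rate (fraction of consecutive pairs that
differ), and the 2×2 transition model. Transition rows with zero
observations report probability 0 in both cells plus an explicit
`row_observed` flag rather than NaN, keeping downstream arithmetic total
without hiding missing data.

## Transition prediction and its evaluation

The majority-transition predictor commits, for each previous response, to
the next response with the larger transition count. Two scoring conventions
keep every reported accuracy deterministic:

* **first trial** — no previous response exists, so resubstitution credits
  it with its chance expectation 0.5 (`expected_half`); a `seeded_guess`
  mode draws an actual guess for simulation realism;
* **ties / unseen contexts** — scored as expected credit 0.5, never an
  arbitrary symbol.

Under `expected_half`, overall accuracy = (0.5 + Σ credits over trials
2..n)/n, which on the ten-trial example gives exactly 60%/75%/65%.

Cross-validation splits trials into contiguous blocks in trial order.
Shuffled folds would place a test trial's neighbors in the training set and
leak exactly the sequential structure under study, so they are deliberately
not offered. A held-out trial's previous responses are observable history;
only the global first `lags` trials are unevaluable. The `linear_lagged`
predictor is a hinge-loss linear classifier (C = 1) on ±1 codes of the
previous m responses (default m = 1), mirroring the linear SVMs of
trial-wise decoding studies; with one lag and clean transition structure
its decisions coincide with the majority vote (tested as an equivalence
property).

`transition_oracle_accuracy` gives the ceiling Σ_prev π(prev)·max p(·|prev)
for a known transition matrix, with π the stationary distribution (for the
degenerate identity chain, where every distribution is stationary, the
uniform one is used) or explicit weights such as empirical previous-symbol
frequencies.

## Run-length analysis

Runs are maximal blocks of identical responses; n_runs = 1 + number of
alternations and run lengths sum to the sequence length (both are asserted
as properties). The final run is right-censored — the sequence ended, not
the phase — and is included by default with an `include_censored=False`
option; the goodness-of-fit tests on generated data exclude it.

Histograms are dense over k = 1..k_max. Pooling across subjects either sums
counts and renormalizes (`sum`) or averages per-subject relative
frequencies (`mean_rel_freq`, the default, matching the "average
frequencies" convention of group-level histograms). The two differ whenever
subjects contribute unequal run counts; a unit test pins an example.

Two fits are compared on the same relative frequencies:

* **exponential function** f(k) = a·e^(−bk), least squares via
  `scipy.optimize.curve_fit` seeded by a log-linear regression on the
  positive frequencies. A free curve with no normalization constraint.
* **exponential distribution / geometric mass**
  P(K=k) = (1−e^(−λ))·e^(−λ(k−1)), equal to geometric(p) with
  p = 1 − e^(−λ) (the discretization identity is asserted to 1e−12).
  Default fit is least squares on the relative frequencies — so its R² is
  comparable with the free curve's, both minimizing the same loss — with
  maximum likelihood on the raw run lengths as an option (the geometric MLE
  is p̂ = n_runs / total length).

R² is 1 − SS_res/SS_tot about the mean of the observed relative
frequencies; when SS_tot = 0 (flat data) R² is reported as not applicable
(None). Since the two-parameter family can only reduce the shared loss, R²
of the function fit is never below that of the distribution fit under least
squares — asserted on simulated histograms.

One subtlety the implementation surfaces explicitly: on data with an
inflated k = 1 bin (a mixture of geometric runs plus extra alternations),
the least-squares single-parameter fit chases the dominant k = 1 value and
its misfit appears as an *overestimate* of k = 2, whereas the distributional
(ML) fit — the canonical way to fit a probability distribution —
underestimates k = 1 directly. `compare_fits` takes a `distribution_method`
argument so both behaviors are inspectable; the mixture tests use ML.

## Permutation nulls

The null hypothesis is exchangeability of trial order (no sequential
dependence). Each permutation uniformly shuffles the symbols, preserving
marginal counts exactly — the response-bias benchmark is respected by
construction — and re-runs the identical evaluation. The p-value is
one-sided with the add-one rule, p = (1 + #{null ≥ observed})/(m + 1), so
p ∈ [1/(m+1), 1] and is never zero. Default m = 1000 gives desk-scale
resolution of 1e−3. A fast evaluator computes resubstitution accuracy from
the 2×2 pair counts alone (each row contributes max(row) credits, half its
total on a tie, plus 0.5 for the first trial); it is pinned against the
trace-based evaluation in a unit test.

`conditional_analysis` partitions evaluable trials by previous response and
reports per-context accuracy, class balance, and optional context-specific
permutation p-values; contexts with fewer than two trials are flagged
`insufficient` rather than dropped. `null_calibration` measures the
empirical type-I error on i.i.d. Bernoulli sequences; validity (empirical
size not exceeding α beyond binomial noise) rather than exactness is the
tested property, since permutation p-values are discrete and conservative
at small m.

## Generators

All generators are pure functions of their spec (including seed).

* `bernoulli(p)` — i.i.d.; p is the probability of the second alphabet
  symbol.
* `markov(switch)` — first symbol uniform, then switch with probability s.
  Because s is state-independent the sequence is vectorized as the start
  symbol XOR the running parity of i.i.d. switch indicators. Run lengths
  are geometric(s); default s = 0.6 emulates the human alternation bias.
* `criterion_shift(delta, sigma)` — latent evidence e_t ~ N(0, σ) compared
  to a criterion c_t; the criterion steps by +δ after the upper response
  and −δ after the lower one (c_1 = 0), a minimal fixed-step stabilization
  mechanism producing negative serial dependence. Defaults δ = 0.2,
  σ = 1.0 give an alternation rate modestly above 0.5, in the range
  observed for human sequence production; both are exposed because the
  mechanism family, not a particular parameterization, is the point.

## The undersampling confound experiment

Patterns are the minimal linear model sufficient to exhibit the confound:
trial t gets x_t = β·w·code(label) + N(0, σ²I_d) with w a fixed unit
direction, code ∈ {−1, +1}, and the label taken from the previous response,
the current response, or none (β effectively 0). Anything richer would be
untestable speculation about real measurement noise.

`balance_by_undersampling` removes majority current-class trials uniformly
at random — deliberately *not* stratified by previous response, because
that omission is the confound being modeled. The previous×current cell
counts of the retained trials are available for inspection and generally
remain unbalanced when the source chain alternates at s ≠ 0.5.

`confound_experiment` runs, per repetition: markov(s) sequence → patterns
with previous-response signal only → undersampling → cross-validated
(5-fold, stratified) linear decoding of the *current* response, plus a
β = 0 control under the same derived seeds. The default decoder is the
nearest-centroid (mean-difference) linear readout, which is the efficient
decoder for this isotropic single-direction Gaussian pattern model: it
keeps the demonstration limited by the transition imbalance itself (ceiling
= empirical switch rate, ≈ 0.6 at s = 0.6) rather than by decoder
estimation variance. A hinge-loss linear SVM (C = 1) is available via
`classifier="svm"`; it extracts the same confound, only less efficiently at
these sample sizes (≈ 0.545 vs ≈ 0.585 mean accuracy at the default
conditions of 200 trials, β = 2, σ = 1, d = 10). With s = 0.5 (balanced
transitions) the effect vanishes and both arms sit at chance.

## The prediction game

The game's predictor is an order-m back-off context model (default m = 3):
counts are kept for every suffix context of order 0..m; the prediction is
the majority continuation of the longest context with at least one
observation, with ties and unseen histories resolved by a seeded coin flip.
At m = 1 the model's counts equal the transition table of the history
(asserted). The running score is tested with an exact one-sided binomial
test against 0.5 — exact rather than approximate because sessions are
short. Sessions are replayable: (script, seed) determines the transcript
byte for byte.

## Problem sizes and numerical choices

Simulation-based tests use the smallest sizes at which the tested property
is clearly resolved: 1e5 symbols for law-of-large-numbers and
goodness-of-fit checks, 1e5 runs for ML recovery (tolerance 0.01), n = 1000
trials for cross-validation (Monte-Carlo tolerance ±0.04), 200 sequences ×
199 permutations for calibration, and 100 repetitions for the confound
experiment. Chi-square goodness-of-fit pools tail bins so every expected
count is ≥ 5 and uses zero degrees-of-freedom correction since the switch
probability is known, not estimated. The bounded 1-D least-squares search
for λ runs on [1e−9, 50] with xatol 1e−12; λ → ∞ (p = 1) is handled as a
point mass at k = 1.

## What the synthetic data does and does not show

The generators reproduce the *sequential statistics* of free-choice data —
alternation bias, geometric or short-run-inflated phase lengths, criterion
drift — but not reaction times, learning or fatigue trends, or any
measurement model of real neural data (no hemodynamics, no searchlight
geometry, no spatial noise correlations). Passing tests therefore establish
that the statistical machinery behaves correctly under known structure and
that the undersampling confound mechanism is real and quantifiable in a
minimal linear model; they do not quantify the confound's magnitude in any
particular empirical dataset.

## Known limitations

* Binary alphabets only; no timing analysis.
* The permutation scheme is a full uniform shuffle — appropriate for the
  exchangeability null, but not a test against richer nulls (e.g. fixed
  run-length multisets).
* Group-level histogram pooling conventions differ across the literature;
  both supported modes are simple averages, with no weighting by subject
  reliability.
* The confound experiment's effect sizes are self-calibrated within its
  minimal pattern model and should not be read as predictions for any
  specific neuroimaging pipeline.
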