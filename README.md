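# seqchoice

Sequential-dependency analysis of binary free-choice sequences.

When people repeatedly make a free binary choice — add or subtract, left or
right — their responses are rarely memoryless. Humans trying to behave
randomly alternate with probability ≈ 0.6 and over-produce short repetition
phases. Any trial-wise decoder (behavioral or neuroimaging) that claims to
predict the *upcoming* choice above a postulated 50% chance level can
therefore be confounded: part or all of the "prediction" may come from the
previous response carried forward. `seqchoice` provides the tools to detect,
quantify, and benchmark such sequential structure, and to test decoding
claims against nulls that respect it.

## What it computes

**Transition predictors.** For a sequence over alphabet {A, S}, the 2×2
transition counts n(prev→next) define a majority-vote predictor of the next
response. It is evaluated by resubstitution (with the unpredictable first
trial credited its chance expectation of ½) or by cross-validation over
contiguous trial blocks. A ten-trial example makes the point: the sequence
S,A,A,A,S,A,S,A,S,S has five As and five Ss (any constant predictor scores
50%), yet the transition predictor is correct 3/5 = 60% of the time after an
A, 3/4 = 75% after an S, and (0.5 + 6)/10 = 65% overall.

**Run-length (phase-length) analysis.** A run is a maximal block of identical
responses; under a memoryless switch process with switch probability *p*,
run lengths are geometric, P(K=k) = (1−p)^(k−1) p — exactly the
discretization of the exponential density with rate λ via p = 1 − e^(−λ)
(λ = 0.826 ↔ p ≈ 0.56). The package fits both a free two-parameter
exponential *function* a·e^(−bk) and the one-parameter exponential
*distribution* to a run-length histogram and compares them: only the latter
is the memoryless null, and on alternation-biased data it underestimates the
frequency of short phases no matter how well the free curve fits.

**Permutation nulls.** Instead of a postulated 50% chance level, prediction
accuracy is tested against the distribution obtained by uniformly shuffling
trial order — preserving the marginal response counts (the response-bias
benchmark) while destroying sequential structure — with the add-one rule
p = (1 + #{null ≥ observed})/(m + 1). Conditional-on-previous-response
analyses and a type-I-error calibration harness are included.

**The class-balancing confound.** Trial-wise decoding pipelines often
undersample the majority *current*-response class to balance it. If feature
patterns carry a signal of the *previous* response only, and transitions are
unbalanced (alternation bias), the previous×current cells remain unbalanced
after class balancing — and a linear decoder of the current response scores
above chance with zero genuine current-choice information.
`confound_experiment` demonstrates this end to end against a matched
no-signal control.

**Generators and a game.** Seeded Bernoulli, Markov (switch-probability),
and criterion-shift sequence generators with known structure; and
`seqchoice play`, an interactive "flip a coin in your head" game in which an
online back-off context model predicts your next keypress and tracks an
exact binomial p-value against chance.

## Worked example

```bash
$ printf 'SAAASASASS' > worked.txt
$ seqchoice analyze --input worked.txt --permutations 999 --seed 1 --report report.json
```

The report contains (abridged):

```
counts              {"A": 5, "S": 5}          # balanced marginals: bias 0.5
n_pairs             9
alternation_rate    0.667                     # 6 of the 9 pairs switch
transition_counts   {"A->A": 2, "A->S": 3, "S->A": 3, "S->S": 1}
resubstitution      {"conditional_accuracy": {"A": 0.6, "S": 0.75},
                     "overall_accuracy": 0.65}
oracle_accuracy_empirical_weights   0.667     # (5/9)*0.6 + (4/9)*0.75
permutation         {"observed_accuracy": 0.65, "p_value": 0.543}
```

Reading: although the marginals look like a fair coin, the transition
predictor reaches 65% — but at n = 10 the permutation test (p = 0.543)
rightly declines to call that evidence of sequential dependence; with 300
trials of a switch-0.8 process the same test returns p ≤ 0.001.

The same pipeline is available from Python:

```python
from seqchoice import parse_sequence, evaluate_resubstitution
rep = evaluate_resubstitution(parse_sequence("SAAASASASS"))
rep.conditional_accuracy  # {'A': 0.6, 'S': 0.75}
rep.overall_accuracy      # 0.65
```

Other commands: `seqchoice predict`, `seqchoice runlength`,
`seqchoice permtest`, `seqchoice simulate`, `seqchoice confound`,
`seqchoice play` (try `--script` for replayable sessions). See
`seqchoice COMMAND --help`.

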