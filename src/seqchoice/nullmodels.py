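"""Permutation-test null distributions for sequential prediction accuracy.

Above-chance next-response decoding is only meaningful against a null that
respects the observable benchmarks of the sequence — in particular its
response bias. Rather than postulating a 50% chance level, the permutation
null uniformly shuffles trial order: marginal response counts are preserved
by construction while all sequential structure is destroyed. The identical
evaluation is re-run on each shuffled sequence, and the p-value uses the
add-one rule p = (1 + #{null >= observed}) / (m + 1), so it is one-sided,
never zero, and never exceeds 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .predictors import evaluate_resubstitution, resubstitution_accuracy
from .sequence import ChoiceSequence

__all__ = [
    "PermutationResult",
    "ConditionalContextReport",
    "permutation_test",
    "conditional_analysis",
    "null_calibration",
]

Evaluator = Callable[[ChoiceSequence], float]


@dataclass
class PermutationResult:
    """Observed accuracy, its permutation null, and the add-one p-value."""

    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    scheme: str = "full_shuffle"

    def null_quantiles(self, qs=(0.05, 0.25, 0.5, 0.75, 0.95)) -> dict[float, float]:
        return {q: float(np.quantile(self.null_accuracies, q)) for q in qs}

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "observed_accuracy": float(self.observed_accuracy),
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
            "seed": int(self.seed),
            "scheme": self.scheme,
            "null_quantiles": {str(q): v for q, v in self.null_quantiles().items()},
        }
        if include_null:
            out["null_accuracies"] = self.null_accuracies.tolist()
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _default_evaluator(seq: ChoiceSequence) -> float:
    return resubstitution_accuracy(seq.codes())


def permutation_test(
    seq: ChoiceSequence,
    evaluator: Evaluator | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of sequential prediction accuracy.

    ``evaluator`` maps a sequence to an accuracy; the default is the overall
    resubstitution accuracy of the majority-transition predictor. Each of the
    ``n_permutations`` null draws uniformly shuffles the symbol order (same
    marginal counts, no sequential structure) and re-runs the identical
    evaluation. Identical seeds reproduce the null list exactly.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    evaluator = evaluator or _default_evaluator
    observed = float(evaluator(seq))
    rng = np.random.default_rng(seed)
    codes = seq.codes()
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(codes)
        null[i] = evaluator(
            ChoiceSequence.from_codes(perm, seq.alphabet, seq.subject_id)
        )
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass
class ConditionalContextReport:
    """Per-previous-response context: accuracy, class balance, optional null."""

    context: str
    n_trials: int
    accuracy: float | None
    class_balance: dict[str, int] = field(default_factory=dict)
    p_value: float | None = None
    insufficient: bool = False

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "n_trials": self.n_trials,
            "accuracy": self.accuracy,
            "class_balance": dict(self.class_balance),
            "p_value": self.p_value,
            "insufficient": self.insufficient,
        }


def _conditional_accuracies(seq: ChoiceSequence) -> dict[str, tuple[float, int]]:
    rep = evaluate_resubstitution(seq)
    return {
        a: (rep.conditional_accuracy[a], rep.conditional_n[a]) for a in seq.alphabet
    }


def conditional_analysis(
    seq: ChoiceSequence,
    n_permutations: int = 0,
    seed: int = 0,
) -> dict[str, ConditionalContextReport]:
    """Separate accuracy analyses conditional on the previous response.

    Evaluable trials (2..n) are partitioned by their previous response; each
    context gets its own accuracy, the class balance of actual responses in
    that context, and — when ``n_permutations > 0`` — a context-specific
    permutation p-value. Contexts with fewer than 2 trials are flagged
    ``insufficient`` rather than dropped.
    """
    rep = evaluate_resubstitution(seq)
    reports: dict[str, ConditionalContextReport] = {}
    # class balance of actual responses within each context
    balance: dict[str, dict[str, int]] = {a: {b: 0 for b in seq.alphabet} for a in seq.alphabet}
    for prev, _pred, actual, _c in rep.per_trial_trace[1:]:
        balance[prev][actual] += 1

    nulls: dict[str, list[float]] | None = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        codes = seq.codes()
        nulls = {a: [] for a in seq.alphabet}
        for _ in range(n_permutations):
            perm_seq = ChoiceSequence.from_codes(
                rng.permutation(codes), seq.alphabet, seq.subject_id
            )
            for a, (acc, n) in _conditional_accuracies(perm_seq).items():
                if n:
                    nulls[a].append(acc)

    for a in seq.alphabet:
        n = rep.conditional_n[a]
        if n < 2:
            reports[a] = ConditionalContextReport(
                context=a, n_trials=n,
                accuracy=rep.conditional_accuracy[a] if n else None,
                class_balance=balance[a], insufficient=True,
            )
            continue
        p = None
        if nulls is not None and nulls[a]:
            arr = np.asarray(nulls[a])
            p = float((1 + np.sum(arr >= rep.conditional_accuracy[a])) / (len(arr) + 1))
        reports[a] = ConditionalContextReport(
            context=a, n_trials=n, accuracy=rep.conditional_accuracy[a],
            class_balance=balance[a], p_value=p,
        )
    return reports


@dataclass
class CalibrationReport:
    """Empirical type-I error of the permutation test under an i.i.d. null."""

    alpha: float
    rejection_rate: float
    p_values: np.ndarray
    n_sequences: int
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "rejection_rate": self.rejection_rate,
            "n_sequences": self.n_sequences,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def null_calibration(
    n_sequences: int = 200,
    sequence_length: int = 200,
    p: float = 0.5,
    n_permutations: int = 199,
    alpha: float = 0.05,
    evaluator: Evaluator | None = None,
    seed: int = 0,
    alphabet: tuple[str, str] = ("A", "S"),
) -> CalibrationReport:
    """Simulate i.i.d. Bernoulli sequences (no sequential dependence), run the
    permutation test on each, and report the fraction of p-values <= alpha.

    For a calibrated test this empirical type-I error rate is close to alpha
    (the permutation p-value is valid, i.e. stochastically >= uniform, so the
    rate should not exceed alpha by more than binomial noise).
    """
    ss = np.random.SeedSequence(seed)
    gen_rng = np.random.default_rng(ss.spawn(1)[0])
    perm_seeds = gen_rng.integers(2**31, size=n_sequences)
    pvals = np.empty(n_sequences)
    for i in range(n_sequences):
        codes = (gen_rng.random(sequence_length) < p).astype(np.int8)
        seq = ChoiceSequence.from_codes(codes, alphabet)
        res = permutation_test(
            seq, evaluator=evaluator, n_permutations=n_permutations,
            seed=int(perm_seeds[i]),
        )
        pvals[i] = res.p_value
    return CalibrationReport(
        alpha=alpha,
        rejection_rate=float(np.mean(pvals <= alpha)),
        p_values=pvals,
        n_sequences=n_sequences,
        n_permutations=n_permutations,
        seed=seed,
    )
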