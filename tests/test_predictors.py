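"""Transition predictors and their resubstitution / cross-validated
evaluation, anchored on the ten-trial worked example."""

import numpy as np
import pytest

from seqchoice import (
    GeneratorSpec,
    MarkovPredictor,
    evaluate_crossvalidated,
    evaluate_resubstitution,
    generate,
    majority_transition_predictor,
    parse_sequence,
    transition_counts,
    transition_oracle_accuracy,
)
from seqchoice.predictors import resubstitution_accuracy


class TestMajorityPredictor:
    def test_worked_example_votes(self, worked_sequence):
        pred = majority_transition_predictor(transition_counts(worked_sequence))
        assert pred.predict_with_abstention(["A"]) == ["S"]  # A->S 3 > A->A 2
        assert pred.predict_with_abstention(["S"]) == ["A"]  # S->A 3 > S->S 1

    def test_constant_sequence_votes_repeat(self):
        pred = majority_transition_predictor(transition_counts(parse_sequence("AAAA")))
        assert pred.predict_with_abstention(["A"]) == ["A"]

    def test_tie_is_uncommitted(self):
        # "ASSA": S->S = 1 and S->A = 1, so the S context is tied
        pred = majority_transition_predictor(transition_counts(parse_sequence("ASSA")))
        assert pred.predict_with_abstention(["S"]) == [None]
        assert pred.predict_with_abstention(["A"]) == ["S"]

    def test_sklearn_fit_predict_roundtrip(self, worked_sequence):
        sym = worked_sequence.symbols
        est = MarkovPredictor().fit(list(sym[:-1]), list(sym[1:]))
        assert est.predict(["A", "S"]).tolist() == ["S", "A"]
        assert est.get_params() == {"random_state": None}


class TestResubstitution:
    def test_worked_example_exact(self, worked_sequence):
        rep = evaluate_resubstitution(worked_sequence)
        assert rep.conditional_accuracy["A"] == 0.6  # 3 of 5 after an A
        assert rep.conditional_accuracy["S"] == 0.75  # 3 of 4 after an S
        assert rep.overall_accuracy == 0.65  # (0.5 + 6) / 10
        assert rep.conditional_n == {"A": 5, "S": 4}

    def test_overall_recombines_from_conditionals(self, worked_sequence):
        rep = evaluate_resubstitution(worked_sequence)
        n = rep.n_trials
        weighted = sum(
            rep.conditional_accuracy[a] * rep.conditional_n[a] for a in ("A", "S")
        )
        assert weighted / (n - 1) == pytest.approx(
            (rep.overall_accuracy * n - 0.5) / (n - 1)
        )

    def test_conditional_rows_at_least_half(self, rng):
        # majority rule cannot score below 0.5 on its own training row
        for _ in range(50):
            n = int(rng.integers(2, 40))
            seq = parse_sequence(
                "".join(rng.choice(["A", "S"], size=n)) if n else "A"
            )
            rep = evaluate_resubstitution(seq)
            for a in ("A", "S"):
                if rep.conditional_n[a] >= 1:
                    assert rep.conditional_accuracy[a] >= 0.5

    def test_seeded_guess_policy_is_reproducible(self, worked_sequence):
        r1 = evaluate_resubstitution(worked_sequence, "seeded_guess", seed=7)
        r2 = evaluate_resubstitution(worked_sequence, "seeded_guess", seed=7)
        assert r1.overall_accuracy == r2.overall_accuracy

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            evaluate_resubstitution(parse_sequence("A"))

    def test_fast_path_matches_trace_evaluation(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 60))
            seq = parse_sequence("".join(rng.choice(["A", "S"], size=n)))
            assert resubstitution_accuracy(seq.codes()) == pytest.approx(
                evaluate_resubstitution(seq).overall_accuracy
            )


class TestCrossValidation:
    def test_iid_sequence_near_chance(self):
        # expectation over sequences: any single i.i.d. draw can carry an
        # accidental (and genuinely exploitable) alternation excess
        accs = [
            evaluate_crossvalidated(
                generate(GeneratorSpec("bernoulli", 1000, seed, {"p": 0.5})),
                k_folds=10,
            ).overall_accuracy
            for seed in range(21, 31)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.04

    def test_markov_sequence_tracks_switch_probability(self):
        seq = generate(GeneratorSpec("markov", 1000, 22, {"switch": 0.8}))
        rep = evaluate_crossvalidated(seq, k_folds=10)
        assert abs(rep.overall_accuracy - 0.8) < 0.04

    def test_perfect_alternation_fully_predictable(self):
        seq = parse_sequence("AS" * 50)
        for kind in ("markov", "linear_lagged"):
            rep = evaluate_crossvalidated(seq, k_folds=10, predictor_kind=kind)
            assert rep.overall_accuracy == 1.0

    def test_too_short_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="length >= 20"):
            evaluate_crossvalidated(parse_sequence("ASAS"), k_folds=10)

    def test_linear_lag1_matches_markov_on_large_markov_data(self):
        # oracle equivalence: with one lag and clean transition structure the
        # maximum-margin classifier must reproduce the majority vote
        seq = generate(GeneratorSpec("markov", 2000, 23, {"switch": 0.7}))
        m = evaluate_crossvalidated(seq, k_folds=5, predictor_kind="markov")
        l = evaluate_crossvalidated(seq, k_folds=5, predictor_kind="linear_lagged")
        pm = [p for _, p, _, _ in m.per_trial_trace]
        pl = [p for _, p, _, _ in l.per_trial_trace]
        assert pm == pl

    def test_iid_mean_accuracy_over_many_sequences(self):
        # over 200 sequences of 500 i.i.d. trials CV accuracy centres on 0.5
        accs = []
        for i in range(200):
            seq = generate(GeneratorSpec("bernoulli", 500, 10_000 + i, {"p": 0.5}))
            accs.append(evaluate_crossvalidated(seq, k_folds=10).overall_accuracy)
        assert 0.48 <= np.mean(accs) <= 0.52


class TestOracleAccuracy:
    def test_symmetric_chain(self):
        P = np.array([[0.7, 0.3], [0.3, 0.7]])
        assert transition_oracle_accuracy(P) == pytest.approx(0.7)

    def test_iid_chain_is_chance(self):
        P = np.full((2, 2), 0.5)
        assert transition_oracle_accuracy(P) == pytest.approx(0.5)

    def test_worked_example_with_empirical_weights(self, worked_sequence):
        tm = transition_counts(worked_sequence)
        w = tm.counts.sum(axis=1) / tm.n_pairs  # previous-symbol weights 5/9, 4/9
        acc = transition_oracle_accuracy(tm, weights=w)
        assert acc == pytest.approx((5 / 9) * 0.6 + (4 / 9) * 0.75)

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            transition_oracle_accuracy(np.array([[0.5, 0.4], [0.5, 0.5]]))
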