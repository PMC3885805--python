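"""Interactive "flip a coin in your head" choice-prediction game.

Before each keypress an online back-off context model predicts the player's
next response; afterwards the prediction is revealed, the model updates, and
the running accuracy is tested against the 50% chance level with an exact
one-sided binomial test. Humans trying to behave randomly alternate too
often and repeat context patterns, so the model typically beats chance
within a few dozen trials.

The model keeps counts for every context of order 0..m (default m=3) over
the response history. To predict, it takes the LONGEST context with at least
one observation and votes for the majority continuation; ties and unseen
histories fall back to a seeded coin flip. Sessions are fully replayable: a
scripted input plus a seed reproduces the transcript byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
from scipy.stats import binomtest

from .sequence import ChoiceSequence

__all__ = ["ContextModel", "GameState", "play_game"]


class ContextModel:
    """Online back-off context model over a binary alphabet.

    Maintains continuation counts for every suffix context of order 0..m.
    At order m=1 the counts reduce exactly to the first-order transition
    table of the history consumed so far.
    """

    def __init__(self, max_order: int = 3):
        if max_order < 0:
            raise ValueError("max_order must be >= 0")
        self.max_order = max_order
        self.counts: dict[tuple[int, ...], np.ndarray] = {}

    def predict(self, history: list[int]) -> int | None:
        """Majority continuation of the longest observed context, or None."""
        for order in range(min(self.max_order, len(history)), -1, -1):
            ctx = tuple(history[len(history) - order :])
            row = self.counts.get(ctx)
            if row is None or row.sum() == 0:
                continue
            if row[0] == row[1]:
                return None  # observed but tied
            return int(row.argmax())
        return None

    def update(self, history: list[int], symbol: int) -> None:
        """Record ``symbol`` as the continuation of every suffix of history."""
        for order in range(0, min(self.max_order, len(history)) + 1):
            ctx = tuple(history[len(history) - order :])
            row = self.counts.setdefault(ctx, np.zeros(2, dtype=int))
            row[symbol] += 1


@dataclass
class GameState:
    """State of one prediction-game session."""

    history: list[int] = field(default_factory=list)
    model: ContextModel = field(default_factory=ContextModel)
    trials_played: int = 0
    trials_predicted_correctly: int = 0
    alphabet: tuple[str, str] = ("A", "S")

    @property
    def accuracy(self) -> float | None:
        if self.trials_played == 0:
            return None
        return self.trials_predicted_correctly / self.trials_played

    @property
    def p_value(self) -> float | None:
        """Exact one-sided binomial p-value of the running score vs chance 0.5."""
        if self.trials_played == 0:
            return None
        return float(
            binomtest(
                self.trials_predicted_correctly, self.trials_played, 0.5,
                alternative="greater",
            ).pvalue
        )

    def sequence(self) -> ChoiceSequence:
        return ChoiceSequence.from_codes(np.array(self.history), self.alphabet)


def play_game(
    keys: Iterable[str],
    max_order: int = 3,
    seed: int = 0,
    alphabet: tuple[str, str] = ("A", "S"),
    out: IO[str] | None = None,
    quit_keys: tuple[str, ...] = ("q", "Q"),
) -> tuple[GameState, str]:
    """Run a (scripted or interactive) prediction-game session.

    ``keys`` yields raw keypresses; symbols outside the alphabet (other than a
    quit key) repeat the prompt and are not counted. Returns the final
    :class:`GameState` and the full transcript; the transcript is a pure
    function of (keys, max_order, seed).
    """
    rng = np.random.default_rng(seed)
    state = GameState(model=ContextModel(max_order), alphabet=tuple(alphabet))
    lines: list[str] = [
        f"Try to be random! Press {alphabet[0]} or {alphabet[1]} "
        f"({'/'.join(quit_keys[:1])} to quit)."
    ]
    it: Iterator[str] = iter(keys)
    for key in it:
        key = key.strip()
        if not key:
            continue
        if key in quit_keys:
            break
        if key not in alphabet:
            lines.append(f"invalid key {key!r}: press {alphabet[0]}, {alphabet[1]} or q")
            continue
        predicted = state.model.predict(state.history)
        committed = predicted is not None
        if predicted is None:
            predicted = int(rng.integers(2))
        actual = alphabet.index(key)
        correct = predicted == actual
        state.model.update(state.history, actual)
        state.history.append(actual)
        state.trials_played += 1
        state.trials_predicted_correctly += int(correct)
        p = state.p_value
        lines.append(
            f"trial {state.trials_played:3d}: you={alphabet[actual]} "
            f"predicted={alphabet[predicted]}{'' if committed else '*'} "
            f"{'HIT ' if correct else 'miss'} "
            f"score={state.trials_predicted_correctly}/{state.trials_played} "
            f"({100 * state.accuracy:.1f}%) p={p:.4f}"
        )
    if state.trials_played:
        lines.append(
            f"final: {state.trials_predicted_correctly}/{state.trials_played} correct "
            f"({100 * state.accuracy:.1f}%), exact binomial p={state.p_value:.4f} "
            "vs 50% chance"
        )
    else:
        lines.append("no trials played.")
    transcript = "\n".join(lines) + "\n"
    if out is not None:
        out.write(transcript)
    return state, transcript
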