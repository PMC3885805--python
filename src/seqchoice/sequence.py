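"""Binary choice sequences and elementary sequential statistics.

A :class:`ChoiceSequence` holds one subject's ordered binary responses over a
two-symbol alphabet (default ``("A", "S")``, e.g. freely choosing addition or
subtraction). The module provides parsing from plain text and CSV, plus the
basic statistics that any sequential-dependency analysis starts from: the
response bias (accuracy of the best constant predictor), the alternation rate,
and the 2x2 first-order transition model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChoiceSequence",
    "TransitionModel",
    "parse_sequence",
    "read_sequence_file",
    "read_sequences_csv",
    "write_sequence_file",
    "transition_counts",
    "response_bias",
    "alternation_rate",
]

#: The worked-example sequence of ten free addition/subtraction choices used
#: throughout the documentation and tests.
WORKED_EXAMPLE = "SAAASASASS"

# Characters silently accepted as separators in text input.
_SEPARATORS = set(" \t\r\n,;")


@dataclass(frozen=True)
class ChoiceSequence:
    """An ordered binary response sequence for one subject/session.

    Parameters
    ----------
    symbols : tuple of str
        Responses, in trial order. Every element must belong to ``alphabet``.
    alphabet : (str, str)
        The two admissible response symbols, in canonical order. Symbols are
        internally encoded 0/1 by alphabet position.
    subject_id : str, optional
        Label carried through pooling and reports.
    """

    symbols: tuple[str, ...]
    alphabet: tuple[str, str] = ("A", "S")
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.alphabet) != 2 or self.alphabet[0] == self.alphabet[1]:
            raise ValueError(
                f"alphabet must hold exactly 2 distinct symbols, got {self.alphabet!r}"
            )
        if len(self.symbols) < 1:
            raise ValueError("a ChoiceSequence needs at least one response")
        allowed = set(self.alphabet)
        for i, s in enumerate(self.symbols, start=1):
            if s not in allowed:
                raise ValueError(
                    f"symbol {s!r} at position {i} is not in alphabet {self.alphabet!r}"
                )
        # normalize to tuples so instances hash and compare by value
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "alphabet", tuple(self.alphabet))

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __str__(self) -> str:
        return "".join(self.symbols)

    def codes(self) -> np.ndarray:
        """Responses encoded 0/1 by alphabet order, as an int8 array."""
        lookup = {self.alphabet[0]: 0, self.alphabet[1]: 1}
        return np.fromiter((lookup[s] for s in self.symbols), dtype=np.int8,
                           count=len(self.symbols))

    @classmethod
    def from_codes(
        cls,
        codes: Sequence[int] | np.ndarray,
        alphabet: tuple[str, str] = ("A", "S"),
        subject_id: str | None = None,
    ) -> "ChoiceSequence":
        """Build a sequence from a 0/1 integer array."""
        arr = np.asarray(codes)
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("codes must be 0 or 1")
        return cls(tuple(alphabet[int(c)] for c in arr), tuple(alphabet), subject_id)


@dataclass(frozen=True)
class TransitionModel:
    """First-order (2x2) transition counts and conditional probabilities.

    ``counts[i, j]`` is the number of consecutive pairs whose previous response
    is ``alphabet[i]`` and next response is ``alphabet[j]``. ``probabilities``
    are the row-normalized counts; a row with zero observations carries
    probability 0 in both cells and is flagged in ``row_observed``.
    """

    counts: np.ndarray
    probabilities: np.ndarray
    n_pairs: int
    marginal: np.ndarray
    alphabet: tuple[str, str]
    row_observed: np.ndarray = field(default_factory=lambda: np.array([True, True]))

    def count(self, prev: str, nxt: str) -> int:
        i, j = self.alphabet.index(prev), self.alphabet.index(nxt)
        return int(self.counts[i, j])

    def probability(self, nxt: str, prev: str) -> float:
        """Conditional probability p(next | previous)."""
        i, j = self.alphabet.index(prev), self.alphabet.index(nxt)
        return float(self.probabilities[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.alphabet),
                            columns=list(self.alphabet))


def parse_sequence(
    text: str,
    alphabet: tuple[str, str] = ("A", "S"),
    subject_id: str | None = None,
) -> ChoiceSequence:
    """Parse a response sequence from text.

    Whitespace, commas and semicolons are accepted as separators; matching is
    case-sensitive. Any other character is rejected with its symbol position
    (1-based, counting accepted symbols).

    >>> len(parse_sequence("SAAASASASS"))
    10
    """
    symbols: list[str] = []
    allowed = set(alphabet)
    for ch in text:
        if ch in _SEPARATORS:
            continue
        if ch not in allowed:
            raise ValueError(
                f"invalid symbol {ch!r} at position {len(symbols) + 1}: "
                f"expected one of {alphabet!r}"
            )
        symbols.append(ch)
    if not symbols:
        raise ValueError("empty input: no response symbols found")
    return ChoiceSequence(tuple(symbols), tuple(alphabet), subject_id)


def read_sequence_file(
    path: str | Path, alphabet: tuple[str, str] = ("A", "S")
) -> ChoiceSequence:
    """Read a plain-text sequence file (one symbol per line or one string)."""
    text = Path(path).read_text()
    try:
        return parse_sequence(text, alphabet)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_sequence_file(seq: ChoiceSequence, path: str | Path) -> None:
    """Write a sequence as one symbol per line."""
    Path(path).write_text("\n".join(seq.symbols) + "\n")


def read_sequences_csv(
    path: str | Path, alphabet: tuple[str, str] = ("A", "S")
) -> list[ChoiceSequence]:
    """Read sequences from a CSV with columns subject_id, trial_index, response.

    ``trial_index`` must be strictly increasing within each subject; rows are
    grouped by ``subject_id`` in order of first appearance.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "response": str})
    required = {"subject_id", "trial_index", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out: list[ChoiceSequence] = []
    for sid in df["subject_id"].unique():
        block = df[df["subject_id"] == sid]
        idx = block["trial_index"].to_numpy()
        if not (np.diff(idx) > 0).all():
            raise ValueError(
                f"{path}: trial_index not strictly increasing for subject {sid!r}"
            )
        try:
            out.append(
                ChoiceSequence(tuple(block["response"]), tuple(alphabet), sid)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: subject {sid!r}: {exc}") from exc
    return out


def transition_counts(seq: ChoiceSequence) -> TransitionModel:
    """Tabulate all consecutive response pairs into a 2x2 transition model.

    Requires at least two trials (one pair). The sum of the count table equals
    ``len(seq) - 1``.
    """
    if len(seq) < 2:
        raise ValueError("transition counts need a sequence of length >= 2 (no pairs)")
    codes = seq.codes()
    prev, nxt = codes[:-1], codes[1:]
    counts = np.bincount(prev * 2 + nxt, minlength=4).reshape(2, 2)
    row_totals = counts.sum(axis=1)
    row_observed = row_totals > 0
    probabilities = np.zeros((2, 2), dtype=float)
    for i in range(2):
        if row_observed[i]:
            probabilities[i] = counts[i] / row_totals[i]
    marginal = np.bincount(codes, minlength=2)
    return TransitionModel(
        counts=counts,
        probabilities=probabilities,
        n_pairs=int(counts.sum()),
        marginal=marginal,
        alphabet=seq.alphabet,
        row_observed=row_observed,
    )


def response_bias(seq: ChoiceSequence) -> float:
    """max(f_A, f_S): accuracy of the best constant predictor. Always >= 0.5."""
    codes = seq.codes()
    f1 = codes.mean()
    return float(max(f1, 1.0 - f1))


def alternation_rate(seq: ChoiceSequence) -> float:
    """Fraction of consecutive pairs whose two symbols differ.

    Humans asked to behave randomly typically alternate with probability
    around 0.6 rather than the memoryless 0.5.
    """
    if len(seq) < 2:
        raise ValueError("alternation rate needs a sequence of length >= 2")
    codes = seq.codes()
    return float((codes[:-1] != codes[1:]).mean())
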