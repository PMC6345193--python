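"""Adaptive word-span task: administration logic and scoring.

The task presents spoken word sequences and asks the child to repeat them
in order.  Sequence length is adjusted by performance (an adaptive
staircase): two *calibration* items adapt after every item, the following
*test* items adapt after every completed pair.  A correct repetition earns
points equal to the sequence length; an incorrect one earns length minus
one.  The span score for a condition is the mean of the test-item points.

Everything here is deterministic given the responder's sequence of
correct/incorrect decisions, which makes exhaustive enumeration of all
response patterns feasible (:func:`enumerate_score_range`) and lets
recorded administrations be replayed bit-for-bit (:func:`replay`).
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

from .exceptions import (
    BoundsError,
    ConfigError,
    EnumerationSizeError,
    StructuralError,
    UsageError,
)

CALIBRATION = "calibration"
TEST = "test"

WORD_LENGTHS = ("short", "long")
LEXICALITIES = ("real", "pseudo")

#: The four task conditions in fixed administration order of the length
#: factor (short before long); lexicality order is assigned per child.
CONDITIONS = tuple(
    (length, lex) for length in WORD_LENGTHS for lex in LEXICALITIES
)


@dataclass(frozen=True)
class EngineConfig:
    """Parameters of the adaptive administration.

    ``presentation_rate_s``, ``pool_words`` and ``sequences_per_length``
    are stimulus-material metadata carried along for documentation; the
    scoring logic never depends on them.
    """

    min_length: int = 2
    max_length: int = 8
    n_calibration: int = 2
    n_test: int = 8
    start_length: int = 3
    presentation_rate_s: float = 1.5
    pool_words: int = 9
    sequences_per_length: int = 11

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ConfigError(f"min_length must be >= 1, got {self.min_length}")
        if self.max_length < self.min_length:
            raise ConfigError(
                f"max_length ({self.max_length}) < min_length ({self.min_length})"
            )
        if not self.min_length <= self.start_length <= self.max_length:
            raise ConfigError(
                f"start_length {self.start_length} outside "
                f"[{self.min_length}, {self.max_length}]"
            )
        if self.n_calibration < 0 or self.n_test < 1:
            raise ConfigError("need n_calibration >= 0 and n_test >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_calibration + self.n_test


DEFAULT_CONFIG = EngineConfig()


@dataclass(frozen=True)
class TrialOutcome:
    """One presented sequence: its phase, length, and point award."""

    phase: str
    index: int
    length: int
    correct: bool
    points: int


@dataclass(frozen=True)
class AdministrationRecord:
    """A full adaptive run for one condition, with its span score."""

    condition: tuple[str, str]
    trials: tuple[TrialOutcome, ...]
    span_score: float
    config: EngineConfig = DEFAULT_CONFIG

    @property
    def test_trials(self) -> tuple[TrialOutcome, ...]:
        return tuple(t for t in self.trials if t.phase == TEST)

    @property
    def response_pattern(self) -> tuple[bool, ...]:
        return tuple(t.correct for t in self.trials)


def score_trial(length: int, correct: bool, config: EngineConfig = DEFAULT_CONFIG) -> int:
    """Points for one repetition: ``length`` if correct, ``length - 1`` if not."""
    if not config.min_length <= length <= config.max_length:
        raise BoundsError(
            f"length {length} outside [{config.min_length}, {config.max_length}]"
        )
    return length if correct else length - 1


def next_length(
    phase: str,
    current: int,
    outcomes: Sequence[bool],
    config: EngineConfig = DEFAULT_CONFIG,
) -> int:
    """Staircase update, clamped to the configured bounds.

    Calibration adapts on a single outcome (+1 correct / -1 incorrect);
    the test phase adapts on a completed pair (+1 both correct, -1 both
    incorrect, unchanged when split).
    """
    if not config.min_length <= current <= config.max_length:
        raise BoundsError(
            f"length {current} outside [{config.min_length}, {config.max_length}]"
        )
    if phase == CALIBRATION:
        if len(outcomes) != 1:
            raise UsageError("calibration adapts on exactly one outcome")
        step = 1 if outcomes[0] else -1
    elif phase == TEST:
        if len(outcomes) != 2:
            raise UsageError("test phase adapts on a pair of outcomes")
        if all(outcomes):
            step = 1
        elif not any(outcomes):
            step = -1
        else:
            step = 0
    else:
        raise UsageError(f"unknown phase {phase!r}")
    return min(max(current + step, config.min_length), config.max_length)


def compute_span_score(record: AdministrationRecord) -> float:
    """Mean of the test-item points; calibration items are excluded."""
    test = record.test_trials
    if len(test) != record.config.n_test:
        raise StructuralError(
            f"expected {record.config.n_test} test trials, found {len(test)}"
        )
    return sum(t.points for t in test) / len(test)


Responder = Callable[[int, tuple[str, str]], bool]


def administer(
    responder: Responder,
    condition: tuple[str, str] = ("short", "real"),
    config: EngineConfig = DEFAULT_CONFIG,
    rng=None,
) -> AdministrationRecord:
    """Run one full adaptive administration.

    Parameters
    ----------
    responder
        Callable ``(length, condition) -> bool`` deciding whether the
        simulated child repeats a sequence of that length correctly.  A
        stochastic responder should close over its own seeded generator
        (or over ``rng``, passed through untouched for convenience).
    condition
        ``(word_length, lexicality)`` label, metadata only.
    config
        Staircase parameters.

    Notes
    -----
    The test phase starts at the length reached after the calibration
    items; the staircase is therefore continuous across the phase
    boundary.  Length is clamped at the configured floor/ceiling and a
    clamped update still counts as an adaptation.
    """
    if rng is not None:
        base = responder
        responder = lambda length, cond: base(length, cond, rng)  # noqa: E731

    trials: list[TrialOutcome] = []
    length = config.start_length
    per_length_use: Counter[int] = Counter()

    for i in range(config.n_calibration):
        per_length_use[length] += 1
        correct = bool(responder(length, condition))
        trials.append(
            TrialOutcome(CALIBRATION, i, length, correct, score_trial(length, correct, config))
        )
        length = next_length(CALIBRATION, length, [correct], config)

    pair: list[bool] = []
    for j in range(config.n_test):
        per_length_use[length] += 1
        correct = bool(responder(length, condition))
        trials.append(
            TrialOutcome(
                TEST, config.n_calibration + j, length, correct,
                score_trial(length, correct, config),
            )
        )
        pair.append(correct)
        if len(pair) == 2:
            length = next_length(TEST, length, pair, config)
            pair = []

    overused = {L: c for L, c in per_length_use.items() if c > config.sequences_per_length}
    if overused:
        warnings.warn(
            f"sequence pool exhausted (>{config.sequences_per_length} uses) "
            f"for lengths {sorted(overused)}; sequences reused",
            stacklevel=2,
        )

    test_points = [t.points for t in trials if t.phase == TEST]
    return AdministrationRecord(
        condition=condition,
        trials=tuple(trials),
        span_score=sum(test_points) / len(test_points),
        config=config,
    )


def replay(
    pattern: Iterable[bool],
    condition: tuple[str, str] = ("short", "real"),
    config: EngineConfig = DEFAULT_CONFIG,
) -> AdministrationRecord:
    """Deterministically re-run an administration from a recorded
    correct/incorrect pattern (calibration items first)."""
    it = iter(pattern)

    def scripted(length: int, cond: tuple[str, str]) -> bool:
        try:
            return bool(next(it))
        except StopIteration:  # pragma: no cover - guarded below
            raise StructuralError("response pattern shorter than the administration")

    record = administer(scripted, condition, config)
    if next(it, None) is not None:
        raise StructuralError("response pattern longer than the administration")
    return record


class ScoreRange(NamedTuple):
    min_score: float
    max_score: float
    scores: tuple[float, ...]  # attainable-score multiset over all patterns


def enumerate_score_range(
    config: EngineConfig = DEFAULT_CONFIG, limit: int = 2**16
) -> ScoreRange:
    """Exhaustively replay every correct/incorrect response pattern.

    Serves as the engine's own oracle: with the defaults there are
    2**10 = 1024 patterns.  Returns the extreme span scores and the full
    multiset of attainable scores (one entry per pattern).
    """
    n = config.n_trials
    if 2**n > limit:
        raise EnumerationSizeError(
            f"2^{n} patterns exceed the enumeration limit of {limit}"
        )
    scores = tuple(
        replay(pattern, config=config).span_score
        for pattern in itertools.product([False, True], repeat=n)
    )
    return ScoreRange(min(scores), max(scores), scores)
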