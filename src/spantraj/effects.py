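"""Working-memory effect scores and long/wide reshaping.

Three outcomes are derived from the four condition span scores
(short/long x real/pseudo):

* phonological-loop capacity — the mean over all four conditions;
* the rehearsal (word-length) effect — short minus long, averaged over
  lexicality: silent re-articulation benefits short words;
* the redintegration (lexicality) effect — real minus pseudo, averaged
  over length: lexical long-term knowledge helps reconstruct a degraded
  trace for real words only.

Condition contrasts are centred at +/-0.5 (short and real coded +0.5) so
that in the regression models a condition main effect equals the effect
in span units and the intercept is the grand mean.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .cohort import SPAN_COLUMNS
from .exceptions import MissingDataError, SchemaError

logger = logging.getLogger(__name__)

SHORT, LONG = "short", "long"
REAL, PSEUDO = "real", "pseudo"

LENGTH_CONTRAST = {SHORT: 0.5, LONG: -0.5}
LEXICALITY_CONTRAST = {REAL: 0.5, PSEUDO: -0.5}

ID_COLUMNS = ("participant_id", "group")
CARRY_COLUMNS = ("sex", "ca_months", "cog_raw", "voc_raw", "lexicality_order")


def _as_condition_scores(scores) -> dict:
    """Normalise input to ``{(length, lexicality): score}``."""
    if isinstance(scores, Mapping):
        out = dict(scores)
    elif isinstance(scores, pd.Series) or hasattr(scores, "_fields"):
        out = {}
        for cond, col in SPAN_COLUMNS.items():
            if col in scores:
                out[cond] = scores[col]
    else:  # positional: the four conditions in administration order
        out = dict(zip(SPAN_COLUMNS, scores))
    missing = [c for c in SPAN_COLUMNS if c not in out or pd.isna(out[c])]
    if missing:
        raise MissingDataError(f"missing condition scores: {missing}")
    return {c: float(out[c]) for c in SPAN_COLUMNS}


def condition_mean(*scores: float) -> float:
    """The aggregation operator used throughout: a plain arithmetic mean."""
    if not scores:
        raise MissingDataError("no scores to aggregate")
    if any(pd.isna(s) for s in scores):
        raise MissingDataError("cannot aggregate missing scores")
    return float(np.mean(scores))


def pl_capacity(scores) -> float:
    """Phonological-loop capacity: mean of the four condition scores."""
    s = _as_condition_scores(scores)
    return condition_mean(*s.values())


def length_effect(scores) -> float:
    """Word-length (rehearsal) effect: mean(short) - mean(long)."""
    s = _as_condition_scores(scores)
    return condition_mean(s[(SHORT, REAL)], s[(SHORT, PSEUDO)]) - condition_mean(
        s[(LONG, REAL)], s[(LONG, PSEUDO)]
    )


def lexicality_effect(scores) -> float:
    """Lexicality (redintegration) effect: mean(real) - mean(pseudo)."""
    s = _as_condition_scores(scores)
    return condition_mean(s[(SHORT, REAL)], s[(LONG, REAL)]) - condition_mean(
        s[(SHORT, PSEUDO)], s[(LONG, PSEUDO)]
    )


def add_effect_scores(participants: pd.DataFrame) -> pd.DataFrame:
    """Append pl_capacity / rehearsal_effect / redintegration_effect columns.

    Participants missing any condition score get NaN effect scores and
    are thereby excluded listwise from analyses that need them (logged).
    """
    cols = list(SPAN_COLUMNS.values())
    missing_cols = [c for c in cols if c not in participants.columns]
    if missing_cols:
        raise SchemaError(f"missing span columns: {missing_cols}")
    out = participants.copy()
    spans = out[cols]
    complete = spans.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%d participant(s) with incomplete conditions excluded "
                    "from effect scores", n_dropped)
    out["pl_capacity"] = spans.mean(axis=1).where(complete)
    short = spans[[SPAN_COLUMNS[(SHORT, REAL)], SPAN_COLUMNS[(SHORT, PSEUDO)]]].mean(axis=1)
    long_ = spans[[SPAN_COLUMNS[(LONG, REAL)], SPAN_COLUMNS[(LONG, PSEUDO)]]].mean(axis=1)
    real = spans[[SPAN_COLUMNS[(SHORT, REAL)], SPAN_COLUMNS[(LONG, REAL)]]].mean(axis=1)
    pseudo = spans[[SPAN_COLUMNS[(SHORT, PSEUDO)], SPAN_COLUMNS[(LONG, PSEUDO)]]].mean(axis=1)
    out["rehearsal_effect"] = (short - long_).where(complete)
    out["redintegration_effect"] = (real - pseudo).where(complete)
    return out


def to_long_format(participants: pd.DataFrame) -> pd.DataFrame:
    """Reshape wide participant rows to one row per participant x condition.

    Adds centred contrast columns ``length_c`` and ``lexicality_c`` which
    sum to zero within each participant.  Round-trips losslessly through
    :func:`to_wide_format`.
    """
    if participants["participant_id"].duplicated().any():
        dup = participants.loc[
            participants["participant_id"].duplicated(), "participant_id"
        ].tolist()
        raise SchemaError(f"duplicate participant ids: {dup}")
    keep = [c for c in (*ID_COLUMNS, *CARRY_COLUMNS) if c in participants.columns]
    rows = []
    for (length, lex), col in SPAN_COLUMNS.items():
        if col not in participants.columns:
            raise SchemaError(f"missing span column {col}")
        block = participants[keep].copy()
        block["word_length"] = length
        block["lexicality"] = lex
        block["length_c"] = LENGTH_CONTRAST[length]
        block["lexicality_c"] = LEXICALITY_CONTRAST[lex]
        block["span"] = participants[col].to_numpy()
        rows.append(block)
    long = pd.concat(rows, ignore_index=True)
    return long.sort_values(["participant_id", "word_length", "lexicality"],
                            ignore_index=True)


def to_wide_format(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_long_format`."""
    keep = [c for c in (*ID_COLUMNS, *CARRY_COLUMNS) if c in long.columns]
    wide = long.pivot_table(index="participant_id", columns=["word_length", "lexicality"],
                            values="span", aggfunc="first")
    wide.columns = [SPAN_COLUMNS[c] for c in wide.columns]
    meta = long[keep].drop_duplicates("participant_id").set_index("participant_id")
    out = meta.join(wide).reset_index()
    return out[keep + list(SPAN_COLUMNS.values())]
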