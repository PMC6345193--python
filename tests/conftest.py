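"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spantraj.cohort import CohortConfig, simulate_cohort

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


def staircase_oracle(pattern, start=3, lo=2, hi=8, n_cal=2, n_test=8):
    """Independent brute-force re-implementation of the adaptive task.

    Deliberately written differently from the package (plain lists, no
    shared helpers) so it can serve as an oracle: returns the test-item
    lengths and the span score for one correct/incorrect pattern.
    """
    i = 0
    L = start
    for _ in range(n_cal):
        ok = pattern[i]
        i += 1
        L = L + 1 if ok else L - 1
        L = lo if L < lo else hi if L > hi else L
    test_lengths, test_points, buf = [], [], []
    for _ in range(n_test):
        ok = pattern[i]
        i += 1
        test_lengths.append(L)
        test_points.append(L if ok else L - 1)
        buf.append(ok)
        if len(buf) == 2:
            if buf[0] and buf[1]:
                L += 1
            elif not buf[0] and not buf[1]:
                L -= 1
            L = lo if L < lo else hi if L > hi else L
            buf = []
    return test_lengths, sum(test_points) / n_test


def normal_equations(X, y):
    """Textbook least squares: solve X'X b = X'y directly."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def make_wide_participants(ids, groups, di, spans):
    """Minimal wide participant table for trajectory toy tests.

    ``spans`` is (sr, lr, sp, lp) arrays or a single array used for all
    four conditions (pure-capacity designs).
    """
    if isinstance(spans, (list, tuple)) and len(spans) == 4:
        sr, lr, sp, lp = spans
    else:
        sr = lr = sp = lp = np.asarray(spans, float)
    di = np.asarray(di, float)
    return pd.DataFrame({
        "participant_id": list(ids),
        "group": list(groups),
        "ca_months": di,
        "cog_raw": di,
        "voc_raw": di,
        "span_short_real": sr,
        "span_long_real": lr,
        "span_short_pseudo": sp,
        "span_long_pseudo": lp,
    })


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def participants(default_cohort):
    return default_cohort[0]


@pytest.fixture(scope="session")
def trials(default_cohort):
    return default_cohort[1]
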