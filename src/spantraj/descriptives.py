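"""Group descriptives: the statistics behind the sample-characteristics
and indicator-correlation tables.

Covers the two-sample comparisons (Student/Welch t with Cohen's d, and a
2x2 chi-square with the phi coefficient for the sex ratio), per-group
Pearson correlation matrices with pairwise-complete ns, and Cronbach's
alpha as the internal consistency of the four condition span scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .cohort import GROUPS, MBID, TD, SPAN_COLUMNS
from .exceptions import ParameterError, UsageError

DI_LABELS = {"ca_months": "Chronological age (months)",
             "cog_raw": "Cognitive capacity (raw)",
             "voc_raw": "Vocabulary size (raw)"}


@dataclass(frozen=True)
class GroupComparison:
    """One between-group test: descriptives, statistic and effect size."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    statistic: float
    df: float
    p: float
    effect_size: float
    statistic_name: str  # "t" or "chi2"
    effect_name: str     # "d" or "phi"
    variance_policy: str  # "student", "welch" or "n/a"


def two_sample_t(x, y, policy: str = "auto") -> GroupComparison:
    """Two-sample t test with Cohen's d.

    ``policy="auto"`` runs a Levene variance-homogeneity pretest at
    alpha 0.05 and falls back to the Welch correction when variances
    differ; d always uses the pooled SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise UsageError("each sample needs n >= 2")
    if policy not in ("auto", "student", "welch"):
        raise UsageError(f"unknown variance policy {policy!r}")
    if policy == "auto":
        _, p_lev = st.levene(x, y, center="mean")
        policy = "welch" if p_lev < 0.05 else "student"
    equal_var = policy == "student"
    res = st.ttest_ind(x, y, equal_var=equal_var)
    n1, n2 = len(x), len(y)
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    sp = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    d = (x.mean() - y.mean()) / sp if sp > 0 else 0.0
    return GroupComparison(
        mean1=float(x.mean()), sd1=float(x.std(ddof=1)), n1=n1,
        mean2=float(y.mean()), sd2=float(y.std(ddof=1)), n2=n2,
        statistic=float(res.statistic), df=float(df), p=float(res.pvalue),
        effect_size=float(d), statistic_name="t", effect_name="d",
        variance_policy=policy,
    )


def chi_square_2x2(counts, correction: str = "yates") -> GroupComparison:
    """Chi-square test on a 2x2 table with the phi coefficient.

    The test statistic uses Yates' continuity correction by default (the
    convention of the statistics package the reference tables were
    produced with; pass ``correction="none"`` for the plain Pearson
    statistic), while phi is always ``sqrt(chi2_pearson / n)`` from the
    *uncorrected* Pearson statistic, its standard definition.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or not np.allclose(table, np.round(table)):
        raise UsageError("need a 2x2 table of nonnegative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterError("degenerate table: a zero marginal")
    if correction not in ("yates", "none"):
        raise UsageError(f"unknown correction {correction!r}")
    chi2, p, dof, _ = st.chi2_contingency(table, correction=(correction == "yates"))
    pearson, _, _, _ = st.chi2_contingency(table, correction=False)
    n = table.sum()
    phi = float(np.sqrt(pearson / n))
    return GroupComparison(
        mean1=float(table[0, 0]), sd1=float(table[0, 1]), n1=int(table[0].sum()),
        mean2=float(table[1, 0]), sd2=float(table[1, 1]), n2=int(table[1].sum()),
        statistic=float(chi2), df=float(dof), p=float(p),
        effect_size=phi, statistic_name="chi2", effect_name="phi",
        variance_policy="n/a",
    )


def pearson_matrix(participants: pd.DataFrame, columns=None, by: str = "group"):
    """Per-group Pearson correlation matrices with pairwise-complete ns.

    Returns ``{group: (r_matrix, n_matrix)}`` as DataFrames.  A constant
    column yields NaN entries (flagged, not an error).
    """
    if columns is None:
        columns = ["ca_months", "cog_raw", "voc_raw"]
    out = {}
    for group, sub in participants.groupby(by):
        k = len(columns)
        r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
        n = pd.DataFrame(0, index=columns, columns=columns, dtype=int)
        for i, a in enumerate(columns):
            for j, b in enumerate(columns):
                pair = sub[[a, b]].dropna()
                n.iloc[i, j] = len(pair)
                if i == j:
                    continue
                if len(pair) < 3:
                    r.iloc[i, j] = np.nan
                    continue
                xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
                if xa.std() == 0 or xb.std() == 0:
                    r.iloc[i, j] = np.nan  # undefined for a constant column
                else:
                    r.iloc[i, j] = st.pearsonr(xa, xb).statistic
        out[group] = (r, n)
    return out


def internal_consistency(item_scores) -> float:
    """Cronbach's alpha over the item columns (here: the four condition
    span scores).  Returns NaN when the total score has zero variance."""
    X = np.asarray(item_scores, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if k < 2 or n < 3:
        raise UsageError("need at least 2 items and 3 participants")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def descriptive_table(participants: pd.DataFrame) -> pd.DataFrame:
    """Sample-characteristics table for a two-group cohort.

    One row per variable (sex ratio, the developmental indicators, and
    the six span rows: short/long/total for real words and pseudowords)
    with per-group descriptives and the between-group test.
    """
    rows = []

    def t_row(label, col_or_series):
        vals = participants[col_or_series] if isinstance(col_or_series, str) \
            else col_or_series
        x = vals[participants["group"] == MBID]
        y = vals[participants["group"] == TD]
        c = two_sample_t(x, y, policy="auto")
        rows.append({
            "variable": label,
            "mbid_mean": c.mean1, "mbid_sd": c.sd1, "mbid_n": c.n1,
            "td_mean": c.mean2, "td_sd": c.sd2, "td_n": c.n2,
            "statistic": c.statistic_name, "value": c.statistic,
            "df": c.df, "p": c.p,
            "effect": c.effect_name, "effect_size": c.effect_size,
            "variance_policy": c.variance_policy,
        })

    if "sex" in participants.columns:
        table = [
            [int(((participants["group"] == g) & (participants["sex"] == s)).sum())
             for s in ("male", "female")]
            for g in GROUPS
        ]
        c = chi_square_2x2(table)
        rows.append({
            "variable": "sex (male/female)",
            "mbid_mean": table[0][0], "mbid_sd": table[0][1], "mbid_n": sum(table[0]),
            "td_mean": table[1][0], "td_sd": table[1][1], "td_n": sum(table[1]),
            "statistic": "chi2", "value": c.statistic, "df": c.df, "p": c.p,
            "effect": "phi", "effect_size": c.effect_size,
            "variance_policy": "n/a",
        })

    for col, label in DI_LABELS.items():
        if col in participants.columns:
            t_row(label, col)
    if "iq" in participants.columns:
        t_row("Intelligence (IQ norm scores)", "iq")

    spans = {c: participants[col] for c, col in SPAN_COLUMNS.items()
             if col in participants.columns}
    if len(spans) == 4:
        t_row("Word span real words, short", spans[("short", "real")])
        t_row("Word span real words, long", spans[("long", "real")])
        t_row("Word span total real words",
              (spans[("short", "real")] + spans[("long", "real")]) / 2.0)
        t_row("Word span pseudowords, short", spans[("short", "pseudo")])
        t_row("Word span pseudowords, long", spans[("long", "pseudo")])
        t_row("Word span total pseudowords",
              (spans[("short", "pseudo")] + spans[("long", "pseudo")]) / 2.0)

    return pd.DataFrame(rows)
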