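"""Cross-sectional developmental-trajectory inference.

The central question: does an outcome (phonological-loop capacity, the
rehearsal effect, or the redintegration effect) develop differently in
the MBID group than in typically developing children, when "development"
is indexed by a developmental indicator (DI: chronological age,
cognitive capacity, or vocabulary size)?  Each trajectory is a linear
regression of the outcome on the DI, compared between groups:

* a group difference in *intercepts* (evaluated at the rescaled DI
  origin, the MBID minimum) marks a **delayed onset**;
* a group difference in *slopes* marks a difference in **rate**;
* both together mark a **combination**.

The protocol proceeds through four nested steps — DI only; + group;
+ task condition; + the full task x group x DI interaction — and tests
each term with a partial F against the model without it.  For capacity
there is no task factor, so the protocol stops at step 2 and the group
terms themselves carry the classification.

Usage follows the statsmodels idiom::

    model = DevelopmentalTrajectory.from_dataframe(participants,
                                                   outcome="rehearsal", di="CA")
    res = model.fit()
    print(res.summary())
    res.classification.label      # e.g. "delayed_onset"

Observations in the task-condition models are two aggregated rows per
participant treated as independent in OLS; a cluster-robust variant
(clustering on participant) is available behind ``cluster_robust=True``
and changes only standard errors and p-values, never the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .cohort import MBID, SPAN_COLUMNS
from .effects import add_effect_scores
from .exceptions import (
    GroupingError,
    MissingDataError,
    SchemaError,
    SingularDesignError,
    UsageError,
)

OUTCOMES = ("capacity", "rehearsal", "redintegration")
DIS = ("CA", "COG", "VOC")
DI_COLUMNS = {"CA": "ca_months", "COG": "cog_raw", "VOC": "voc_raw"}
TASK_FACTOR = {"rehearsal": "Length", "redintegration": "Lexicality"}
EFFECT_COLUMN = {
    "capacity": "pl_capacity",
    "rehearsal": "rehearsal_effect",
    "redintegration": "redintegration_effect",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which trajectory to fit, and at which protocol step."""

    outcome: str
    di: str
    step: int | None = None  # None resolves to the outcome's final step
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.step is None:
            object.__setattr__(self, "step", self.max_step(self.outcome))
        if self.outcome not in OUTCOMES:
            raise UsageError(f"unknown outcome {self.outcome!r}; one of {OUTCOMES}")
        if self.di not in DIS:
            raise UsageError(f"unknown DI {self.di!r}; one of {DIS}")
        if not 0 < self.alpha < 1:
            raise UsageError("alpha must be in (0, 1)")
        if not 1 <= self.step <= self.max_step(self.outcome):
            raise UsageError(
                f"step {self.step} invalid for outcome {self.outcome!r} "
                f"(max {self.max_step(self.outcome)})"
            )

    @staticmethod
    def max_step(outcome: str) -> int:
        return 2 if outcome == "capacity" else 4

    @property
    def task_factor(self) -> str | None:
        return TASK_FACTOR.get(self.outcome)

    @property
    def onset_term(self) -> str:
        return "Group" if self.outcome == "capacity" else f"{self.task_factor}:Group"

    @property
    def rate_term(self) -> str:
        return "Group:DI" if self.outcome == "capacity" else f"{self.task_factor}:Group:DI"


def rescale_di(values, group_labels):
    """Shift a DI so that the MBID minimum sits at 0.

    Keeps the intercept comparison inside the observed range instead of
    extrapolating to a raw-score zero; slopes are unaffected.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    mask = group_labels == MBID
    if not mask.any():
        raise GroupingError("no MBID participants; cannot anchor the rescaling")
    anchor = np.nanmin(values[mask])
    if np.isnan(anchor):
        raise GroupingError("all MBID DI values are missing")
    return values - anchor


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix for one protocol step, with field-named columns.

    ``data`` is an analysis table with columns ``di`` (already rescaled),
    ``group_mbid`` (indicator, TD = 0) and, for task outcomes, ``task_c``
    (the centred +/-0.5 condition contrast).  Terms enter in protocol
    order; each step appends an intercept-like and a slope-like column.
    """
    required = {"di", "group_mbid"}
    if spec.step >= 3:
        required.add("task_c")
    missing = required - set(data.columns)
    if missing:
        raise SchemaError(f"analysis table lacks columns: {sorted(missing)}")

    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["DI"] = data["di"].to_numpy(dtype=float)
    if spec.step >= 2:
        X["Group"] = data["group_mbid"].to_numpy(dtype=float)
        X["Group:DI"] = X["Group"] * X["DI"]
    if spec.step >= 3:
        task = spec.task_factor
        X[task] = data["task_c"].to_numpy(dtype=float)
        X[f"{task}:DI"] = X[task] * X["DI"]
    if spec.step >= 4:
        task = spec.task_factor
        X[f"{task}:Group"] = X[task] * X["Group"]
        X[f"{task}:Group:DI"] = X[task] * X["Group"] * X["DI"]
    return X


@dataclass(frozen=True)
class TermTest:
    F: float
    p: float
    partial_eta2: float
    df_num: int
    df_den: int


@dataclass
class TrajectoryFit:
    """One least-squares fit: estimates, uncertainties, residual summary."""

    params: pd.Series
    bse: pd.Series
    rss: float
    df_resid: int
    nobs: int
    X: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    cluster_pvalues: pd.Series | None = field(default=None, repr=False)

    @property
    def columns(self) -> tuple:
        return tuple(self.X.columns)

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        X = self.X if X is None else X[list(self.columns)]
        return X.to_numpy(dtype=float) @ self.params.to_numpy()


def fit_ols(X: pd.DataFrame, y, cluster_groups=None) -> TrajectoryFit:
    """Ordinary least squares with an explicit rank guard.

    Raises :class:`SingularDesignError` naming the collinear columns when
    the design is rank deficient (e.g. a DI constant within a group).
    ``cluster_groups`` switches the *standard errors* (and the stored
    p-values) to the cluster-robust sandwich; estimates are untouched.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise UsageError(f"need more observations ({n}) than parameters ({p})")
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < p:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(A, pivoting=True, mode="economic")
        bad = [X.columns[i] for i in sorted(piv[rank:])]
        raise SingularDesignError(f"collinear design columns: {bad}")
    res = sm.OLS(y, A).fit()
    cluster_p = None
    if cluster_groups is not None:
        rob = sm.OLS(y, A).fit(cov_type="cluster",
                               cov_kwds={"groups": np.asarray(cluster_groups)})
        bse = pd.Series(rob.bse, index=X.columns)
        cluster_p = pd.Series(rob.pvalues, index=X.columns)
    else:
        bse = pd.Series(res.bse, index=X.columns)
    return TrajectoryFit(
        params=pd.Series(res.params, index=X.columns),
        bse=bse,
        rss=float(res.ssr),
        df_resid=int(res.df_resid),
        nobs=n,
        X=X,
        y=y,
        cluster_pvalues=cluster_p,
    )


def term_test(full: TrajectoryFit, reduced: TrajectoryFit) -> TermTest:
    """Partial F test of the terms present in ``full`` but not ``reduced``."""
    if full.nobs != reduced.nobs:
        raise UsageError("models fit on different data cannot be compared")
    extra = set(reduced.columns) - set(full.columns)
    if extra or len(reduced.columns) >= len(full.columns):
        raise UsageError("reduced model is not nested in the full model")
    df_num = len(full.columns) - len(reduced.columns)
    df_den = full.df_resid
    dss = max(reduced.rss - full.rss, 0.0)
    if full.rss <= 0:
        F = np.inf if dss > 0 else 0.0
    else:
        F = (dss / df_num) / (full.rss / df_den)
    p = float(st.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    eta2 = dss / reduced.rss if reduced.rss > 0 else 0.0
    return TermTest(float(F), p, float(eta2), df_num, df_den)


def single_term_tests(fit: TrajectoryFit) -> dict:
    """Drop-one partial F for every non-constant term in a fit."""
    out = {}
    for term in fit.columns:
        if term == "const":
            continue
        reduced = fit_ols(fit.X.drop(columns=[term]), fit.y)
        out[term] = term_test(fit, reduced)
    return out


@dataclass(frozen=True)
class PatternClassification:
    """Delayed-onset / slowed-rate verdict for one trajectory."""

    onset_delayed: bool
    rate_differs: bool
    label: str
    rate_sign: int
    p_onset: float
    p_rate: float
    onset_term: str
    rate_term: str

    @staticmethod
    def _label(onset: bool, rate: bool) -> str:
        if onset and rate:
            return "combination"
        if onset:
            return "delayed_onset"
        if rate:
            return "slowed_rate"
        return "no_difference"


def classify_pattern(fit: TrajectoryFit, spec: ModelSpec,
                     term_tests: dict | None = None) -> PatternClassification:
    """Read the developmental pattern off the final-step fit.

    The intercept-difference term decides delayed onset, the
    slope-difference term decides a rate difference; the sign of the rate
    coefficient records whether the MBID slope is steeper (+1) or
    shallower (-1).
    """
    for term in (spec.onset_term, spec.rate_term):
        if term not in fit.columns:
            raise UsageError(
                f"fit lacks term {term!r}; fit the final protocol step first"
            )
    tests = term_tests if term_tests is not None else single_term_tests(fit)
    p_onset = tests[spec.onset_term].p
    p_rate = tests[spec.rate_term].p
    onset = p_onset < spec.alpha
    rate = p_rate < spec.alpha
    coef = fit.params[spec.rate_term]
    return PatternClassification(
        onset_delayed=onset,
        rate_differs=rate,
        label=PatternClassification._label(onset, rate),
        rate_sign=int(np.sign(coef)) if coef != 0 else 0,
        p_onset=p_onset,
        p_rate=p_rate,
        onset_term=spec.onset_term,
        rate_term=spec.rate_term,
    )


# --- model / results objects --------------------------------------------------

class DevelopmentalTrajectory:
    """Trajectory model for one outcome x DI combination.

    Parameters
    ----------
    participants
        Wide participant table (one row each) with group, DI columns and
        the four condition span columns.
    outcome
        "capacity", "rehearsal" or "redintegration".
    di
        "CA", "COG" or "VOC".
    alpha
        Significance level for term tests and classification.
    cluster_robust
        Use participant-clustered standard errors for coefficient
        p-values (estimates unchanged; off by default, matching the
        independence treatment of the published protocol).
    """

    def __init__(self, participants: pd.DataFrame, outcome: str = "capacity",
                 di: str = "CA", alpha: float = 0.05,
                 cluster_robust: bool = False) -> None:
        self.spec = ModelSpec(outcome, di, step=ModelSpec.max_step(outcome), alpha=alpha)
        self.outcome = outcome
        self.di = di
        self.alpha = alpha
        self.cluster_robust = cluster_robust
        self.participants = participants
        self.data, self.n_excluded = self._build_analysis_table(participants)

    @classmethod
    def from_dataframe(cls, participants: pd.DataFrame, outcome: str = "capacity",
                       di: str = "CA", **kwargs) -> "DevelopmentalTrajectory":
        return cls(participants, outcome=outcome, di=di, **kwargs)

    # -- data preparation
    def _build_analysis_table(self, participants: pd.DataFrame):
        di_col = DI_COLUMNS[self.di]
        need = {"participant_id", "group", di_col, *SPAN_COLUMNS.values()}
        missing = need - set(participants.columns)
        if missing:
            raise SchemaError(f"participant table lacks columns: {sorted(missing)}")
        spans = participants[list(SPAN_COLUMNS.values())]
        usable = participants[di_col].notna() & spans.notna().all(axis=1)
        used = participants.loc[usable].reset_index(drop=True)
        n_excluded = int((~usable).sum())
        if not (used["group"] == MBID).any():
            raise GroupingError("no usable MBID participants for this DI")

        sr, lr, sp, lp = (used[SPAN_COLUMNS[c]].to_numpy() for c in SPAN_COLUMNS)
        if self.outcome == "capacity":
            rows = pd.DataFrame({
                "participant_id": used["participant_id"],
                "group": used["group"],
                "di_orig": used[di_col].to_numpy(dtype=float),
                "y": (sr + lr + sp + lp) / 4.0,
            })
        else:
            if self.outcome == "rehearsal":
                plus, minus = (sr + sp) / 2.0, (lr + lp) / 2.0
            else:  # redintegration
                plus, minus = (sr + lr) / 2.0, (sp + lp) / 2.0
            half = pd.DataFrame({
                "participant_id": used["participant_id"],
                "group": used["group"],
                "di_orig": used[di_col].to_numpy(dtype=float),
            })
            hi = half.copy()
            hi["task_c"] = 0.5
            hi["y"] = plus
            lo = half.copy()
            lo["task_c"] = -0.5
            lo["y"] = minus
            rows = pd.concat([hi, lo], ignore_index=True)
        rows["group_mbid"] = (rows["group"] == MBID).astype(float)
        rows["di"] = rescale_di(rows["di_orig"], rows["group"])
        return rows, n_excluded

    # -- estimation
    def fit(self, step: int | None = None) -> "TrajectoryResults":
        max_step = self.spec.step if step is None else step
        ModelSpec(self.outcome, self.di, step=max_step, alpha=self.alpha)  # validate
        clusters = (self.data["participant_id"].to_numpy()
                    if self.cluster_robust else None)
        y = self.data["y"].to_numpy(dtype=float)
        step_fits: dict[int, TrajectoryFit] = {}
        step_tests: dict[int, dict] = {}
        for s in range(1, max_step + 1):
            spec_s = ModelSpec(self.outcome, self.di, step=s, alpha=self.alpha)
            X = build_design(self.data, spec_s)
            f = fit_ols(X, y, cluster_groups=clusters)
            step_fits[s] = f
            step_tests[s] = single_term_tests(f)
            if self.cluster_robust and f.cluster_pvalues is not None:
                # single-df robust Wald replaces the OLS partial F p-value
                for term, tt in step_tests[s].items():
                    step_tests[s][term] = TermTest(
                        F=float((f.params[term] / f.bse[term]) ** 2),
                        p=float(f.cluster_pvalues[term]),
                        partial_eta2=tt.partial_eta2,
                        df_num=1, df_den=tt.df_den,
                    )
        return TrajectoryResults(self, step_fits, step_tests)


class TrajectoryResults:
    """Fitted trajectory protocol: per-step estimates, term tests, verdict."""

    def __init__(self, model: DevelopmentalTrajectory,
                 step_fits: dict, step_tests: dict) -> None:
        self.model = model
        self.spec = ModelSpec(model.outcome, model.di,
                              step=max(step_fits), alpha=model.alpha)
        self.step_fits = step_fits
        self.step_tests = step_tests
        self.final_step = max(step_fits)
        fit = step_fits[self.final_step]
        self.params = fit.params
        self.bse = fit.bse
        self.nobs = fit.nobs
        self.n_excluded = model.n_excluded
        if self.final_step == self.spec.max_step(model.outcome):
            self.classification = classify_pattern(
                fit, self.spec, self.step_tests[self.final_step]
            )
        else:
            self.classification = None

    @property
    def final_fit(self) -> TrajectoryFit:
        return self.step_fits[self.final_step]

    # -- reporting
    def summary(self) -> str:
        m = self.model
        lines = [
            f"Developmental trajectory: {m.outcome} ~ {m.di} "
            f"(n obs = {self.nobs}, excluded participants = {self.n_excluded})",
            "",
        ]
        for s in sorted(self.step_fits):
            fit = self.step_fits[s]
            lines.append(f"Step {s}: RSS = {fit.rss:.4f}, df = {fit.df_resid}")
            lines.append(f"  {'term':<18}{'coef':>10}{'se':>10}{'F':>10}"
                         f"{'p':>10}{'eta2_p':>8}")
            for term in fit.columns:
                c, se = fit.params[term], fit.bse[term]
                if term == "const":
                    lines.append(f"  {term:<18}{c:>10.4f}{se:>10.4f}")
                else:
                    t = self.step_tests[s][term]
                    lines.append(
                        f"  {term:<18}{c:>10.4f}{se:>10.4f}{t.F:>10.3f}"
                        f"{t.p:>10.4f}{t.partial_eta2:>8.3f}"
                    )
            lines.append("")
        if self.classification is not None:
            c = self.classification
            lines.append(
                f"Pattern: {c.label} (onset term {c.onset_term}: p = {c.p_onset:.4f}; "
                f"rate term {c.rate_term}: p = {c.p_rate:.4f}, "
                f"MBID slope {'steeper' if c.rate_sign > 0 else 'shallower' if c.rate_sign < 0 else 'equal'})"
            )
        return "\n".join(lines)

    def fitted_effect_table(self) -> pd.DataFrame:
        """Per-participant observed and fitted outcome values on the
        effect scale (the data behind the trajectory scatterplots)."""
        data = self.model.data
        fit = self.final_fit
        yhat = fit.predict()
        d = data.assign(fitted=yhat)
        if self.model.outcome == "capacity":
            out = d[["participant_id", "group", "di_orig", "y", "fitted"]].copy()
        else:
            hi = d[d["task_c"] > 0].set_index("participant_id")
            lo = d[d["task_c"] < 0].set_index("participant_id")
            out = pd.DataFrame({
                "group": hi["group"],
                "di_orig": hi["di_orig"],
                "y": hi["y"] - lo["y"],
                "fitted": hi["fitted"] - lo["fitted"],
            }).reset_index()
        return out.rename(columns={"di_orig": DI_COLUMNS[self.model.di],
                                   "y": "observed_effect",
                                   "fitted": "fitted_effect"})

    # -- follow-up analyses
    def per_group_slope_test(self, group: str):
        return per_group_slope_test(self.model.participants, group,
                                    ModelSpec(self.model.outcome, self.model.di,
                                              step=self.final_step,
                                              alpha=self.model.alpha))

    def sensitivity(self, exclusion) -> "SensitivityResult":
        return sensitivity_refit(self.model.participants, exclusion,
                                 ModelSpec(self.model.outcome, self.model.di,
                                           alpha=self.model.alpha,
                                           step=self.spec.max_step(self.model.outcome)),
                                 cluster_robust=self.model.cluster_robust)

    def to_dict(self) -> dict:
        out = {
            "outcome": self.model.outcome,
            "di": self.model.di,
            "n_obs": int(self.nobs),
            "n_excluded": int(self.n_excluded),
            "steps": {},
        }
        for s, fit in self.step_fits.items():
            out["steps"][str(s)] = {
                "terms": {
                    term: {
                        "coef": float(fit.params[term]),
                        "se": float(fit.bse[term]),
                        **(
                            {
                                "F": self.step_tests[s][term].F,
                                "p": self.step_tests[s][term].p,
                                "partial_eta2": self.step_tests[s][term].partial_eta2,
                            }
                            if term != "const"
                            else {}
                        ),
                    }
                    for term in fit.columns
                },
                "rss": fit.rss,
                "df_resid": fit.df_resid,
            }
        if self.classification is not None:
            c = self.classification
            out["classification"] = {
                "label": c.label,
                "onset_delayed": c.onset_delayed,
                "rate_differs": c.rate_differs,
                "rate_sign": c.rate_sign,
                "p_onset": c.p_onset,
                "p_rate": c.p_rate,
                "onset_term": c.onset_term,
                "rate_term": c.rate_term,
            }
        return out


# --- follow-up operations -----------------------------------------------------

def per_group_slope_test(participants: pd.DataFrame, group: str, spec: ModelSpec):
    """Within-group slope test on the participant-level effect score.

    Regresses the outcome's effect score (capacity, word-length effect or
    lexicality effect) on the DI within one group; returns
    ``(F, p, slope, df_den)`` with F(1, n - 2) — the separate-analysis
    convention with participant-level degrees of freedom.
    """
    scored = add_effect_scores(participants)
    di_col = DI_COLUMNS[spec.di]
    eff_col = EFFECT_COLUMN[spec.outcome]
    sub = scored[(scored["group"] == group)
                 & scored[di_col].notna() & scored[eff_col].notna()]
    if len(sub) < 3:
        raise UsageError(f"group {group!r} has too few usable rows ({len(sub)})")
    X = pd.DataFrame({"const": 1.0, "DI": sub[di_col].to_numpy(dtype=float)},
                     index=sub.index)
    fit = fit_ols(X, sub[eff_col].to_numpy(dtype=float))
    tt = single_term_tests(fit)["DI"]
    return tt.F, tt.p, float(fit.params["DI"]), tt.df_den


@dataclass
class SensitivityResult:
    """Before/after refits for an exclusion rule, with a delta report."""

    before: TrajectoryResults
    after: TrajectoryResults
    n_excluded: int
    excluded_ids: tuple
    changed_terms: dict  # term -> (significant_before, significant_after)

    def flips(self) -> dict:
        return {t: ba for t, ba in self.changed_terms.items() if ba[0] != ba[1]}


def sensitivity_refit(participants: pd.DataFrame, exclusion, spec: ModelSpec,
                      cluster_robust: bool = False) -> SensitivityResult:
    """Refit a trajectory after excluding participants.

    ``exclusion`` is either a list of participant ids or a predicate
    ``DataFrame -> boolean mask`` marking rows to *exclude* (e.g.
    ``lambda d: d["cog_raw"] < 45`` removes low cognitive-capacity raw
    scores, the published robustness check).
    """
    if callable(exclusion):
        mask = np.asarray(exclusion(participants), dtype=bool)
    else:
        mask = participants["participant_id"].isin(list(exclusion)).to_numpy()
    kept = participants.loc[~mask]
    excluded_ids = tuple(participants.loc[mask, "participant_id"])

    def run(df):
        m = DevelopmentalTrajectory(df, outcome=spec.outcome, di=spec.di,
                                    alpha=spec.alpha, cluster_robust=cluster_robust)
        return m.fit()

    before = run(participants)
    after = run(kept)
    changed = {}
    for term, tt in before.step_tests[before.final_step].items():
        tt_after = after.step_tests[after.final_step].get(term)
        if tt_after is not None:
            changed[term] = (tt.p < spec.alpha, tt_after.p < spec.alpha)
    return SensitivityResult(before, after, int(mask.sum()), excluded_ids, changed)
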