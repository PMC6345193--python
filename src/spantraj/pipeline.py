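"""End-to-end orchestration: configuration, seeding, and the pipeline
stages (simulate -> effects -> trajectories -> report).

Everything is reproducible from ``(config, master seed)``: the master
seed is split into named substreams per stage, each output carries the
seed and a hash of the configuration, and stage boundaries log row
counts so filters are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    GROUPS, MBID, TD, CohortConfig, SPAN_COLUMNS, simulate_cohort,
)
from .descriptives import descriptive_table, internal_consistency, pearson_matrix
from .effects import add_effect_scores
from .engine import EngineConfig
from .exceptions import ConfigError, SchemaError, UsageError
from .trajectories import (
    DIS, OUTCOMES, DevelopmentalTrajectory, ModelSpec, sensitivity_refit,
)

logger = logging.getLogger(__name__)

_CONDS = list(SPAN_COLUMNS)


def _cond_to_str(cond) -> str:
    return f"{cond[0]}_{cond[1]}"


def _str_to_cond(s: str):
    length, lex = s.split("_")
    return (length, lex)


@dataclass
class SensitivityRule:
    """A configured exclusion rule for the robustness refits."""

    name: str
    outcomes: list
    dis: list
    column: str | None = None   # threshold predicate: exclude column < / > value
    op: str = "lt"
    value: float | None = None
    exclude_ids: list = field(default_factory=list)

    def exclusion(self):
        if self.exclude_ids:
            return list(self.exclude_ids)
        if self.column is None or self.value is None:
            raise ConfigError(f"sensitivity rule {self.name!r} has no predicate")
        col, op, val = self.column, self.op, self.value
        if op == "lt":
            return lambda d: d[col].fillna(np.inf) < val
        if op == "gt":
            return lambda d: d[col].fillna(-np.inf) > val
        raise ConfigError(f"unknown predicate op {op!r}")


#: The published robustness check: drop low cognitive-capacity raw scores
#: from the cognitive-capacity trajectories.
DEFAULT_SENSITIVITY = [
    SensitivityRule(name="low_cog_raw", outcomes=["capacity", "rehearsal"],
                    dis=["COG"], column="cog_raw", op="lt", value=45.0),
]


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through JSON."""

    engine: EngineConfig = field(default_factory=EngineConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    alpha: float = 0.05
    dis: list = field(default_factory=lambda: list(DIS))
    outcomes: list = field(default_factory=lambda: list(OUTCOMES))
    cluster_robust: bool = False
    sensitivity: list = field(default_factory=lambda: list(DEFAULT_SENSITIVITY))
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [o for o in self.outcomes if o not in OUTCOMES]
        bad += [d for d in self.dis if d not in DIS]
        if bad:
            raise ConfigError(f"unknown outcomes/DIs in config: {bad}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        self.cohort = dataclasses.replace(self.cohort, engine=self.engine,
                                          seed=self.seed)

    # -- JSON round trip
    def to_dict(self) -> dict:
        c = self.cohort
        return {
            "seed": self.seed,
            "alpha": self.alpha,
            "dis": list(self.dis),
            "outcomes": list(self.outcomes),
            "cluster_robust": self.cluster_robust,
            "engine": dataclasses.asdict(self.engine),
            "cohort": {
                "n_mbid": c.n_mbid, "n_td": c.n_td,
                "n_td_subsample": c.n_td_subsample,
                "n_mbid_missing_cog": c.n_mbid_missing_cog,
                "n_mbid_missing_voc": c.n_mbid_missing_voc,
                "di_means": c.di_means, "di_sds": c.di_sds,
                "di_bounds": {g: {k: list(v) for k, v in b.items()}
                              for g, b in c.di_bounds.items()},
                "di_correlations": {g: np.asarray(m).tolist()
                                    for g, m in c.di_correlations.items()},
                "beta0": {g: {_cond_to_str(k): v for k, v in d.items()}
                          for g, d in c.beta0.items()},
                "beta1": {g: {_cond_to_str(k): v for k, v in d.items()}
                          for g, d in c.beta1.items()},
                "residual_sd": c.residual_sd,
                "person_sd": c.person_sd,
                "scale_s": c.scale_s,
                "p_male": c.p_male,
            },
            "sensitivity": [dataclasses.asdict(r) for r in self.sensitivity],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        engine = EngineConfig(**d.get("engine", {}))
        cd = dict(d.get("cohort", {}))
        if "di_bounds" in cd:
            cd["di_bounds"] = {g: {k: tuple(v) for k, v in b.items()}
                               for g, b in cd["di_bounds"].items()}
        for key in ("beta0", "beta1"):
            if key in cd:
                cd[key] = {g: {_str_to_cond(k): v for k, v in dd.items()}
                           for g, dd in cd[key].items()}
        cohort = CohortConfig(**cd, engine=engine, seed=d.get("seed", 0))
        rules = [SensitivityRule(**r) for r in d.get("sensitivity", [])]
        return cls(engine=engine, cohort=cohort,
                   alpha=d.get("alpha", 0.05),
                   dis=d.get("dis", list(DIS)),
                   outcomes=d.get("outcomes", list(OUTCOMES)),
                   cluster_robust=d.get("cluster_robust", False),
                   sensitivity=rules, seed=d.get("seed", 0))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


REQUIRED_PARTICIPANT_COLUMNS = (
    "participant_id", "group", "ca_months", "cog_raw", "voc_raw",
    *SPAN_COLUMNS.values(),
)


def validate_participants(participants: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_PARTICIPANT_COLUMNS
               if c not in participants.columns]
    if missing:
        raise SchemaError(f"participant table lacks columns: {missing}")
    unknown = set(participants["group"]) - set(GROUPS)
    if unknown:
        rows = participants.index[~participants["group"].isin(GROUPS)][:5]
        raise SchemaError(
            f"unknown group labels {sorted(unknown)} (first rows: {list(rows)})"
        )


# --- stages -------------------------------------------------------------------

def run_simulate(config: PipelineConfig, out_dir=None, seed: int | None = None):
    """Generate the synthetic cohort; optionally write CSVs + manifest."""
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    participants, trials = simulate_cohort(config.cohort)
    logger.info("simulated %d participants, %d trial rows",
                len(participants), len(trials))
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "spantraj_version": __version__,
        "n_participants": int(len(participants)),
        "n_trials": int(len(trials)),
        "group_counts": participants["group"].value_counts().to_dict(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        participants.to_csv(out / "participants.csv", index=False)
        trials.to_csv(out / "trials.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return participants, trials, manifest


def run_analyze(participants: pd.DataFrame, config: PipelineConfig):
    """Fit every configured trajectory (3 outcomes x 3 DIs by default).

    Returns ``(report, fitted_values)``: a JSON-ready report with one
    entry per trajectory (step-1..4 fits, term tests, classification,
    configured sensitivity refits) and a per-participant fitted-value
    table for plotting.
    """
    validate_participants(participants)
    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "alpha": config.alpha,
        "trajectories": [],
    }
    fitted_frames = []
    for outcome in config.outcomes:
        for di in config.dis:
            model = DevelopmentalTrajectory(participants, outcome=outcome, di=di,
                                            alpha=config.alpha,
                                            cluster_robust=config.cluster_robust)
            res = model.fit()
            entry = res.to_dict()
            entry["sensitivity"] = []
            for rule in config.sensitivity:
                if outcome in rule.outcomes and di in rule.dis:
                    sens = sensitivity_refit(
                        participants, rule.exclusion(),
                        ModelSpec(outcome, di, alpha=config.alpha,
                                  step=ModelSpec.max_step(outcome)),
                        cluster_robust=config.cluster_robust,
                    )
                    entry["sensitivity"].append({
                        "rule": rule.name,
                        "n_excluded": sens.n_excluded,
                        "classification_after":
                            sens.after.to_dict().get("classification"),
                        "significance_flips": {
                            t: {"before": b, "after": a}
                            for t, (b, a) in sens.flips().items()
                        },
                    })
            report["trajectories"].append(entry)
            ft = res.fitted_effect_table()
            ft.insert(1, "outcome", outcome)
            ft.insert(2, "di", di)
            ft = ft.rename(columns={ft.columns[3]: "di_value"})
            fitted_frames.append(ft)
            logger.info("trajectory %s ~ %s: n=%d, label=%s", outcome, di,
                        res.nobs,
                        res.classification.label if res.classification else "-")
    fitted = pd.concat(fitted_frames, ignore_index=True)
    return report, fitted


def run_descriptives(participants: pd.DataFrame):
    """Sample-characteristics table, indicator correlations and the
    internal consistency of the four condition scores per group."""
    validate_participants(participants)
    table = descriptive_table(participants)
    corr = pearson_matrix(participants)
    alphas = {}
    for group, sub in participants.groupby("group"):
        items = sub[list(SPAN_COLUMNS.values())].dropna()
        alphas[group] = internal_consistency(items.to_numpy())
    report = {
        "correlations": {g: {"r": r.round(6).to_dict(), "n": n.to_dict()}
                         for g, (r, n) in corr.items()},
        "internal_consistency": alphas,
    }
    return table, report


# --- recovery harness ---------------------------------------------------------

RECOVERY_SCENARIOS = ("null", "onset", "rate", "combined")

#: Generator gaps used by the recovery scenarios (calibrated once for
#: clear power at the default sample sizes; documented in docs/methods.md).
ONSET_GAP_WORDS = 0.4          # MBID latent intercepts shifted down
RATE_GAP_WORDS_PER_MONTH = 0.012  # MBID latent slopes shallower


def _expected_min_ca(config: CohortConfig) -> float:
    """Expected minimum MBID chronological age (the rescaled DI origin),
    taken as the 1/(n+1) quantile of the truncated age marginal."""
    from scipy.stats import truncnorm

    m = config.di_means[MBID]["ca_months"]
    s = config.di_sds[MBID]["ca_months"]
    lo, hi = config.di_bounds[MBID]["ca_months"]
    a, b = (lo - m) / s, (hi - m) / s
    return float(truncnorm.ppf(1.0 / (config.n_mbid + 1), a, b, loc=m, scale=s))


def scenario_config(config: PipelineConfig, scenario: str,
                    seed: int) -> CohortConfig:
    """Build a cohort generator for one recovery scenario.

    All scenarios share the TD trajectory parameters across groups
    ("null"); "onset" lowers every MBID latent intercept by a fixed gap;
    "rate" pivots the MBID lines around the rescaled DI origin so slopes
    differ while the intercepts there stay equal; "combined" does both.
    """
    if scenario not in RECOVERY_SCENARIOS:
        raise UsageError(f"unknown scenario {scenario!r}; one of {RECOVERY_SCENARIOS}")
    base = config.cohort
    beta0 = {g: dict(base.beta0[TD]) for g in GROUPS}
    beta1 = {g: dict(base.beta1[TD]) for g in GROUPS}
    anchor = _expected_min_ca(base)
    if scenario in ("onset", "combined"):
        for cond in beta0[MBID]:
            beta0[MBID][cond] -= ONSET_GAP_WORDS
    if scenario in ("rate", "combined"):
        for cond in beta1[MBID]:
            beta1[MBID][cond] -= RATE_GAP_WORDS_PER_MONTH
            beta0[MBID][cond] += RATE_GAP_WORDS_PER_MONTH * anchor
    return dataclasses.replace(base, beta0=beta0, beta1=beta1, seed=seed)


def run_recover(config: PipelineConfig, n_replicates: int, scenario: str,
                outcome: str = "capacity", di: str = "CA",
                seed: int | None = None) -> dict:
    """Monte-Carlo validation of the trajectory classifier.

    Repeatedly generates cohorts under a known scenario, runs the full
    pipeline (engine administration included) and tabulates the
    classification labels and per-term rejection rates, with Monte-Carlo
    standard errors.
    """
    if n_replicates < 1:
        raise UsageError("n_replicates must be >= 1")
    if scenario not in RECOVERY_SCENARIOS:
        raise UsageError(f"unknown scenario {scenario!r}; one of {RECOVERY_SCENARIOS}")
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence([master, RECOVERY_SCENARIOS.index(scenario)])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]

    labels = []
    onset_rej = 0
    rate_rej = 0
    for rep_seed in child_seeds:
        cc = scenario_config(config, scenario, rep_seed)
        participants = simulate_cohort(cc, return_trials=False)
        res = DevelopmentalTrajectory(participants, outcome=outcome, di=di,
                                      alpha=config.alpha).fit()
        c = res.classification
        labels.append(c.label)
        onset_rej += c.onset_delayed
        rate_rej += c.rate_differs

    n = n_replicates
    freq = {lab: labels.count(lab) / n for lab in sorted(set(labels))}
    mcse = {lab: float(np.sqrt(p * (1 - p) / n)) for lab, p in freq.items()}
    return {
        "scenario": scenario,
        "outcome": outcome,
        "di": di,
        "n_replicates": n,
        "alpha": config.alpha,
        "label_frequencies": freq,
        "label_mcse": mcse,
        "onset_rejection_rate": onset_rej / n,
        "rate_rejection_rate": rate_rej / n,
        "rejection_mcse": float(np.sqrt(config.alpha * (1 - config.alpha) / n)),
        "seed": master,
    }
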