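"""Synthetic cohort generation.

Stands in for the unavailable raw participant data.  Each simulated child
carries three correlated developmental indicators (chronological age in
months, a cognitive-capacity raw score, a vocabulary raw score), drawn
from group-specific truncated trivariate normals, and a latent span
ability per task condition that is linear in chronological age.  The four
condition span scores are then *measured* by running the child through
the adaptive task engine with a logistic accuracy model, so the scores
inherit the engine's floor, ceiling and discreteness.

Two groups are generated: MBID (mild/borderline intellectual disability)
and TD (typically developing).  Defaults reproduce the published group
sizes (87 / 123), the indicator descriptives, their per-group correlation
structure, the mental-age measurement subsample (102 TD children;
pairwise indicator ns of 80/80/73 in the MBID group) and condition span
means, so the default cohort is a realistic stage for the trajectory
analysis.  It remains illustrative: no claim is made that real children
follow a logistic accuracy curve or exactly linear latent trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .engine import CALIBRATION, TEST, EngineConfig, DEFAULT_CONFIG
from .exceptions import ConfigError, ParameterError

MBID = "MBID"
TD = "TD"
GROUPS = (MBID, TD)

DI_NAMES = ("ca_months", "cog_raw", "voc_raw")

#: Wide-table span column per (word_length, lexicality) condition.
SPAN_COLUMNS = {
    ("short", "real"): "span_short_real",
    ("long", "real"): "span_long_real",
    ("short", "pseudo"): "span_short_pseudo",
    ("long", "pseudo"): "span_long_pseudo",
}
CONDITION_ORDER = tuple(SPAN_COLUMNS)  # fixed short->long administration order


def p_correct(theta, length, scale_s):
    """Probability of a correct repetition of a ``length``-word sequence.

    Logistic in ``(length - theta) / scale_s``: a child whose latent span
    ``theta`` equals the sequence length succeeds half the time; success
    is strictly decreasing in length and increasing in theta.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(np.asarray(scale_s) <= 0):
        raise ParameterError(f"scale_s must be > 0, got {scale_s}")
    return 1.0 / (1.0 + np.exp((np.asarray(length, dtype=float) - theta) / scale_s))


@dataclass(frozen=True)
class ResponderModel:
    """Latent-ability responder: one theta per condition, shared steepness."""

    theta: dict  # (word_length, lexicality) -> latent span in words
    scale_s: float = 0.5

    def __call__(self, length, condition, rng) -> bool:
        return bool(rng.random() < p_correct(self.theta[condition], length, self.scale_s))


# --- default generative parameters -----------------------------------------
# Indicator marginals follow the published sample descriptives (age in
# years;months converted to months); truncation bounds are the printed age
# ranges and plausible raw-score limits (the vocabulary test has 95 items).
_DEFAULT_DI_MEANS = {
    MBID: {"ca_months": 155.0, "cog_raw": 63.7, "voc_raw": 53.1},
    TD: {"ca_months": 101.0, "cog_raw": 65.4, "voc_raw": 54.7},
}
_DEFAULT_DI_SDS = {
    MBID: {"ca_months": 30.0, "cog_raw": 13.2, "voc_raw": 15.9},
    TD: {"ca_months": 22.0, "cog_raw": 13.5, "voc_raw": 14.6},
}
_DEFAULT_DI_BOUNDS = {
    MBID: {"ca_months": (88.0, 205.0), "cog_raw": (20.0, 100.0), "voc_raw": (5.0, 95.0)},
    TD: {"ca_months": (72.0, 161.0), "cog_raw": (20.0, 100.0), "voc_raw": (5.0, 95.0)},
}
# Target pairwise correlations (CA-COG, CA-VOC, COG-VOC) per group.
_DEFAULT_DI_CORR = {
    MBID: ((1.0, 0.42, 0.45), (0.42, 1.0, 0.49), (0.45, 0.49, 1.0)),
    TD: ((1.0, 0.74, 0.73), (0.74, 1.0, 0.67), (0.73, 0.67, 1.0)),
}

# Latent-trajectory preset: theta = beta0 + beta1 * CA(months) + noise.
# Slopes are common across groups (a pure delayed-onset structure);
# intercepts were calibrated by coarse search so that the simulated
# condition means land near the published cells.  Values frozen after
# calibration; see docs/methods.md.
_DEFAULT_BETA1 = {
    MBID: {("short", "real"): 0.016, ("long", "real"): 0.011,
           ("short", "pseudo"): 0.014, ("long", "pseudo"): 0.009},
    TD: {("short", "real"): 0.016, ("long", "real"): 0.011,
         ("short", "pseudo"): 0.014, ("long", "pseudo"): 0.009},
}
_DEFAULT_BETA0 = {
    MBID: {("short", "real"): 1.339, ("long", "real"): 1.504,
           ("short", "pseudo"): 0.950, ("long", "pseudo"): 0.606},
    TD: {("short", "real"): 2.327, ("long", "real"): 2.125,
         ("short", "pseudo"): 1.774, ("long", "pseudo"): 1.157},
}

_DEFAULT_P_MALE = {MBID: 48 / 87, TD: 51 / 123}


def _as_nested_dict(d):
    return {g: dict(v) for g, v in d.items()}


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort."""

    n_mbid: int = 87
    n_td: int = 123
    n_td_subsample: int = 102     # TD children with COG/VOC measured
    n_mbid_missing_cog: int = 7   # MBID children without a COG score
    n_mbid_missing_voc: int = 7   # ... without a VOC score (disjoint sets)
    di_means: dict = field(default_factory=lambda: _as_nested_dict(_DEFAULT_DI_MEANS))
    di_sds: dict = field(default_factory=lambda: _as_nested_dict(_DEFAULT_DI_SDS))
    di_bounds: dict = field(default_factory=lambda: _as_nested_dict(_DEFAULT_DI_BOUNDS))
    di_correlations: dict = field(default_factory=lambda: dict(_DEFAULT_DI_CORR))
    beta0: dict = field(default_factory=lambda: _as_nested_dict(_DEFAULT_BETA0))
    beta1: dict = field(default_factory=lambda: _as_nested_dict(_DEFAULT_BETA1))
    residual_sd: float = 0.35
    person_sd: float = 0.0  # shared person-level ability noise across conditions
    scale_s: float = 0.5
    p_male: dict = field(default_factory=lambda: dict(_DEFAULT_P_MALE))
    engine: EngineConfig = DEFAULT_CONFIG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mbid <= 0 or self.n_td <= 0:
            raise ConfigError("group sizes must be positive")
        if not 0 <= self.n_td_subsample <= self.n_td:
            raise ConfigError("n_td_subsample must be within [0, n_td]")
        if self.n_mbid_missing_cog + self.n_mbid_missing_voc > self.n_mbid:
            raise ConfigError("MBID missing-score counts exceed the group size")
        if self.residual_sd < 0 or self.person_sd < 0:
            raise ConfigError("residual_sd and person_sd must be >= 0")
        if self.scale_s <= 0:
            raise ConfigError("scale_s must be > 0")
        for g in GROUPS:
            R = np.asarray(self.di_correlations[g], dtype=float)
            if not np.allclose(R, R.T):
                raise ParameterError(f"correlation matrix for {g} is not symmetric")
            if np.linalg.eigvalsh(R).min() <= 1e-10:
                raise ParameterError(f"correlation matrix for {g} is not positive definite")

    def group_sizes(self) -> dict:
        return {MBID: self.n_mbid, TD: self.n_td}


# --- developmental indicators -----------------------------------------------

def _truncated_mvn(mean, sd, corr, bounds, n, rng):
    """Rejection-sample an MVN, keeping draws inside the per-margin bounds."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    corr = np.asarray(corr, float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    cov = corr * np.outer(sd, sd)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ParameterError("correlation matrix is not positive definite") from exc
    out = np.empty((0, 3))
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 1000)
        z = rng.standard_normal((m, 3)) @ chol.T + mean
        keep = np.all((z >= lo) & (z <= hi), axis=1)
        out = np.vstack([out, z[keep]])
    return out[:n]


@lru_cache(maxsize=32)
def _calibrated_latent(key):
    """Latent MVN parameters whose *truncated* samples hit the targets.

    Truncating the marginals shifts means, shrinks SDs and attenuates
    correlations, so the parameters fed to the sampler are adjusted by a
    deterministic fixed-point iteration (internal seed, independent of
    user randomness); results are cached per parameter set.  Returns
    ``(latent_means, latent_sds, latent_corr)``.
    """
    mean_t, sd_t, corr_target, bounds = key
    mean_t = np.asarray(mean_t, float)
    sd_t = np.asarray(sd_t, float)
    target = np.asarray(corr_target, float)
    rng = np.random.default_rng(20190109)
    mean_l = mean_t.copy()
    sd_l = sd_t.copy()
    latent = target.copy()
    iu = np.triu_indices(3, 1)
    for _ in range(12):
        draws = _truncated_mvn(mean_l, sd_l, latent, bounds, 120_000, rng)
        mean_l = mean_l + (mean_t - draws.mean(axis=0))
        sd_l = np.clip(sd_l * sd_t / draws.std(axis=0, ddof=1), 1e-9, None)
        realized = np.corrcoef(draws.T)
        adj = latent[iu] + 0.8 * (target[iu] - realized[iu])
        adj = np.clip(adj, -0.99, 0.99)
        latent = np.eye(3)
        latent[iu] = adj
        latent += latent.T - np.diag(latent.diagonal())
        # project to the nearest PD matrix if the update overshoots
        w, v = np.linalg.eigh(latent)
        if w.min() < 1e-6:
            w = np.clip(w, 1e-6, None)
            latent = v @ np.diag(w) @ v.T
            d = np.sqrt(np.diag(latent))
            latent = latent / np.outer(d, d)
    return tuple(mean_l), tuple(sd_l), tuple(map(tuple, latent))


def sample_dis(config: CohortConfig, group: str, n: int, rng) -> np.ndarray:
    """Draw ``n`` developmental-indicator triplets (CA, COG, VOC) for a group.

    Sample correlations converge to ``config.di_correlations[group]`` as
    n grows, despite the truncation of the marginals.
    """
    means = tuple(config.di_means[group][k] for k in DI_NAMES)
    sds = tuple(config.di_sds[group][k] for k in DI_NAMES)
    bounds = tuple(tuple(config.di_bounds[group][k]) for k in DI_NAMES)
    target = tuple(map(tuple, np.asarray(config.di_correlations[group], float)))
    if all(s == 0 for s in sds):
        return np.tile(np.asarray(means), (n, 1))
    if all(np.isinf(b[0]) and np.isinf(b[1]) for b in bounds):
        lat_mean, lat_sd, lat_corr = means, sds, np.asarray(target)
    else:
        lat_mean, lat_sd, lat_corr = _calibrated_latent((means, sds, target, bounds))
        lat_corr = np.asarray(lat_corr)
    return _truncated_mvn(lat_mean, lat_sd, lat_corr, bounds, n, rng)


def latent_theta(di_value, group: str, condition, config: CohortConfig, rng=None):
    """Latent span for one condition: linear in the developmental indicator.

    ``theta = beta0(group, condition) + beta1(group, condition) * di +
    Normal(0, residual_sd)``.  Pass ``rng=None`` for the noise-free line.
    """
    di_value = np.asarray(di_value, dtype=float)
    theta = config.beta0[group][condition] + config.beta1[group][condition] * di_value
    if rng is not None and config.residual_sd > 0:
        theta = theta + rng.normal(0.0, config.residual_sd, size=theta.shape)
    return theta


# --- batch administration ----------------------------------------------------

def administer_batch(theta, scale_s, config: EngineConfig, rng, uniforms=None):
    """Vectorised staircase: run many administrations at once.

    Implements exactly the logic of :func:`spantraj.engine.administer`
    (calibration adapting every item, test adapting after pairs, clamped
    bounds) across a vector of responders.  ``uniforms`` may inject the
    (n, n_trials) uniform draws, used to prove equivalence with the
    scalar engine.

    Returns ``(lengths, correct, points, span)`` with per-trial arrays of
    shape ``(n, n_calibration + n_test)``.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[0]
    n_trials = config.n_trials
    if uniforms is None:
        uniforms = rng.random((n, n_trials))
    lengths = np.empty((n, n_trials), dtype=int)
    correct = np.empty((n, n_trials), dtype=bool)

    cur = np.full(n, config.start_length, dtype=int)
    for t in range(config.n_calibration):
        lengths[:, t] = cur
        correct[:, t] = uniforms[:, t] < p_correct(theta, cur, scale_s)
        cur = np.clip(cur + np.where(correct[:, t], 1, -1),
                      config.min_length, config.max_length)
    prev = np.zeros(n, dtype=bool)
    for j in range(config.n_test):
        t = config.n_calibration + j
        lengths[:, t] = cur
        correct[:, t] = uniforms[:, t] < p_correct(theta, cur, scale_s)
        if j % 2 == 1:  # a pair has completed
            step = np.where(prev & correct[:, t], 1,
                            np.where(~prev & ~correct[:, t], -1, 0))
            cur = np.clip(cur + step, config.min_length, config.max_length)
        prev = correct[:, t]

    points = np.where(correct, lengths, lengths - 1)
    span = points[:, config.n_calibration:].mean(axis=1)
    return lengths, correct, points, span


# --- cohort simulation --------------------------------------------------------

def simulate_cohort(config: CohortConfig | None = None, *, return_trials: bool = True):
    """Generate a full synthetic cohort and administer the four span tasks.

    For each participant the engine runs the conditions in the fixed
    short-before-long order with a randomly assigned lexicality order
    (recorded as metadata; the generative model carries no practice
    effects, so scores do not depend on it).  Fully reproducible from
    ``config.seed`` via named substreams.

    Returns ``(participants, trials)`` DataFrames, or just
    ``participants`` when ``return_trials=False``.
    """
    if config is None:
        config = CohortConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_di, rng_sex, rng_lex, rng_resp, rng_theta, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    frames = []
    trial_frames = []
    offset = 0
    for group in GROUPS:
        n = config.group_sizes()[group]
        dis = sample_dis(config, group, n, rng_di)
        sex = np.where(rng_sex.random(n) < config.p_male[group], "male", "female")
        lex_order = np.where(rng_lex.random(n) < 0.5, "real_first", "pseudo_first")
        ids = [f"{group.lower()}_{i + 1:03d}" for i in range(n)]

        part = pd.DataFrame({
            "participant_id": ids,
            "group": group,
            "sex": sex,
            "ca_months": dis[:, 0],
            "cog_raw": dis[:, 1],
            "voc_raw": dis[:, 2],
            "lexicality_order": lex_order,
        })

        person = (rng_theta.normal(0.0, config.person_sd, size=n)
                  if config.person_sd > 0 else 0.0)
        for condition in CONDITION_ORDER:
            theta = person + latent_theta(dis[:, 0], group, condition, config, rng_theta)
            lengths, corr_arr, points, span = administer_batch(
                theta, config.scale_s, config.engine, rng_resp
            )
            part[SPAN_COLUMNS[condition]] = span
            if return_trials:
                n_trials = config.engine.n_trials
                phase = np.array(
                    [CALIBRATION] * config.engine.n_calibration
                    + [TEST] * config.engine.n_test
                )
                trial_frames.append(pd.DataFrame({
                    "participant_id": np.repeat(ids, n_trials),
                    "condition_length": condition[0],
                    "condition_lexicality": condition[1],
                    "phase": np.tile(phase, n),
                    "trial_index": np.tile(np.arange(n_trials), n),
                    "sequence_length": lengths.ravel(),
                    "correct": corr_arr.ravel(),
                    "points": points.ravel(),
                }))
        frames.append(part)
        offset += n

    participants = pd.concat(frames, ignore_index=True)

    # measurement subsampling: COG/VOC only exist where they were "tested"
    td_idx = participants.index[participants["group"] == TD]
    drop_td = rng_miss.choice(td_idx, size=config.n_td - config.n_td_subsample,
                              replace=False)
    participants.loc[drop_td, ["cog_raw", "voc_raw"]] = np.nan
    mbid_idx = participants.index[participants["group"] == MBID].to_numpy()
    n_miss = config.n_mbid_missing_cog + config.n_mbid_missing_voc
    miss = rng_miss.choice(mbid_idx, size=n_miss, replace=False)
    participants.loc[miss[: config.n_mbid_missing_cog], "cog_raw"] = np.nan
    participants.loc[miss[config.n_mbid_missing_cog:], "voc_raw"] = np.nan

    if return_trials:
        trials = pd.concat(trial_frames, ignore_index=True)
        return participants, trials
    return participants
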