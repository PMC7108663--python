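"""Synthetic participants: count-based learners with condition-dependent
assimilation.

Each simulated participant maintains, per agent, a vector of pseudo-observed
choice counts (a symmetric Dirichlet prior plus the agent's observed
choices), and per condition a pooled count vector over every observed choice
by that condition's agents.  Before each trial the predictive distribution
for the shown agent is the mixture

    (1 - w_c) * normalize(individual counts) + w_c * normalize(pooled counts)

where the assimilation weight ``w_c`` is ``w_logo`` for Logo agents and
``w_nologo`` for NoLogo agents.  A larger weight pulls predictions toward
the condition's aggregate behavior — the generative analogue of social
assimilation.  The prediction is either the argmax of the mixture (ties
broken uniformly at random) or a softmax draw; with a small probability the
trial is recorded as missed (no prediction), but the agent's actual choice
is still observed and both count stores are updated.

Both conditions pool; they differ only in the weight, so setting
``w_logo == w_nologo`` yields a cohort that is exchangeable across
conditions up to the design's mirror reflection (a null simulator for
calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    CONDITIONS,
    LOGO,
    NOLOGO,
    N_VASES,
    AgentSpec,
    DesignConfig,
    ScheduleEntry,
    build_agents,
    build_schedule,
)

TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "global_trial_index",
    "agent_id",
    "condition",
    "presentation_index",
    "predicted_vase",
    "actual_choice",
    "missed",
]


@dataclass(frozen=True)
class LearnerParams:
    """Parameters of the assimilating count learner.

    ``prior_concentration`` is the symmetric pseudo-observation count per
    vase, applied to every individual store and to each condition pool.
    ``w_logo`` / ``w_nologo`` are the assimilation weights in [0, 1].
    ``policy`` maps the predictive mixture to a prediction: ``"argmax"``
    (the instructed most-likely choice, ties uniform) or ``"softmax"``
    (probability proportional to exp(p / temperature)).  ``miss_rate`` is
    the per-trial probability of a timeout with no recorded prediction.
    """

    w_logo: float = 0.5
    w_nologo: float = 0.1
    prior_concentration: float = 1.0
    policy: str = "argmax"
    temperature: float = 0.1
    miss_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_logo <= 1.0 or not 0.0 <= self.w_nologo <= 1.0:
            raise ValueError("assimilation weights must lie in [0, 1]")
        if self.prior_concentration <= 0:
            raise ValueError("prior_concentration must be positive")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must lie in [0, 1)")
        if self.policy not in ("argmax", "softmax"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy == "softmax" and self.temperature <= 0:
            raise ValueError("temperature must be positive")


def sample_agent_choice(agent: AgentSpec, rng: np.random.Generator) -> int:
    """One draw from the agent's induced 4-vase distribution."""
    return int(rng.choice(N_VASES, p=agent.choice_probs))


def _sample_rows(cum: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row from row-wise cumulative probabilities."""
    u = rng.random(cum.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def _mixture_trajectories(
    agent_ids: np.ndarray,
    conditions: np.ndarray,
    actual: np.ndarray,
    params: LearnerParams,
) -> np.ndarray:
    """Per-trial predictive mixture, from counts *before* each trial.

    The count trajectories depend only on the agents' actual choices, never
    on the learner's predictions, so they can be formed in one pass.
    """
    n = len(actual)
    onehot = np.zeros((n, N_VASES))
    onehot[np.arange(n), actual] = 1.0

    ind_before = np.empty((n, N_VASES))
    for aid in np.unique(agent_ids):
        m = agent_ids == aid
        ind_before[m] = np.cumsum(onehot[m], axis=0) - onehot[m]
    pool_before = np.empty((n, N_VASES))
    for cond in np.unique(conditions):
        m = conditions == cond
        pool_before[m] = np.cumsum(onehot[m], axis=0) - onehot[m]

    pc = params.prior_concentration
    ind_c = ind_before + pc
    pool_c = pool_before + pc
    ind_p = ind_c / ind_c.sum(axis=1, keepdims=True)
    pool_p = pool_c / pool_c.sum(axis=1, keepdims=True)
    w = np.where(conditions == LOGO, params.w_logo, params.w_nologo)[:, None]
    return (1.0 - w) * ind_p + w * pool_p


def simulate_participant(
    participant_id: int,
    agents: list[AgentSpec],
    schedule: list[ScheduleEntry],
    params: LearnerParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run one participant through the full schedule; one row per trial.

    ``predicted_vase`` is a nullable integer column, NA on missed trials.
    """
    agent_by_id = {a.agent_id: a for a in agents}
    unknown = {e.agent_id for e in schedule} - set(agent_by_id)
    if unknown:
        raise ValueError(f"schedule references unknown agents: {sorted(unknown)}")

    agent_ids = np.array([e.agent_id for e in schedule])
    conditions = np.array([agent_by_id[a].condition for a in agent_ids])
    probs = np.stack([agent_by_id[a].choice_probs for a in agent_ids])
    n = len(schedule)

    actual = _sample_rows(np.cumsum(probs, axis=1), rng)
    mixture = _mixture_trajectories(agent_ids, conditions, actual, params)

    if params.policy == "argmax":
        # uniform tie-break: among the maxima, pick the one with the largest
        # iid uniform mark
        is_max = mixture >= mixture.max(axis=1, keepdims=True) - 1e-12
        marks = rng.random(mixture.shape) * is_max
        predicted = marks.argmax(axis=1)
    else:
        z = np.exp((mixture - mixture.max(axis=1, keepdims=True)) / params.temperature)
        z /= z.sum(axis=1, keepdims=True)
        predicted = _sample_rows(np.cumsum(z, axis=1), rng)

    missed = rng.random(n) < params.miss_rate

    df = pd.DataFrame(
        {
            "participant_id": participant_id,
            "block": [e.block for e in schedule],
            "global_trial_index": [e.global_trial_index for e in schedule],
            "agent_id": agent_ids,
            "condition": conditions,
            "presentation_index": [e.presentation_index for e in schedule],
            "predicted_vase": pd.array(predicted, dtype="Int64"),
            "actual_choice": actual,
            "missed": missed,
        }
    )
    df.loc[df["missed"], "predicted_vase"] = pd.NA
    return df[TRIAL_COLUMNS]


def cohort_designs(
    n_participants: int, base_config: DesignConfig
) -> dict[int, list[AgentSpec]]:
    """Counterbalanced agent rosters, one per participant (deterministic)."""
    return {
        pid: build_agents(base_config.variant_for(pid))
        for pid in range(n_participants)
    }


def simulate_cohort(
    n_participants: int,
    params: LearnerParams,
    base_config: DesignConfig,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Simulate a counterbalanced cohort with independent RNG streams.

    Each participant's design variant is derived from their id (mod 4) and
    their randomness from an independently spawned child of ``seed``.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    frames = []
    for pid, child in enumerate(ss.spawn(n_participants)):
        cfg = base_config.variant_for(pid)
        rng = np.random.default_rng(child)
        agents = build_agents(cfg)
        schedule = build_schedule(agents, cfg, rng)
        frames.append(simulate_participant(pid, agents, schedule, params, rng))
    return pd.concat(frames, ignore_index=True)


def fit_assimilation_weights(
    trials: pd.DataFrame,
    base_config: DesignConfig,
    params: LearnerParams,
    grid: np.ndarray | None = None,
) -> dict:
    """Grid maximum-likelihood fit of (w_logo, w_nologo) from a trial table.

    Replays each participant's individual and pooled count trajectories from
    the recorded actual choices (these do not depend on the weights), then
    evaluates the softmax-policy log-likelihood of the recorded predictions
    on a grid of candidate weights, per condition.  Because a trial's
    predictive mixture involves only its own condition's weight, the two
    weights are fitted independently.

    Returns a dict with ``w_logo``, ``w_nologo``, the grid, and the
    per-condition log-likelihood profiles.
    """
    if params.policy != "softmax":
        raise ValueError("weight recovery is defined for the softmax policy")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    loglik = {c: np.zeros_like(grid) for c in CONDITIONS}
    pc = params.prior_concentration

    for pid, sub in trials.groupby("participant_id"):
        sub = sub.sort_values("global_trial_index")
        agent_ids = sub["agent_id"].to_numpy()
        conditions = sub["condition"].to_numpy()
        actual = sub["actual_choice"].to_numpy(dtype=int)
        n = len(sub)
        onehot = np.zeros((n, N_VASES))
        onehot[np.arange(n), actual] = 1.0
        ind_before = np.empty((n, N_VASES))
        for aid in np.unique(agent_ids):
            m = agent_ids == aid
            ind_before[m] = np.cumsum(onehot[m], axis=0) - onehot[m]
        pool_before = np.empty((n, N_VASES))
        for cond in np.unique(conditions):
            m = conditions == cond
            pool_before[m] = np.cumsum(onehot[m], axis=0) - onehot[m]
        ind_p = (ind_before + pc) / (ind_before + pc).sum(axis=1, keepdims=True)
        pool_p = (pool_before + pc) / (pool_before + pc).sum(axis=1, keepdims=True)

        observed = ~sub["missed"].to_numpy(dtype=bool)
        pred = sub["predicted_vase"].to_numpy(dtype=object)
        for cond in CONDITIONS:
            m = observed & (conditions == cond)
            if not m.any():
                continue
            k = pred[m].astype(int)
            # mixture for every grid value: (trials, grid, vases)
            mix = (
                (1.0 - grid)[None, :, None] * ind_p[m][:, None, :]
                + grid[None, :, None] * pool_p[m][:, None, :]
            )
            z = mix / params.temperature
            z -= z.max(axis=2, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=2, keepdims=True))
            loglik[cond] += logp[np.arange(m.sum()), :, k].sum(axis=0)

    return {
        "grid": grid,
        "loglik_logo": loglik[LOGO],
        "loglik_nologo": loglik[NOLOGO],
        "w_logo": float(grid[np.argmax(loglik[LOGO])]),
        "w_nologo": float(grid[np.argmax(loglik[NOLOGO])]),
    }
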