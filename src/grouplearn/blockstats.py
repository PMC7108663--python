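"""Block-level divergence tables and the 2x2 repeated-measures ANOVA.

For each participant and condition the analysis asks two questions: how far
are the participant's prediction distributions from each agent's own
preference (Individual level), and how far are they from the condition's
group-level preference (Group level)?  Averaging the per-agent KL
divergences yields one value per participant x condition x level — the four
cells of a fully within-subject 2x2 design (Condition x Level).

The ANOVA is computed by the within-subject contrast method: each 1-df
effect is a per-participant contrast score whose one-sample t statistic
gives F = t^2 with df (1, n-1).  For a 2x2 within design this is
algebraically identical to the full sums-of-squares decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS, AgentSpec, block1_agents, block2_agents, group_preference
from .divergence import kl_divergence, prediction_distribution

INDIVIDUAL = "Individual"
GROUP = "Group"
LEVELS = (INDIVIDUAL, GROUP)

CELLS = [(c, l) for c in CONDITIONS for l in LEVELS]


def divergence_table(
    records: pd.DataFrame,
    designs: dict[int, list[AgentSpec]],
    block: int = 1,
    pseudocount: float = 1.0,
    block2_agent_set: str = "new_only",
) -> pd.DataFrame:
    """Per-participant KL divergence table, the ANOVA's cell data.

    Block 1 analyzes the four original agents of each condition over
    Block-1 trials; Block 2 analyzes, by default, only the newly introduced
    agent of each condition over Block-2 trials (``block2_agent_set="all"``
    additionally scores the old agents' sparse Block-2 trials).  The
    group-level reference is always the condition's Block-1 group
    preference.  Prediction distributions use the smooth-only-when-needed
    convention.

    Returns a tidy frame (participant_id, condition, level, kl_bits) with
    exactly four rows per participant.
    """
    if block not in (1, 2):
        raise ValueError("block must be 1 or 2")
    if block2_agent_set not in ("new_only", "all"):
        raise ValueError(f"unknown block2_agent_set {block2_agent_set!r}")

    rows = []
    for pid, sub in records[records["block"] == block].groupby("participant_id"):
        pid = int(pid)
        if pid not in designs:
            raise KeyError(f"no design for participant {pid}")
        agents = designs[pid]
        for cond in CONDITIONS:
            group_vec = group_preference(agents, cond).vector
            if block == 1:
                analyzed = block1_agents(agents, cond)
            elif block2_agent_set == "new_only":
                analyzed = block2_agents(agents, cond)
            else:
                analyzed = block2_agents(agents, cond) + block1_agents(agents, cond)
            ind_kls, grp_kls = [], []
            for agent in analyzed:
                try:
                    pdist = prediction_distribution(
                        sub,
                        agent_id=agent.agent_id,
                        smoothing_mode="if_zero",
                        pseudocount=pseudocount,
                    )
                except ValueError as err:
                    raise ValueError(
                        f"participant {pid}, agent {agent.agent_id}: {err}"
                    ) from err
                ind_kls.append(kl_divergence(agent.choice_probs, pdist.probs))
                grp_kls.append(kl_divergence(group_vec, pdist.probs))
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "level": INDIVIDUAL,
                    "kl_bits": float(np.mean(ind_kls)),
                }
            )
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "level": GROUP,
                    "kl_bits": float(np.mean(grp_kls)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t(x, y) -> TTestResult:
    """Classical paired-sample t-test on x - y, two-tailed.

    Zero variance of the differences is flagged as degenerate rather than
    raised, since it occurs legitimately for constructed fixtures.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return TTestResult(t=np.nan if d.mean() else 0.0, df=n - 1,
                           p=np.nan if d.mean() else 1.0, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p))


@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    degenerate: bool = False


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    cell_means: dict[tuple[str, str], float] = field(default_factory=dict)
    cell_sds: dict[tuple[str, str], float] = field(default_factory=dict)
    n_participants: int = 0

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "effects": {
                name: vars(e) for name, e in self.effects.items()
            },
            "cell_means": {f"{c}/{l}": v for (c, l), v in self.cell_means.items()},
            "cell_sds": {f"{c}/{l}": v for (c, l), v in self.cell_sds.items()},
        }


def _cell_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    """Participants x 4 cell matrix in CELLS order; errors on missing cells."""
    wide = table.pivot_table(
        index="participant_id",
        columns=["condition", "level"],
        values="kl_bits",
        aggfunc="first",
    )
    missing = [c for c in CELLS if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(f"incomplete 2x2 cell data (missing {missing or 'values'})")
    wide = wide[CELLS]
    return wide.to_numpy(dtype=float), list(wide.index)


def _contrast_effect(scores: np.ndarray) -> EffectResult:
    n = len(scores)
    mean = scores.mean()
    ss_effect = n * mean**2
    ss_error = float(np.sum((scores - mean) ** 2))
    if np.ptp(scores) == 0:
        # zero error variance: a constant-zero contrast is a perfect null,
        # any other constant makes F undefined
        if scores[0] == 0:
            return EffectResult(
                F=0.0, df_num=1, df_den=n - 1, p=1.0,
                partial_eta_sq=0.0, degenerate=True,
            )
        return EffectResult(
            F=np.nan, df_num=1, df_den=n - 1, p=np.nan,
            partial_eta_sq=np.nan, degenerate=True,
        )
    F = ss_effect / (ss_error / (n - 1))
    p = float(stats.f.sf(F, 1, n - 1))
    return EffectResult(
        F=float(F),
        df_num=1,
        df_den=n - 1,
        p=p,
        partial_eta_sq=float(ss_effect / (ss_effect + ss_error)),
    )


def rm_anova_2x2(table: pd.DataFrame) -> AnovaResult:
    """Two-way fully repeated-measures ANOVA on the divergence table.

    Effects: Condition (Logo vs. NoLogo), Level (Individual vs. Group) and
    their interaction, each with df (1, n-1) and partial eta squared
    SS_effect / (SS_effect + SS_error).  All-identical cells across
    participants give zero error variance and are flagged as degenerate.
    """
    cells, pids = _cell_matrix(table)
    n = len(pids)
    if n < 2:
        raise ValueError("need at least 2 participants")
    li, lg, ni, ng = cells.T  # Logo/Ind, Logo/Grp, NoLogo/Ind, NoLogo/Grp

    effects = {
        "condition": _contrast_effect((li + lg) / 2 - (ni + ng) / 2),
        "level": _contrast_effect((li + ni) / 2 - (lg + ng) / 2),
        "interaction": _contrast_effect((li - lg) - (ni - ng)),
    }
    means = {cell: float(cells[:, i].mean()) for i, cell in enumerate(CELLS)}
    sds = {cell: float(cells[:, i].std(ddof=1)) for i, cell in enumerate(CELLS)}
    return AnovaResult(effects=effects, cell_means=means, cell_sds=sds, n_participants=n)


def posthoc_level_tests(table: pd.DataFrame) -> dict[str, TTestResult]:
    """Paired t-tests of Logo vs. NoLogo within each level (interaction
    follow-up)."""
    cells, _ = _cell_matrix(table)
    li, lg, ni, ng = cells.T
    return {INDIVIDUAL: paired_t(li, ni), GROUP: paired_t(lg, ng)}
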