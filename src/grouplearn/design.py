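"""Agent population and trial schedules for the preference-prediction task.

The task shows a participant a sequence of animated agents, each of whom
repeatedly chooses one of four vases that vary on two binary dimensions
(color: stone vs. wood; shape: pear vs. cone).  Half of the agents wear a
common logo (the Logo condition), the other half do not (NoLogo).  Each
agent's choice tendency factorizes over the two dimensions, so a pair of
Bernoulli parameters (``p_color``, ``p_shape``) induces a categorical
distribution over the four vases.

The roster is built under strict symmetry constraints: within a condition
the individual preferences are arranged symmetrically around the condition's
group mean, across conditions each agent has a mirror image, the group mean
deviates from uniform on exactly one dimension, and the grand mean over all
eight first-block agents is uniform so that every vase is chosen equally
often in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

LOGO = "Logo"
NOLOGO = "NoLogo"
CONDITIONS = (LOGO, NOLOGO)

#: Vase index convention: row-major over (color, shape) with phenotype A first.
#: 0 = (color A, shape A), 1 = (color A, shape B), 2 = (color B, shape A),
#: 3 = (color B, shape B).
N_VASES = 4


class DesignError(ValueError):
    """A design configuration violates a structural constraint."""


@dataclass(frozen=True)
class FactorPreference:
    """An agent's choice tendency as two independent Bernoulli parameters.

    ``p_color`` is the probability of phenotype A on the color dimension,
    ``p_shape`` the probability of phenotype A on the shape dimension.
    """

    p_color: float
    p_shape: float

    def __post_init__(self) -> None:
        for name in ("p_color", "p_shape"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name}={v!r} outside [0, 1]")

    def mirrored(self) -> "FactorPreference":
        """Reflection of both dimensions around 0.5."""
        return FactorPreference(1.0 - self.p_color, 1.0 - self.p_shape)


@dataclass(frozen=True)
class CategoricalPreference:
    """A categorical distribution over the four vases."""

    probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_VASES,):
            raise DesignError("preference must have exactly 4 probabilities")
        if np.any(p < 0):
            raise DesignError("negative probability")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise DesignError(f"probabilities sum to {p.sum()!r}, not 1")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    def marginals(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(color, shape) marginal distributions, phenotype A first."""
        p = self.vector
        color = (float(p[0] + p[1]), float(p[2] + p[3]))
        shape = (float(p[0] + p[2]), float(p[1] + p[3]))
        return color, shape


def product_preference(pref: FactorPreference) -> CategoricalPreference:
    """Induce the 4-vase distribution as the outer product of the two
    Bernoulli dimensions (the dimensions are chosen independently)."""
    pc, ps = pref.p_color, pref.p_shape
    return CategoricalPreference(
        (pc * ps, pc * (1.0 - ps), (1.0 - pc) * ps, (1.0 - pc) * (1.0 - ps))
    )


@dataclass(frozen=True)
class AgentSpec:
    agent_id: str
    condition: str
    sex: str
    block_introduced: int
    preference: FactorPreference

    @property
    def choice_probs(self) -> np.ndarray:
        return product_preference(self.preference).vector


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the two-condition, two-block experimental design.

    ``group_dimension`` is the vase dimension on which the two groups'
    mean preferences deviate from uniform; ``group_phenotype_logo`` is the
    phenotype ('A' or 'B') the Logo group favors on that dimension.  The
    offsets are deviations from 0.5 used to place individual agents:
    ``strong_offset`` for the two both-dimension agents, ``single_offset``
    for the single-dimension agent and the second-block agents.
    """

    group_dimension: str = "shape"
    group_phenotype_logo: str = "A"
    strong_offset: float = 0.3
    single_offset: float = 0.3
    seed: int | None = None
    n_block1_trials_per_agent: int = 50
    n_block2_new_agent_trials: int = 30
    n_block2_old_agent_trials_total: int = 40

    def __post_init__(self) -> None:
        if self.group_dimension not in ("color", "shape"):
            raise DesignError(f"group_dimension={self.group_dimension!r}")
        if self.group_phenotype_logo not in ("A", "B"):
            raise DesignError(f"group_phenotype_logo={self.group_phenotype_logo!r}")
        for name in ("strong_offset", "single_offset"):
            v = getattr(self, name)
            if not 0.0 < v <= 0.5:
                raise DesignError(f"{name}={v!r} outside (0, 0.5]")
        for name in (
            "n_block1_trials_per_agent",
            "n_block2_new_agent_trials",
            "n_block2_old_agent_trials_total",
        ):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be non-negative")

    def variant_for(self, participant_id: int) -> "DesignConfig":
        """Counterbalance variant for one participant.

        Group dimension and favored phenotype rotate over participants
        (``participant_id mod 4``), mirroring the between-participant
        counterbalancing of the design.
        """
        variant = participant_id % 4
        return dataclasses.replace(
            self,
            group_dimension=("color", "shape")[variant % 2],
            group_phenotype_logo=("A", "B")[variant // 2],
        )


def _pref(offsets: tuple[float, float], group_dimension: str) -> FactorPreference:
    """Build a FactorPreference from (group-dim, other-dim) offsets."""
    g, o = offsets
    if group_dimension == "shape":
        return FactorPreference(0.5 + o, 0.5 + g)
    return FactorPreference(0.5 + g, 0.5 + o)


def build_agents(config: DesignConfig) -> list[AgentSpec]:
    """Construct the ten agents (8 first-block + 2 second-block).

    Per condition, the first-block roster is: two agents with a preference
    on both dimensions, one with a preference on the group dimension only,
    and one with no preference at all (uniform).  The NoLogo roster is the
    Logo roster reflected on both dimensions.  Second-block agents deviate
    from 0.5 only on the non-group dimension, so their preference is
    orthogonal to the group-level preference.
    """
    s = config.strong_offset
    g1 = config.single_offset
    sign = 1.0 if config.group_phenotype_logo == "A" else -1.0
    # (group-dim offset, other-dim offset) for the Logo roster
    logo_offsets = [
        (sign * s, sign * s),  # both-dimension agent
        (sign * s, -sign * s),  # both-dimension agent, opposite other-dim
        (sign * g1, 0.0),  # single-dimension agent (group dimension)
        (0.0, 0.0),  # uniform agent
    ]
    new_offsets = (0.0, sign * config.single_offset)  # non-group dimension only

    sexes = ("F", "M", "F", "M")
    agents: list[AgentSpec] = []
    for i, (off, sex) in enumerate(zip(logo_offsets, sexes), start=1):
        pref = _pref(off, config.group_dimension)
        agents.append(AgentSpec(f"L{i}", LOGO, sex, 1, pref))
        agents.append(AgentSpec(f"N{i}", NOLOGO, sex, 1, pref.mirrored()))
    new_pref = _pref(new_offsets, config.group_dimension)
    agents.append(AgentSpec("L5", LOGO, "F", 2, new_pref))
    agents.append(AgentSpec("N5", NOLOGO, "M", 2, new_pref.mirrored()))
    return agents


def block1_agents(agents: Sequence[AgentSpec], condition: str | None = None) -> list[AgentSpec]:
    return [
        a
        for a in agents
        if a.block_introduced == 1 and (condition is None or a.condition == condition)
    ]


def block2_agents(agents: Sequence[AgentSpec], condition: str | None = None) -> list[AgentSpec]:
    return [
        a
        for a in agents
        if a.block_introduced == 2 and (condition is None or a.condition == condition)
    ]


def group_preference(agents: Sequence[AgentSpec], condition: str) -> CategoricalPreference:
    """Group-level preference: the unweighted mean of the condition's four
    first-block individual distributions."""
    members = block1_agents(agents, condition)
    if not members:
        raise DesignError(f"no block-1 agents in condition {condition!r}")
    mean = np.mean([a.choice_probs for a in members], axis=0)
    return CategoricalPreference(tuple(mean))


@dataclass(frozen=True)
class ScheduleEntry:
    block: int
    global_trial_index: int
    agent_id: str
    presentation_index: int


def build_schedule(
    agents: Sequence[AgentSpec], config: DesignConfig, rng: np.random.Generator
) -> list[ScheduleEntry]:
    """Randomized trial order for both blocks.

    Block 1 presents each of the 8 first-block agents
    ``n_block1_trials_per_agent`` times in a uniformly random order.  Block 2
    presents each new agent ``n_block2_new_agent_trials`` times and spreads
    ``n_block2_old_agent_trials_total`` trials evenly over the old agents.
    Presentation indices count each agent's appearances from 1 and continue
    across blocks.
    """
    old = [a.agent_id for a in block1_agents(agents)]
    new = [a.agent_id for a in block2_agents(agents)]
    n_old_total = config.n_block2_old_agent_trials_total
    if old and n_old_total % len(old) != 0:
        raise DesignError(
            f"{n_old_total} old-agent trials not divisible over {len(old)} agents"
        )
    per_old_block2 = n_old_total // len(old) if old else 0

    block1_ids = np.repeat(old, config.n_block1_trials_per_agent)
    block1_ids = rng.permutation(block1_ids)
    block2_ids = np.concatenate(
        [
            np.repeat(new, config.n_block2_new_agent_trials),
            np.repeat(old, per_old_block2),
        ]
    )
    block2_ids = rng.permutation(block2_ids) if len(block2_ids) else block2_ids

    schedule: list[ScheduleEntry] = []
    counts: dict[str, int] = {}
    t = 0
    for block, ids in ((1, block1_ids), (2, block2_ids)):
        for aid in ids:
            aid = str(aid)
            t += 1
            counts[aid] = counts.get(aid, 0) + 1
            schedule.append(ScheduleEntry(block, t, aid, counts[aid]))
    return schedule


@dataclass
class DesignReport:
    """Outcome of validating a design against its structural constraints."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, bool(ok), detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[str]:
        return [name for name, ok, _ in self.checks if not ok]

    def __str__(self) -> str:
        lines = []
        for name, ok, detail in self.checks:
            mark = "PASS" if ok else "FAIL"
            lines.append(f"[{mark}] {name}" + (f": {detail}" if detail else ""))
        return "\n".join(lines)


def validate_design(
    agents: Sequence[AgentSpec],
    schedule: Sequence[ScheduleEntry] | None = None,
    config: DesignConfig | None = None,
    atol: float = 1e-9,
) -> DesignReport:
    """Check every structural invariant of the design; reports, never raises."""
    report = DesignReport()
    by_cond = {c: block1_agents(agents, c) for c in CONDITIONS}

    for c in CONDITIONS:
        roster = by_cond[c]
        report.add(
            f"roster_size_{c}", len(roster) == 4, f"{len(roster)} block-1 agents"
        )
        sexes = sorted(a.sex for a in roster)
        report.add(f"sex_balance_{c}", sexes == ["F", "F", "M", "M"], str(sexes))
        n_new = len(block2_agents(agents, c))
        report.add(f"one_new_agent_{c}", n_new == 1, f"{n_new} block-2 agents")

    if all(len(by_cond[c]) == 4 for c in CONDITIONS):
        # mirror pairing across conditions
        logo_set = sorted(
            (a.preference.p_color, a.preference.p_shape) for a in by_cond[LOGO]
        )
        mirror_set = sorted(
            (1 - a.preference.p_color, 1 - a.preference.p_shape)
            for a in by_cond[NOLOGO]
        )
        mirrored = all(
            abs(x1 - x2) < atol and abs(y1 - y2) < atol
            for (x1, y1), (x2, y2) in zip(logo_set, mirror_set)
        )
        report.add("cross_condition_mirror", mirrored)

        for c in CONDITIONS:
            gp = group_preference(agents, c)
            color_m, shape_m = gp.marginals()
            dev_color = abs(color_m[0] - 0.5) > atol
            dev_shape = abs(shape_m[0] - 0.5) > atol
            report.add(
                f"group_mean_single_dimension_{c}",
                dev_color != dev_shape,
                f"color marginal {color_m[0]:.4f}, shape marginal {shape_m[0]:.4f}",
            )
            # within-condition symmetry around the group mean on the non-group dim
            non_group = "p_color" if dev_shape else "p_shape"
            vals = sorted(getattr(a.preference, non_group) for a in by_cond[c])
            sym = all(
                abs((v + w) - 1.0) < atol for v, w in zip(vals, reversed(vals))
            )
            report.add(f"within_condition_symmetry_{c}", sym, f"{non_group}={vals}")

        grand = np.mean([a.choice_probs for a in block1_agents(agents)], axis=0)
        report.add(
            "grand_mean_uniform",
            bool(np.allclose(grand, 0.25, atol=atol)),
            np.array2string(grand, precision=4),
        )

        for c in CONDITIONS:
            gp = group_preference(agents, c)
            color_m, shape_m = gp.marginals()
            group_dim_is_shape = abs(shape_m[0] - 0.5) > atol
            for a in block2_agents(agents, c):
                pc, ps = a.preference.p_color, a.preference.p_shape
                on_group = abs((ps if group_dim_is_shape else pc) - 0.5) < atol
                off_group = abs((pc if group_dim_is_shape else ps) - 0.5) > atol
                report.add(
                    f"new_agent_orthogonal_{a.agent_id}",
                    on_group and off_group,
                    f"p_color={pc}, p_shape={ps}",
                )

    if schedule is not None:
        cfg = config or DesignConfig()
        b1 = [e for e in schedule if e.block == 1]
        b2 = [e for e in schedule if e.block == 2]
        n_b1_expected = 8 * cfg.n_block1_trials_per_agent
        report.add("block1_length", len(b1) == n_b1_expected, f"{len(b1)} trials")
        n_b2_expected = (
            2 * cfg.n_block2_new_agent_trials + cfg.n_block2_old_agent_trials_total
        )
        report.add("block2_length", len(b2) == n_b2_expected, f"{len(b2)} trials")

        from collections import Counter

        c1 = Counter(e.agent_id for e in b1)
        old_ids = {a.agent_id for a in block1_agents(agents)}
        report.add(
            "block1_counts",
            set(c1) == old_ids
            and all(v == cfg.n_block1_trials_per_agent for v in c1.values()),
            str(dict(c1)),
        )
        c2 = Counter(e.agent_id for e in b2)
        new_ids = {a.agent_id for a in block2_agents(agents)}
        ok_new = all(c2.get(i, 0) == cfg.n_block2_new_agent_trials for i in new_ids)
        per_old = cfg.n_block2_old_agent_trials_total // max(len(old_ids), 1)
        ok_old = all(c2.get(i, 0) == per_old for i in old_ids)
        report.add("block2_counts", ok_new and ok_old, str(dict(c2)))

        seen: dict[str, int] = {}
        ok_pres = True
        for e in schedule:
            seen[e.agent_id] = seen.get(e.agent_id, 0) + 1
            if e.presentation_index != seen[e.agent_id]:
                ok_pres = False
                break
        report.add("presentation_indices", ok_pres)

    return report


def agents_to_frame(agents: Sequence[AgentSpec]):
    """Tidy per-agent table (one row per agent, preference and vase probs)."""
    import pandas as pd

    rows = []
    for a in agents:
        v = a.choice_probs
        rows.append(
            {
                "agent_id": a.agent_id,
                "condition": a.condition,
                "sex": a.sex,
                "block_introduced": a.block_introduced,
                "p_color": a.preference.p_color,
                "p_shape": a.preference.p_shape,
                **{f"p_vase{i}": v[i] for i in range(N_VASES)},
            }
        )
    return pd.DataFrame(rows)
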