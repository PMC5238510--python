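"""Task structure and behaviour simulation.

Sessions consist of blocks of 30-50 trials with a constant colour-reward
mapping that flips un-cued between blocks. A block advances early once the
running reward average over the last 12 trials reaches 0.90 (checked from
trial 30 onward) and always at trial 50. Two drifting stimuli appear left
and right of fixation carrying opposite motion directions and opposite
colours; only colour predicts reward. Reward delivery is deterministic:
choosing the stimulus with the rewarded colour always pays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models
from .models import ModelParams, ModelState

__all__ = [
    "StimulusConfig",
    "TrialRecord",
    "SessionPlan",
    "Agent",
    "ModelAgent",
    "RandomAgent",
    "PerfectAgent",
    "make_agent",
    "generate_session",
    "generate_sessions",
    "simulate_block_set",
    "block_end_reasons",
    "write_trials",
    "read_trials",
    "trials_to_frame",
    "TSV_COLUMNS",
]

DIMMING_CONDITIONS = ("simultaneous", "rewarded_first", "rewarded_second")
OUTCOME_CLASSES = ("rewarded_choice", "error_choice", "fixation_break", "premature")

# feature indices (see revlearn.models): 0=L 1=R 2=U 3=D 4=C1 5=C2
_MOTION_INDEX = {"up": 2, "down": 3}
_COLOR_INDEX = {1: 4, 2: 5}


@dataclass(frozen=True)
class StimulusConfig:
    """One trial's stimulus layout.

    The right stimulus always carries the complementary colour and motion
    direction of the left one, so only the left features are stored.
    """

    left_color: int  # 1 or 2
    left_motion: str  # "up" or "down"
    dimming_condition: str

    def __post_init__(self):
        if self.left_color not in (1, 2):
            raise ValueError("left_color must be 1 or 2")
        if self.left_motion not in ("up", "down"):
            raise ValueError("left_motion must be 'up' or 'down'")
        if self.dimming_condition not in DIMMING_CONDITIONS:
            raise ValueError(f"bad dimming_condition {self.dimming_condition!r}")

    @property
    def right_color(self) -> int:
        return 3 - self.left_color

    @property
    def right_motion(self) -> str:
        return "down" if self.left_motion == "up" else "up"

    def feature_indices(self):
        """(left, right) tuples of the three feature indices per stimulus."""
        left = (0, _MOTION_INDEX[self.left_motion], _COLOR_INDEX[self.left_color])
        right = (1, _MOTION_INDEX[self.right_motion], _COLOR_INDEX[self.right_color])
        return left, right


@dataclass(frozen=True)
class TrialRecord:
    session_id: str
    condition: str
    block_index: int
    trial_in_block: int
    stimulus: StimulusConfig
    rewarded_color: int
    choice: str  # "left", "right" or "none"
    reward: int
    outcome_class: str

    def __post_init__(self):
        if self.block_index < 1 or self.trial_in_block < 1:
            raise ValueError("block_index and trial_in_block are 1-based")
        if self.trial_in_block > 50:
            raise ValueError("trial_in_block exceeds the 50-trial block cap")
        if self.rewarded_color not in (1, 2):
            raise ValueError("rewarded_color must be 1 or 2")
        if self.choice not in ("left", "right", "none"):
            raise ValueError(f"bad choice {self.choice!r}")
        if self.outcome_class not in OUTCOME_CLASSES:
            raise ValueError(f"bad outcome_class {self.outcome_class!r}")
        if self.reward not in (0, 1):
            raise ValueError("reward must be 0 or 1")
        expected = 0
        if self.choice != "none":
            expected = int(self.chosen_color == self.rewarded_color)
        if self.reward != expected:
            raise ValueError(
                "reward must be 1 iff the chosen stimulus carries the rewarded colour"
            )

    @property
    def chosen_color(self):
        if self.choice == "none":
            return None
        return self.stimulus.left_color if self.choice == "left" else self.stimulus.right_color


@dataclass(frozen=True)
class SessionPlan:
    session_id: str = "s1"
    condition: str = "control"
    n_blocks: int = 8
    block_length_min: int = 30
    block_length_max: int = 50
    block_advance_window: int = 12
    block_advance_threshold: float = 0.90
    dimming_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    lapse_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")
        if not np.isclose(sum(self.dimming_proportions), 1.0):
            raise ValueError("dimming proportions must sum to 1")
        if not 0 <= self.lapse_rate < 1:
            raise ValueError("lapse_rate must be in [0, 1)")
        if not (1 <= self.block_length_min <= self.block_length_max):
            raise ValueError("bad block length range")


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

class Agent:
    """Chooses a side given the two stimuli and learns from the outcome."""

    def start_session(self, rng):
        pass

    def choose(self, left_features, right_features, rng) -> int:
        raise NotImplementedError

    def observe(self, left_features, right_features, choice: int, reward: int) -> None:
        pass


class ModelAgent(Agent):
    """Agent that samples choices from one of the eight learning models."""

    def __init__(self, model: str, params: ModelParams):
        params.validate(model)
        self.model = model
        self.params = params
        self.state = ModelState()

    def start_session(self, rng):
        self.state = ModelState()

    def choose(self, left_features, right_features, rng) -> int:
        p_left, _ = models.choice_probs(
            self.model, self.params, self.state, left_features, right_features
        )
        return 0 if rng.random() < p_left else 1

    def observe(self, left_features, right_features, choice, reward):
        models.step_trial(
            self.model, self.params, self.state, left_features, right_features, choice, reward
        )


class RandomAgent(Agent):
    """Uniform random chooser (chance baseline)."""

    def choose(self, left_features, right_features, rng) -> int:
        return int(rng.random() < 0.5)


class PerfectAgent(Agent):
    """Oracle that always picks the currently rewarded colour (for calibration)."""

    def __init__(self):
        self._rewarded_color_index = None

    def set_rewarded_color(self, color: int):
        self._rewarded_color_index = _COLOR_INDEX[color]

    def choose(self, left_features, right_features, rng) -> int:
        return 0 if left_features[2] == self._rewarded_color_index else 1


def make_agent(model: str, params: ModelParams | None = None) -> Agent:
    """Agent factory; ``model`` is a registry name, ``"random"`` or ``"perfect"``."""
    if model == "random":
        return RandomAgent()
    if model == "perfect":
        return PerfectAgent()
    if model not in models.MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    return ModelAgent(model, params if params is not None else ModelParams())


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def generate_session(plan: SessionPlan, agent: Agent, rng=None) -> list[TrialRecord]:
    """Simulate one session of ``plan.n_blocks`` reversal blocks.

    The first block's rewarded colour is drawn from the seeded generator and
    flips at every (un-cued) reversal. Motion direction and colour-to-side
    assignment are randomized independently each trial; the dimming condition
    is drawn from ``plan.dimming_proportions``.
    """
    if rng is None:
        rng = np.random.default_rng(plan.rng_seed)
    agent.start_session(rng)
    rewarded_color = int(rng.integers(1, 3))
    trials: list[TrialRecord] = []
    window = plan.block_advance_window

    for block in range(1, plan.n_blocks + 1):
        if isinstance(agent, PerfectAgent):
            agent.set_rewarded_color(rewarded_color)
        rewards: list[int] = []
        t = 0
        while True:
            t += 1
            stim = StimulusConfig(
                left_color=int(rng.integers(1, 3)),
                left_motion="up" if rng.random() < 0.5 else "down",
                dimming_condition=str(
                    rng.choice(DIMMING_CONDITIONS, p=plan.dimming_proportions)
                ),
            )
            left, right = stim.feature_indices()
            if plan.lapse_rate > 0 and rng.random() < plan.lapse_rate:
                choice, reward = "none", 0
                outcome = "premature" if rng.random() < 0.5 else "fixation_break"
            else:
                side = agent.choose(left, right, rng)
                chosen_color = stim.left_color if side == 0 else stim.right_color
                reward = int(chosen_color == rewarded_color)
                agent.observe(left, right, side, reward)
                choice = "left" if side == 0 else "right"
                outcome = "rewarded_choice" if reward else "error_choice"
                rewards.append(reward)
            trials.append(
                TrialRecord(
                    session_id=plan.session_id,
                    condition=plan.condition,
                    block_index=block,
                    trial_in_block=t,
                    stimulus=stim,
                    rewarded_color=rewarded_color,
                    choice=choice,
                    reward=reward,
                    outcome_class=outcome,
                )
            )
            learned = (
                t >= plan.block_length_min
                and len(rewards) >= window
                and float(np.mean(rewards[-window:])) >= plan.block_advance_threshold
            )
            if learned or t >= plan.block_length_max:
                break
        rewarded_color = 3 - rewarded_color  # un-cued reversal
    return trials


def generate_sessions(plans, agent_factory, seed: int) -> list[TrialRecord]:
    """Simulate several sessions with independent sub-seeded generators.

    ``agent_factory`` is called once per session (fresh learner state);
    per-session seeds are spawned from ``seed`` so sessions are independent
    but jointly reproducible.
    """
    root = np.random.SeedSequence(seed)
    trials: list[TrialRecord] = []
    for plan, child in zip(plans, root.spawn(len(plans))):
        rng = np.random.default_rng(child)
        trials.extend(generate_session(plan, agent_factory(), rng=rng))
    return trials


def simulate_block_set(
    model: str,
    params: ModelParams | None = None,
    n_blocks: int = 148,
    blocks_per_session: int = 8,
    seed: int = 0,
    condition: str = "control",
    lapse_rate: float = 0.0,
) -> list[TrialRecord]:
    """Simulate ``n_blocks`` reversal blocks split into sessions.

    Sessions hold ``blocks_per_session`` blocks (the last may be shorter);
    the learner state restarts at each session boundary.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be positive")
    plans = []
    remaining, i = n_blocks, 0
    while remaining > 0:
        nb = min(blocks_per_session, remaining)
        plans.append(
            SessionPlan(
                session_id=f"{condition}_{i + 1:02d}",
                condition=condition,
                n_blocks=nb,
                lapse_rate=lapse_rate,
                rng_seed=seed + i,
            )
        )
        remaining -= nb
        i += 1
    return generate_sessions(plans, lambda: make_agent(model, params), seed=seed)


def block_end_reasons(trials) -> pd.DataFrame:
    """Tag each block as ended by criterion ('learned') or the 50-trial cap."""
    df = trials_to_frame(trials)
    rows = []
    for (sid, block), g in df.groupby(["session_id", "block_index"], sort=True):
        n = len(g)
        rewards = g.loc[g["choice"] != "none", "reward"].to_numpy()
        met = (
            n >= 30
            and len(rewards) >= 12
            and float(np.mean(rewards[-12:])) >= 0.90
        )
        rows.append(
            {
                "session_id": sid,
                "block_index": block,
                "n_trials": n,
                "end_reason": "criterion" if met else "cap",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "session_id",
    "condition",
    "block_index",
    "trial_in_block",
    "left_color",
    "left_motion",
    "rewarded_color",
    "dimming_condition",
    "choice",
    "reward",
    "outcome_class",
]


def trials_to_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return pd.DataFrame(
        {
            "session_id": [t.session_id for t in trials],
            "condition": [t.condition for t in trials],
            "block_index": [t.block_index for t in trials],
            "trial_in_block": [t.trial_in_block for t in trials],
            "left_color": [t.stimulus.left_color for t in trials],
            "left_motion": [t.stimulus.left_motion for t in trials],
            "rewarded_color": [t.rewarded_color for t in trials],
            "dimming_condition": [t.stimulus.dimming_condition for t in trials],
            "choice": [t.choice for t in trials],
            "reward": [t.reward for t in trials],
            "outcome_class": [t.outcome_class for t in trials],
        }
    )


def write_trials(trials, path) -> None:
    """Write a trial table as UTF-8 TSV with the documented column schema."""
    trials_to_frame(trials).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_trials(path) -> list[TrialRecord]:
    """Read and validate a TSV trial table (inverse of :func:`write_trials`)."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"session_id": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        stim = StimulusConfig(
            left_color=int(row.left_color),
            left_motion=str(row.left_motion),
            dimming_condition=str(row.dimming_condition),
        )
        records.append(
            TrialRecord(
                session_id=str(row.session_id),
                condition=str(row.condition),
                block_index=int(row.block_index),
                trial_in_block=int(row.trial_in_block),
                stimulus=stim,
                rewarded_color=int(row.rewarded_color),
                choice=str(row.choice),
                reward=int(row.reward),
                outcome_class=str(row.outcome_class),
            )
        )
    return records
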