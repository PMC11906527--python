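"""Orthogonalized intertemporal go/no-go task: design, trial sequences, feedback.

The task crosses the required instrumental response (go / no-go) with the
reward available for a correct response (an immediate small reward vs a
larger reward delayed by 120 days), giving four conditions, each signalled
by a unique cue. Feedback is probabilistic: on a fixed fraction of trials
the displayed outcome does not correspond to the correctness of the
response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd


class Action(str, Enum):
    GO = "go"
    NOGO = "nogo"


class RewardType(str, Enum):
    IMMEDIATE = "immediate"
    DELAYED = "delayed"


@dataclass(frozen=True)
class Condition:
    """One task condition: a required action crossed with an available reward."""

    required_action: Action
    reward_type: RewardType

    @property
    def valence(self) -> int:
        """Fixed cue value V(s): +1 for immediate-reward cues, -1 for delayed."""
        return 1 if self.reward_type is RewardType.IMMEDIATE else -1

    @property
    def label(self) -> str:
        return f"{self.required_action.value}_{self.reward_type.value}"


#: The four conditions, in canonical order. Index into this tuple is the
#: integer condition code used throughout the package.
CONDITIONS: tuple[Condition, ...] = (
    Condition(Action.GO, RewardType.IMMEDIATE),
    Condition(Action.GO, RewardType.DELAYED),
    Condition(Action.NOGO, RewardType.IMMEDIATE),
    Condition(Action.NOGO, RewardType.DELAYED),
)

CONDITION_LABELS: tuple[str, ...] = tuple(c.label for c in CONDITIONS)

#: V(s) per condition code, matching CONDITIONS order.
CONDITION_VALENCE: np.ndarray = np.array([c.valence for c in CONDITIONS], dtype=np.int64)

#: 1 if the required action is go, else 0, per condition code.
CONDITION_REQUIRED_GO: np.ndarray = np.array(
    [1 if c.required_action is Action.GO else 0 for c in CONDITIONS], dtype=np.int64
)


@dataclass(frozen=True)
class TaskDesign:
    """Structural constants of the go/no-go task.

    Defaults reproduce the study design: 4 conditions x 50 presentations in
    pseudorandom order (no condition more than twice in a row), divided into
    4 blocks of 50 trials, with a 20% chance that displayed feedback is
    incongruent with response correctness. The response window is metadata
    only; no timing is simulated.
    """

    trials_per_condition: int = 50
    n_blocks: int = 4
    block_length: int = 50
    p_incongruent_feedback: float = 0.20
    max_condition_run: int = 2
    response_window_ms: int = 600

    def __post_init__(self) -> None:
        if self.trials_per_condition * len(CONDITIONS) != self.n_blocks * self.block_length:
            raise ValueError(
                "trials_per_condition x 4 must equal n_blocks x block_length "
                f"(got {self.trials_per_condition * 4} vs {self.n_blocks * self.block_length})"
            )
        if not 0.0 <= self.p_incongruent_feedback <= 1.0:
            raise ValueError("p_incongruent_feedback must lie in [0, 1]")
        if self.max_condition_run < 1:
            raise ValueError("max_condition_run must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(CONDITIONS)


#: Column order of the CSV trial-table dialect.
TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "block",
    "required_action",
    "reward_type",
    "response",
    "correct",
    "feedback_reward",
    "feedback_congruent",
    "excluded",
]


def generate_trial_sequence(
    design: TaskDesign, seed: int | np.random.Generator
) -> np.ndarray:
    """Generate a pseudorandom condition sequence honouring the run constraint.

    Returns an array of integer condition codes (indices into ``CONDITIONS``)
    of length ``design.n_trials`` containing exactly
    ``design.trials_per_condition`` of each code, with no run of more than
    ``design.max_condition_run`` identical codes. The constraint is enforced
    across block boundaries.

    Sampling is sequential: each position draws a condition with probability
    proportional to its remaining count, among conditions that would not
    violate the run constraint; dead ends trigger a restart. Deterministic
    for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cond = len(CONDITIONS)
    total = design.n_trials
    # A single condition cannot fill the sequence in runs of max_condition_run
    # if its count exceeds what interleaving allows; at the default design the
    # constraint is always satisfiable.
    if design.trials_per_condition > (total - design.trials_per_condition + 1) * design.max_condition_run:
        raise ValueError("run-length constraint unsatisfiable for this design")

    for _attempt in range(10_000):
        remaining = np.full(n_cond, design.trials_per_condition, dtype=np.int64)
        seq = np.empty(total, dtype=np.int64)
        run_cond, run_len = -1, 0
        ok = True
        for t in range(total):
            legal = remaining > 0
            if run_len >= design.max_condition_run:
                legal = legal.copy()
                legal[run_cond] = False
            if not legal.any():
                ok = False
                break
            w = np.where(legal, remaining, 0).astype(float)
            c = int(rng.choice(n_cond, p=w / w.sum()))
            seq[t] = c
            remaining[c] -= 1
            if c == run_cond:
                run_len += 1
            else:
                run_cond, run_len = c, 1
        if ok:
            return seq
    raise RuntimeError("failed to generate a constrained sequence")  # pragma: no cover


def assign_feedback(
    correct: bool,
    reward_type: RewardType | str,
    p_incongruent: float,
    rng: np.random.Generator,
) -> tuple[str, bool]:
    """Draw the displayed feedback for one trial.

    With probability ``1 - p_incongruent`` the display matches correctness
    (correct -> the cue's reward, incorrect -> no reward); otherwise it is
    flipped. Returns ``(feedback_reward, feedback_congruent)`` where
    ``feedback_reward`` is the cue's reward type label or ``"none"``.
    """
    if not 0.0 <= p_incongruent <= 1.0:
        raise ValueError("p_incongruent must lie in [0, 1]")
    reward_label = RewardType(reward_type).value
    congruent = rng.random() >= p_incongruent
    shown_reward = correct if congruent else not correct
    return (reward_label if shown_reward else "none", congruent)


def max_run_length(seq: Sequence[int]) -> int:
    """Length of the longest run of identical values (empty sequence -> 0)."""
    best = run = 0
    prev = object()
    for x in seq:
        run = run + 1 if x == prev else 1
        prev = x
        best = max(best, run)
    return best


def trials_to_frame(
    participant_id: str,
    cond_codes: np.ndarray,
    responses: np.ndarray,
    feedback_reward: np.ndarray,
    feedback_congruent: np.ndarray,
    design: TaskDesign,
    excluded: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble per-trial arrays into the canonical long-format trial table.

    ``responses`` is 1 for go and 0 for no-go; ``feedback_reward`` is 1 when a
    reward was displayed. The displayed reward label is the cue's reward type.
    """
    n = len(cond_codes)
    required_go = CONDITION_REQUIRED_GO[cond_codes]
    correct = responses == required_go
    reward_type = np.array([CONDITIONS[c].reward_type.value for c in cond_codes])
    fb_label = np.where(feedback_reward == 1, reward_type, "none")
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": np.arange(n, dtype=np.int64),
            "block": np.arange(n) // design.block_length + 1,
            "required_action": np.where(required_go == 1, "go", "nogo"),
            "reward_type": reward_type,
            "response": np.where(responses == 1, "go", "nogo"),
            "correct": correct,
            "feedback_reward": fb_label,
            "feedback_congruent": feedback_congruent.astype(bool),
            "excluded": excluded.astype(bool),
        },
        columns=TRIAL_COLUMNS,
    )


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV, validating the dialect."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df[TRIAL_COLUMNS]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical CSV dialect."""
    df[TRIAL_COLUMNS].to_csv(path, index=False)
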