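"""Choice titration: MCQ discount-rate estimation and the adaptive staircase.

The preference-matching procedure has two parts. First, the 27-item
monetary choice questionnaire (MCQ) yields an individual hyperbolic
discount rate k under Mazur's model V = A / (1 + kD). Second, an adaptive
staircase titrates the immediate amount of the pair (€X today vs €28 in
120 days): the amount starts at the MCQ-implied present value of €28,
moves in €2 steps opposite to each choice, and stops once the last six
amounts span at most one step (€2). The indifference value is the mean of
those six amounts, rounded to the nearest integer. Choosing €0 today over
the delayed €28 (confirmed) excludes the participant; preferring the
delayed €28 over €28 today (confirmed) fixes the indifference value at 28.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

DELAYED_AMOUNT = 28.0
DELAY_DAYS = 120
STEP = 2
MAX_AMOUNT = 28
MAX_TRIALS = 50
STABILITY_WINDOW = 6

#: The 27-item monetary choice questionnaire in its fixed published order:
#: (immediate amount, delayed amount, delay in days), read in euros.
MCQ_ITEMS: tuple[tuple[int, int, int], ...] = (
    (54, 55, 117), (55, 75, 61), (19, 25, 53), (31, 85, 7), (14, 25, 19),
    (47, 50, 160), (15, 35, 13), (25, 60, 14), (78, 80, 162), (40, 55, 62),
    (11, 30, 7), (67, 75, 119), (34, 35, 186), (27, 50, 21), (69, 85, 91),
    (49, 60, 89), (80, 85, 157), (24, 35, 29), (33, 80, 14), (28, 30, 179),
    (34, 50, 30), (25, 30, 80), (41, 75, 20), (54, 60, 111), (54, 80, 30),
    (22, 25, 136), (20, 55, 7),
)


def hyperbolic_value(amount: float, delay_days: float, k: float) -> float:
    """Mazur's hyperbolic subjective value V = A / (1 + kD)."""
    return amount / (1.0 + k * delay_days)


def item_boundary_k(immediate: float, delayed: float, delay_days: float) -> float:
    """The k at which an item's two options have equal subjective value."""
    return (delayed - immediate) / (immediate * delay_days)


def estimate_k_mcq(choices: Sequence[str], items=MCQ_ITEMS) -> float:
    """Consistency-maximizing hyperbolic discount rate from MCQ choices.

    ``choices`` holds one of {"immediate", "delayed"} per item, in item
    order. Candidate rates are the geometric midpoints between consecutive
    item-boundary ks, plus points just beyond the ladder's ends; the k (or
    geometric mean of tied ks) whose implied deterministic chooser agrees
    with the most observed choices is returned. All-delayed responders land
    at the ladder's lower boundary, all-immediate at the upper.
    """
    if len(choices) != len(items):
        raise ValueError(f"expected {len(items)} answered items, got {len(choices)}")
    for c in choices:
        if c not in ("immediate", "delayed"):
            raise ValueError(f"invalid choice {c!r}")
    bounds = np.array(sorted(item_boundary_k(a, d, t) for a, d, t in items))
    # Candidate ladder: below the smallest boundary, geometric midpoints,
    # above the largest boundary.
    candidates = [bounds[0] / 2.0]
    candidates += list(np.sqrt(bounds[:-1] * bounds[1:]))
    candidates.append(bounds[-1] * 2.0)
    best_score, best_ks = -1, []
    for k in candidates:
        score = 0
        for (a, d, t), c in zip(items, choices):
            predicted = "delayed" if hyperbolic_value(d, t, k) > a else "immediate"
            score += predicted == c
        if score > best_score:
            best_score, best_ks = score, [k]
        elif score == best_score:
            best_ks.append(k)
    return float(np.exp(np.mean(np.log(best_ks))))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def staircase_start(k: float) -> int:
    """Starting immediate amount: present value of €28 at 120 days.

    28 / (1 + 120k), rounded to the nearest even integer (ties upward),
    clipped to [0, 28].
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    pv = hyperbolic_value(DELAYED_AMOUNT, DELAY_DAYS, k)
    even = 2 * int(math.floor(pv / 2.0 + 0.5))
    return int(min(max(even, 0), MAX_AMOUNT))


@dataclass
class TitrationTrace:
    """Full staircase history for one participant."""

    trial_amounts: list[int] = field(default_factory=list)
    choices: list[str] = field(default_factory=list)
    confirmation_events: list[dict] = field(default_factory=list)
    stability_reached: bool = False
    indifference_value: int | None = None
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trial_amounts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "immediate_amount": self.trial_amounts,
                "choice": self.choices,
            }
        )


@dataclass(frozen=True)
class IndifferencePair:
    """A preference-matched immediate/delayed reward pair."""

    immediate_amount: int
    delayed_amount: int = int(DELAYED_AMOUNT)
    delay_days: int = DELAY_DAYS


def _window_stable(amounts: Sequence[int]) -> bool:
    w = amounts[-STABILITY_WINDOW:]
    return len(w) == STABILITY_WINDOW and max(w) - min(w) <= STEP


def indifference_value(trace: TitrationTrace) -> int:
    """Mean of the last six immediate amounts, rounded half away from zero."""
    if not trace.stability_reached:
        raise ValueError("indifference undefined: staircase did not stabilize")
    mean = float(np.mean(trace.trial_amounts[-STABILITY_WINDOW:]))
    return _round_half_away(mean)


def run_staircase(
    chooser: Callable[[float, float, int], str],
    start: int,
    max_trials: int = MAX_TRIALS,
) -> TitrationTrace:
    """Run the adaptive titrator against a chooser function.

    ``chooser(immediate_amount, delayed_amount, delay_days)`` returns
    "immediate" or "delayed". The immediate amount moves down €2 after an
    immediate choice and up €2 after a delayed choice. Termination:

    * the six most recent amounts span at most €2 -> stable, indifference
      value computed from their mean;
    * a confirmed preference for €0 today over the delayed reward ->
      excluded;
    * a confirmed preference for the delayed €28 over €28 today ->
      indifference value set at 28;
    * ``max_trials`` trials without stability -> excluded.
    """
    if start % 2 != 0 or not 0 <= start <= MAX_AMOUNT:
        raise ValueError("start must be an even integer in [0, 28]")
    trace = TitrationTrace()
    amount = int(start)

    def ask(amt: int) -> str:
        c = chooser(float(amt), DELAYED_AMOUNT, DELAY_DAYS)
        if c not in ("immediate", "delayed"):
            raise ValueError(f"chooser returned invalid choice {c!r}")
        trace.trial_amounts.append(amt)
        trace.choices.append(c)
        return c

    while trace.n_trials < max_trials:
        choice = ask(amount)
        if _window_stable(trace.trial_amounts):
            trace.stability_reached = True
            trace.indifference_value = indifference_value(trace)
            return trace
        boundary = (amount == 0 and choice == "immediate") or (
            amount == MAX_AMOUNT and choice == "delayed"
        )
        if boundary:
            if trace.n_trials >= max_trials:
                break
            confirm = ask(amount)  # confirmation trial at the same amount
            confirmed = confirm == choice
            trace.confirmation_events.append(
                {"amount": amount, "choice": choice, "confirmed": confirmed}
            )
            if confirmed:
                if amount == 0:
                    trace.excluded = True
                    trace.exclusion_reason = "preferred €0 today over the delayed reward"
                else:
                    trace.stability_reached = True
                    trace.indifference_value = MAX_AMOUNT
                return trace
            choice = confirm  # not confirmed: continue from the repeated choice
            if _window_stable(trace.trial_amounts):
                trace.stability_reached = True
                trace.indifference_value = indifference_value(trace)
                return trace
        amount += -STEP if choice == "immediate" else STEP
        amount = int(min(max(amount, 0), MAX_AMOUNT))

    trace.excluded = True
    trace.exclusion_reason = f"no stability within {max_trials} trials"
    return trace
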