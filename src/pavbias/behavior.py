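"""Descriptive behavioural summaries and group tests on the Pavlovian bias.

Raw go-response proportions per participant and condition (or collapsed
over reward / required action / block), cohort aggregates with
normal-approximation 95% confidence intervals, a per-participant raw bias
index p(go | immediate) - p(go | delayed), and the one-sample t and
Wilcoxon signed-rank tests on the fitted cue-response bias parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_GROUPINGS = {
    "condition": ["required_action", "reward_type"],
    "reward": ["reward_type"],
    "action": ["required_action"],
    "block": ["block"],
    "condition_block": ["required_action", "reward_type", "block"],
}


@dataclass(frozen=True)
class GoSummary:
    """Go-response proportions at a chosen grouping."""

    grouping: str
    per_participant: pd.DataFrame   # participant_id, group cols, prop_go, n_trials
    cohort: pd.DataFrame            # group cols, mean, ci_low, ci_high, n_participants

    def summary(self) -> str:
        return self.cohort.to_string(index=False)


def go_proportions(trials: pd.DataFrame, grouping: str = "condition") -> GoSummary:
    """Raw go proportions among included trials, per participant and cohort.

    Cohort means aggregate over participant means (each participant weighted
    equally); 95% CIs use the normal approximation over participant means.
    Groups with no included trials for a participant are absent (undefined),
    never reported as 0.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPINGS)}")
    if len(trials) == 0:
        raise ValueError("empty cohort")
    keys = _GROUPINGS[grouping]
    inc = trials[~trials["excluded"].astype(bool)].copy()
    inc["is_go"] = (inc["response"].astype(str) == "go").astype(float)
    per = (
        inc.groupby(["participant_id", *keys], observed=True)["is_go"]
        .agg(prop_go="mean", n_trials="size")
        .reset_index()
    )
    g = per.groupby(keys, observed=True)["prop_go"]
    cohort = g.agg(mean="mean", sd="std", n_participants="size").reset_index()
    se = cohort["sd"] / np.sqrt(cohort["n_participants"])
    cohort["ci_low"] = cohort["mean"] - 1.96 * se
    cohort["ci_high"] = cohort["mean"] + 1.96 * se
    return GoSummary(grouping=grouping, per_participant=per, cohort=cohort)


def bias_index(trials: pd.DataFrame) -> float:
    """Raw per-participant Pavlovian bias: p(go|immediate) - p(go|delayed).

    Positive values are the hypothesized direction (immediacy invigorates
    responding). Raises if either reward type has no included trials.
    """
    inc = trials[~trials["excluded"].astype(bool)]
    out = {}
    for rt in ("immediate", "delayed"):
        sub = inc[inc["reward_type"] == rt]
        if len(sub) == 0:
            raise ValueError(f"no included {rt}-reward trials: bias undefined")
        out[rt] = (sub["response"].astype(str) == "go").mean()
    return float(out["immediate"] - out["delayed"])


@dataclass(frozen=True)
class PiTestResult:
    """One-sample tests of the cue-response bias against zero."""

    n: int
    mean: float
    t_stat: float
    df: int
    t_pvalue: float
    wilcoxon_stat: float
    wilcoxon_pvalue: float
    degenerate: bool = False

    def summary(self) -> str:
        if self.degenerate:
            return f"pi test (n={self.n}): degenerate input (zero variance)"
        return (
            f"pi test (n={self.n}, mean={self.mean:.4f}): "
            f"t({self.df}) = {self.t_stat:.3f}, p = {self.t_pvalue:.4f}; "
            f"Wilcoxon V = {self.wilcoxon_stat:.1f}, p = {self.wilcoxon_pvalue:.4f}"
        )


def test_pi(pi_values) -> PiTestResult:
    """Two-sided one-sample t and Wilcoxon signed-rank tests against zero.

    Zero-variance input (including all-zero values, which leave the Wilcoxon
    with no nonzero ranks) is reported as degenerate, with NaN statistics.
    Wilcoxon uses the Pratt treatment of zeros.
    """
    x = np.asarray(list(pi_values), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two values")
    if np.allclose(x.std(ddof=1), 0.0):
        return PiTestResult(
            n=len(x), mean=float(x.mean()), t_stat=float("nan"), df=len(x) - 1,
            t_pvalue=float("nan"), wilcoxon_stat=float("nan"),
            wilcoxon_pvalue=float("nan"), degenerate=True,
        )
    t = stats.ttest_1samp(x, 0.0)
    w = stats.wilcoxon(x, zero_method="pratt", alternative="two-sided")
    return PiTestResult(
        n=len(x), mean=float(x.mean()), t_stat=float(t.statistic), df=len(x) - 1,
        t_pvalue=float(t.pvalue), wilcoxon_stat=float(w.statistic),
        wilcoxon_pvalue=float(w.pvalue),
    )
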