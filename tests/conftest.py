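"""Shared fixtures and the independent brute-force likelihood oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pavbias import OptimizerConfig, TaskDesign
from pavbias.task import CONDITIONS, trials_to_frame

#: Cohort-mean parameters of the winning cue-response-bias model.
M3_MEANS = {"alpha": 0.19, "tau": 7.33, "xi": 0.17, "b": 0.06, "pi": 0.03}

#: Cheaper optimizer settings for unit tests that only need a decent mode,
#: not the full search (acceptance checks use the defaults).
FAST_OPT = OptimizerConfig(popsize=8, maxiter=80, tol=1e-6)


def brute_force_log_likelihood(params_full, trials: pd.DataFrame) -> float:
    """Per-trial product oracle, written independently of the kernels.

    ``params_full`` is the expanded (a0, a1, tau, xi, b, pi) tuple. Walks the
    table row by row with a dict-keyed Q table, computes each trial's go
    probability with an explicit two-term softmax, multiplies the per-trial
    probabilities of the observed responses (included trials only), and
    returns the log of the product. Q updates happen on every trial.
    """
    a0, a1, tau, xi, b, pi = params_full
    q = {(c, a): 0.0 for c in range(4) for a in ("go", "nogo")}
    prob = 1.0
    for _, row in trials.iterrows():
        cond = next(
            i for i, c in enumerate(CONDITIONS)
            if c.required_action.value == row["required_action"]
            and c.reward_type.value == row["reward_type"]
        )
        v = 1 if row["reward_type"] == "immediate" else -1
        w_go = q[(cond, "go")] + b + pi * v
        w_nogo = q[(cond, "nogo")]
        ex = np.exp(np.array([tau * w_go, tau * w_nogo]))
        p_go = ex[0] / ex.sum() * (1 - xi) + xi / 2
        p_trial = p_go if row["response"] == "go" else 1 - p_go
        if not row["excluded"]:
            prob *= p_trial
        r = 0.0 if row["feedback_reward"] == "none" else 1.0
        shown_go = row["response"] == "go"
        congruent_pair = (shown_go and v == 1) or (not shown_go and v == -1)
        alpha = a0 if (r == 1.0 and congruent_pair) else a1
        key = (cond, "go" if shown_go else "nogo")
        q[key] = q[key] + alpha * (r - q[key])
    return float(np.log(prob))


def random_trial_table(rng: np.random.Generator, n_trials: int, participant="p0",
                       p_excluded: float = 0.0) -> pd.DataFrame:
    """A random (not necessarily design-conforming) trial table."""
    design = TaskDesign()
    cond = rng.integers(0, 4, size=n_trials)
    resp = rng.integers(0, 2, size=n_trials)
    reward = rng.integers(0, 2, size=n_trials)
    congruent = rng.integers(0, 2, size=n_trials).astype(bool)
    excluded = rng.random(n_trials) < p_excluded
    return trials_to_frame(participant, cond, resp, reward, congruent, design,
                           excluded=excluded)


def random_inbox_params(rng: np.random.Generator, model_id: str) -> dict[str, float]:
    from pavbias import MODELS, PARAM_BOUNDS

    out = {}
    for name in MODELS[model_id].free_parameters:
        lo, hi = PARAM_BOUNDS[name]
        if name == "tau":
            hi = 10.0  # keep softmax off the hard-saturation regime
        out[name] = float(rng.uniform(lo, hi))
    return out


@pytest.fixture(scope="session")
def design() -> TaskDesign:
    return TaskDesign()


@pytest.fixture(scope="session")
def m3_agent_table():
    """One simulated participant at the cohort-mean parameters."""
    from pavbias import simulate_agent

    return simulate_agent(M3_MEANS, "M3", seed=20260920)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant synthetic cohort at the default study conditions."""
    from pavbias import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_participants=12, master_seed=7))
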