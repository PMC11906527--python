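"""The reinforcement-learning model family M0-M5.

All six models are Rescorla-Wagner Q-learners over the four task cues with a
softmax policy on two actions (go / no-go). The family is nested:

* **M0** — learning rate alpha, inverse temperature tau.
* **M1** — adds irreducible noise xi: the softmax policy is mixed with a
  uniform lapse, p = softmax * (1 - xi) + xi / 2.
* **M2** — adds a go bias b to the go action weight.
* **M3** — adds the Pavlovian cue-response bias pi, which shifts the go
  weight by +pi for immediate-reward cues and -pi for delayed-reward cues
  (cue values V(s) fixed at +1 / -1).
* **M4** — replaces pi by a learning bias: a separate learning rate alpha0
  for bias-congruent pairings (go followed by a displayed immediate reward;
  no-go followed by a displayed delayed reward) and alpha1 otherwise.
* **M5** — both biases (M3 + M4).

Value updating uses the *displayed* (possibly incongruent) feedback, coded
r = 1 when a reward is shown and 0 otherwise; Q starts at zero for every
(cue, action) cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .task import (
    CONDITION_LABELS,
    CONDITION_REQUIRED_GO,
    CONDITION_VALENCE,
    TaskDesign,
    generate_trial_sequence,
    trials_to_frame,
)

#: Box constraints per parameter name.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "alpha0": (0.0, 1.0),
    "alpha1": (0.0, 1.0),
    "tau": (0.0, 50.0),
    "xi": (0.0, 1.0),
    "b": (-3.0, 3.0),
    "pi": (-3.0, 3.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Identity and free parameters of one model in the family."""

    model_id: str
    free_parameters: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.free_parameters)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [PARAM_BOUNDS[p] for p in self.free_parameters]

    def expand(self, params: Mapping[str, float] | Sequence[float]) -> tuple[float, ...]:
        """Expand free parameters to the full (a0, a1, tau, xi, b, pi) vector.

        Absent parameters take their neutral values (xi = b = pi = 0,
        alpha0 = alpha1 = alpha). Accepts a mapping or a sequence ordered as
        ``free_parameters``.
        """
        p = self._as_dict(params)
        if "alpha" in p:
            a0 = a1 = p["alpha"]
        else:
            a0, a1 = p["alpha0"], p["alpha1"]
        return (a0, a1, p["tau"], p.get("xi", 0.0), p.get("b", 0.0), p.get("pi", 0.0))

    def _as_dict(self, params: Mapping[str, float] | Sequence[float]) -> dict[str, float]:
        if isinstance(params, Mapping):
            missing = set(self.free_parameters) - set(params)
            if missing:
                raise ValueError(f"{self.model_id}: missing parameters {sorted(missing)}")
            return {k: float(params[k]) for k in self.free_parameters}
        vals = list(params)
        if len(vals) != self.k:
            raise ValueError(f"{self.model_id}: expected {self.k} parameters, got {len(vals)}")
        return dict(zip(self.free_parameters, map(float, vals)))

    def validate(self, params: Mapping[str, float] | Sequence[float]) -> dict[str, float]:
        """Return the parameter dict, checking box constraints."""
        p = self._as_dict(params)
        for name, v in p.items():
            lo, hi = PARAM_BOUNDS[name]
            if not (lo <= v <= hi) or not np.isfinite(v):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        return p


MODELS: dict[str, ModelSpec] = {
    "M0": ModelSpec("M0", ("alpha", "tau")),
    "M1": ModelSpec("M1", ("alpha", "tau", "xi")),
    "M2": ModelSpec("M2", ("alpha", "tau", "xi", "b")),
    "M3": ModelSpec("M3", ("alpha", "tau", "xi", "b", "pi")),
    "M4": ModelSpec("M4", ("alpha0", "alpha1", "tau", "xi", "b")),
    "M5": ModelSpec("M5", ("alpha0", "alpha1", "tau", "xi", "b", "pi")),
}


def get_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from {list(MODELS)}") from None


# ---------------------------------------------------------------------------
# Elementary model operations (scalar forms, used directly in tests and docs;
# the sequence likelihood and simulator run the compiled kernels)
# ---------------------------------------------------------------------------

def update_q(q_prev: float, r: float, alpha: float) -> float:
    """One Rescorla-Wagner update: q + alpha * (r - q)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return q_prev + alpha * (r - q_prev)


def select_learning_rate(
    action: str, feedback_reward_type: str, params, model: str | ModelSpec
) -> float:
    """Learning rate applied to one (action, displayed feedback) pairing.

    For M4/M5, bias-congruent pairings (go & immediate reward, no-go &
    delayed reward) use alpha0; all others, including no-reward feedback,
    use alpha1. Models without a learning bias return alpha.
    """
    spec = get_model(model)
    a0, a1, *_ = spec.expand(params)
    go = action == "go"
    if feedback_reward_type == "immediate" and go:
        return a0
    if feedback_reward_type == "delayed" and not go:
        return a0
    return a1


def action_weight(
    q: float, action: str, v_cue: int, params, model: str | ModelSpec
) -> float:
    """Action weight w: go gets q + b + pi * V(s); no-go is q unchanged."""
    spec = get_model(model)
    _, _, _, _, b, pi = spec.expand(params)
    if action == "go":
        return q + b + pi * v_cue
    return q


def go_probability(w_go: float, w_nogo: float, tau: float, xi: float) -> float:
    """Softmax go probability with irreducible noise.

    p = softmax(tau * w)_go * (1 - xi) + xi / 2, hence bounded in
    [xi/2, 1 - xi/2].
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    d = tau * (w_go - w_nogo)
    if d >= 0:
        p = 1.0 / (1.0 + np.exp(-d))
    else:
        e = np.exp(d)
        p = e / (1.0 + e)
    return float(p * (1.0 - xi) + 0.5 * xi)


# ---------------------------------------------------------------------------
# Trial-table <-> array packing
# ---------------------------------------------------------------------------

_COND_CODE = {lab: i for i, lab in enumerate(CONDITION_LABELS)}


def pack_trials(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Convert a long-format trial table into the kernel's integer arrays.

    Validates trial ordering: trial_index must be strictly increasing with no
    duplicates.
    """
    idx = trials["trial_index"].to_numpy()
    if len(idx) and not (np.diff(idx) > 0).all():
        raise ValueError("trials must be ordered by trial_index without duplicates")
    labels = trials["required_action"].astype(str) + "_" + trials["reward_type"].astype(str)
    try:
        cond = labels.map(_COND_CODE).to_numpy(dtype=np.int64)
    except (TypeError, ValueError):
        raise ValueError("unrecognised condition labels in trial table") from None
    if np.isnan(cond.astype(float)).any():  # pragma: no cover - map gives NaN on miss
        raise ValueError("unrecognised condition labels in trial table")
    resp = (trials["response"].astype(str) == "go").to_numpy(dtype=np.int64)
    reward = (trials["feedback_reward"].astype(str) != "none").to_numpy(dtype=np.int64)
    included = (~trials["excluded"].astype(bool)).to_numpy()
    return {
        "cond": cond,
        "resp": resp,
        "reward": reward,
        "included": included,
        "valence": CONDITION_VALENCE,
    }


def sequence_log_likelihood(
    params, model: str | ModelSpec, trials: pd.DataFrame
) -> float:
    """Log-likelihood of the observed responses under one model.

    Sums log p(response_t) over included trials; Q is updated after every
    trial (excluded ones too) from the displayed feedback.
    """
    spec = get_model(model)
    spec.validate(params)
    a0, a1, tau, xi, b, pi = spec.expand(params)
    arrs = pack_trials(trials)
    return float(
        _kernels.loglik_kernel(
            arrs["cond"], arrs["resp"], arrs["reward"], arrs["included"],
            arrs["valence"], a0, a1, tau, xi, b, pi,
        )
    )


def simulate_agent(
    params,
    model: str | ModelSpec,
    design: TaskDesign | None = None,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
) -> pd.DataFrame:
    """Full generative run of one agent through the task.

    Draws a constrained condition sequence, samples responses from the
    model's policy, assigns probabilistic feedback, and updates Q online.
    Returns a canonical trial table. Reproducible for a given seed.
    """
    spec = get_model(model)
    spec.validate(params)
    design = design or TaskDesign()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cond = generate_trial_sequence(design, rng)
    n = len(cond)
    a0, a1, tau, xi, b, pi = spec.expand(params)
    resp, fb_reward, fb_congruent = _kernels.simulate_kernel(
        cond,
        CONDITION_VALENCE,
        CONDITION_REQUIRED_GO,
        rng.random(n),
        rng.random(n),
        design.p_incongruent_feedback,
        a0, a1, tau, xi, b, pi,
    )
    return trials_to_frame(
        participant_id, cond, np.asarray(resp), np.asarray(fb_reward),
        np.asarray(fb_congruent), design,
    )
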