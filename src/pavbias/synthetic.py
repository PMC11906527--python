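"""Synthetic study generation: go/no-go cohorts and titration choosers.

Emulates the structure of the study's dataset so the whole pipeline runs
without any download: a cohort of 184 simulated participants, each playing
200 trials (4 conditions x 50, 80/20 probabilistic feedback), with
generating parameters drawn from truncated Gaussians anchored at the fitted
cohort's summary statistics (means from the winning model's estimates;
scales implied by the printed 95% confidence intervals at n = 184), plus
hyperbolic-discounter choosers for the titration staircase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import MODELS, PARAM_BOUNDS, get_model, simulate_agent
from .task import TaskDesign
from .titration import DELAY_DAYS, hyperbolic_value

#: Default generating distributions per parameter: (location, scale).
#: Locations are the fitted-cohort means of the winning cue-response-bias
#: model (alpha 0.19, tau 7.33, xi 0.17, b 0.06, pi 0.03); scales are the
#: cohort SDs implied by the printed 95% CIs at n = 184. The two learning
#: rates of the learning-bias models share the alpha anchor. Samples are
#: truncated to the fitting boxes.
DEFAULT_PARAM_DISTS: dict[str, tuple[float, float]] = {
    "alpha": (0.19, 0.21),
    "alpha0": (0.19, 0.21),
    "alpha1": (0.19, 0.21),
    "tau": (7.33, 2.77),
    "xi": (0.17, 0.21),
    "b": (0.06, 0.31),
    "pi": (0.03, 0.24),
}


def _sample_truncated(
    loc: float, scale: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if scale == 0:
        if not lo <= loc <= hi:
            raise ValueError(f"degenerate location {loc} outside [{lo}, {hi}]")
        return float(loc)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng))


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for one synthetic go/no-go cohort."""

    n_participants: int = 184
    model_id: str = "M3"
    parameter_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_DISTS)
    )
    design: TaskDesign = field(default_factory=TaskDesign)
    master_seed: int = 0

    def to_manifest(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "model_id": self.model_id,
            "parameter_distributions": {
                k: list(v) for k, v in self.parameter_distributions.items()
            },
            "design": asdict(self.design),
            "master_seed": self.master_seed,
        }


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated cohort: per-participant parameters and trial tables."""

    config: CohortConfig
    parameters: pd.DataFrame   # participant_id + one column per free parameter
    trials: pd.DataFrame       # long-format cohort trial table

    def write(self, trials_path, params_path=None, manifest_path=None) -> None:
        from .task import write_trials

        write_trials(self.trials, trials_path)
        if params_path is not None:
            self.parameters.to_csv(params_path, index=False)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.config.to_manifest(), fh, indent=2)


def sample_parameters(
    model_id: str,
    rng: np.random.Generator,
    dists: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Draw one in-box parameter vector for a model from truncated Gaussians."""
    spec = get_model(model_id)
    dists = dists or DEFAULT_PARAM_DISTS
    out = {}
    for name in spec.free_parameters:
        if name not in dists:
            raise ValueError(f"no distribution configured for parameter {name!r}")
        loc, scale = dists[name]
        lo, hi = PARAM_BOUNDS[name]
        out[name] = _sample_truncated(loc, scale, lo, hi, rng)
    return out


def generate_cohort(config: CohortConfig | None = None) -> SyntheticStudy:
    """Simulate a full cohort from one generating model.

    Each participant gets an independent parameter draw and a fresh
    constrained trial sequence; per-participant randomness is derived from
    the master seed via spawned seed sequences, so the same config always
    reproduces the same study byte for byte.
    """
    config = config or CohortConfig()
    spec = get_model(config.model_id)
    children = np.random.SeedSequence(config.master_seed).spawn(config.n_participants)
    param_rows, tables = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"sim{i:04d}"
        params = sample_parameters(spec.model_id, rng, config.parameter_distributions)
        table = simulate_agent(params, spec, config.design, seed=rng, participant_id=pid)
        param_rows.append({"participant_id": pid, "model_id": spec.model_id, **params})
        tables.append(table)
    return SyntheticStudy(
        config=config,
        parameters=pd.DataFrame(param_rows),
        trials=pd.concat(tables, ignore_index=True),
    )


def generate_titration_chooser(
    k: float,
    choice_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Callable[[float, float, int], str]:
    """A simulated intertemporal chooser with hyperbolic preferences.

    The chooser picks the immediate option with probability
    logistic((A_immediate - PV) / choice_noise) where PV is the hyperbolic
    present value of the delayed option; zero noise gives the deterministic
    Mazur chooser (immediate iff A_immediate > PV).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if choice_noise < 0:
        raise ValueError("choice_noise must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def chooser(immediate_amount: float, delayed_amount: float, delay_days: int) -> str:
        pv = hyperbolic_value(delayed_amount, delay_days, k)
        if choice_noise == 0.0:
            return "immediate" if immediate_amount > pv else "delayed"
        if np.isinf(choice_noise):
            p_imm = 0.5
        else:
            z = (immediate_amount - pv) / choice_noise
            p_imm = 1.0 / (1.0 + np.exp(-z))
        return "immediate" if rng.random() < p_imm else "delayed"

    return chooser
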