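"""Model validation: parameter recovery, model recovery, posterior predictives.

Three complementary checks of the fitted model family:

* **Parameter recovery** — simulate agents at known parameters, refit the
  same model, and report the association (Pearson, with Spearman alongside)
  between generating and recovered values per parameter.
* **Model recovery** — simulate agents from each model, fit all candidate
  models to each dataset, and tabulate how often each model wins by AIC
  (a confusion matrix of generating vs best-fitting model).
* **Posterior predictive checks** — simulate many datasets at the fitted
  per-participant parameters and compare the mean trial-by-trial go
  probability per condition against the observed curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import compare_models
from .fitting import OptimizerConfig, PriorSpec, fit_map
from .models import get_model, simulate_agent
from .synthetic import DEFAULT_PARAM_DISTS, sample_parameters
from .task import CONDITION_LABELS, TaskDesign


def _derived_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class RecoveryReport:
    """Generating-vs-recovered parameter associations for one model."""

    model_id: str
    associations: pd.DataFrame   # parameter, pearson_r, spearman_rho
    generating: pd.DataFrame
    recovered: pd.DataFrame
    n_simulated_agents: int
    seed: int

    def pearson(self, parameter: str) -> float:
        row = self.associations.set_index("parameter")
        return float(row.loc[parameter, "pearson_r"])

    def summary(self) -> str:
        head = f"Parameter recovery, {self.model_id} (n={self.n_simulated_agents})"
        return head + "\n" + self.associations.to_string(index=False)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Model-recovery confusion matrix (rows: generating, cols: best by AIC)."""

    proportions: pd.DataFrame
    n_per_row: int
    seed: int

    def modal_winner(self, generating: str) -> str:
        return str(self.proportions.loc[generating].idxmax())

    def summary(self) -> str:
        return (
            f"Model recovery ({self.n_per_row} agents per generating model)\n"
            + self.proportions.round(3).to_string()
        )


@dataclass(frozen=True)
class PpcSummary:
    """Posterior predictive trial-by-trial go curves per condition."""

    model_id: str
    n_datasets: int
    curves: pd.DataFrame        # condition, occurrence, mean, ci_low, ci_high
    condition_means: pd.Series  # mean p(go) per condition, pooled over trials
    observed: pd.DataFrame | None = None

    def condition_curve(self, condition: str) -> pd.DataFrame:
        return self.curves[self.curves["condition"] == condition]


def _association(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Pearson r, Spearman rho); NaN when either side has zero variance."""
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    return (
        float(stats.pearsonr(x, y).statistic),
        float(stats.spearmanr(x, y).statistic),
    )


def parameter_recovery(
    model,
    generating_params,
    design: TaskDesign | None = None,
    seed: int = 0,
    priors: PriorSpec | None = None,
    optimizer_config: OptimizerConfig | None = None,
) -> RecoveryReport:
    """Simulate one dataset per parameter vector, refit, report associations.

    ``generating_params`` is a list of parameter mappings (or a DataFrame
    with one column per free parameter). Associations for a parameter with
    zero generating variance are reported as NaN (undefined), never as 0.
    """
    spec = get_model(model)
    design = design or TaskDesign()
    if isinstance(generating_params, pd.DataFrame):
        generating_params = generating_params[list(spec.free_parameters)].to_dict("records")
    gen = pd.DataFrame(generating_params)[list(spec.free_parameters)]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(gen))
    rec_rows = []
    for i, (child, params) in enumerate(zip(children, gen.to_dict("records"))):
        sim_seed, fit_seed = (_derived_seed(c) for c in child.spawn(2))
        table = simulate_agent(params, spec, design, seed=sim_seed, participant_id=f"rec{i:04d}")
        res = fit_map(table, spec, priors, optimizer_config, seed=fit_seed)
        rec_rows.append(dict(res.params))
    rec = pd.DataFrame(rec_rows)[list(spec.free_parameters)]
    assoc = []
    for p in spec.free_parameters:
        r, rho = _association(gen[p].to_numpy(), rec[p].to_numpy())
        assoc.append({"parameter": p, "pearson_r": r, "spearman_rho": rho})
    return RecoveryReport(
        model_id=spec.model_id,
        associations=pd.DataFrame(assoc),
        generating=gen,
        recovered=rec,
        n_simulated_agents=len(gen),
        seed=seed,
    )


def model_recovery(
    models,
    n_agents_per_model: int = 50,
    design: TaskDesign | None = None,
    seed: int = 0,
    parameter_distributions=None,
    priors: PriorSpec | None = None,
    optimizer_config: OptimizerConfig | None = None,
    generating_models=None,
) -> ConfusionMatrix:
    """Confusion matrix of generating model vs best-fitting model by AIC.

    For each generating model (``generating_models`` defaults to ``models``),
    ``n_agents_per_model`` agents are simulated at parameters drawn from
    ``parameter_distributions`` (cohort defaults when omitted); every
    candidate model in ``models`` is fitted to every dataset and the
    per-agent AIC winner tallied (ties split equally). Rows sum to 1.
    """
    if n_agents_per_model < 1:
        raise ValueError("n_agents_per_model must be >= 1")
    specs = [get_model(m) for m in models]
    ids = [s.model_id for s in specs]
    gen_specs = specs if generating_models is None else [
        get_model(m) for m in generating_models
    ]
    design = design or TaskDesign()
    dists = parameter_distributions or DEFAULT_PARAM_DISTS
    ss = np.random.SeedSequence(seed)
    counts = pd.DataFrame(0.0, index=[s.model_id for s in gen_specs], columns=ids)
    for gen_spec, gen_child in zip(gen_specs, ss.spawn(len(gen_specs))):
        for agent_child in gen_child.spawn(n_agents_per_model):
            draw, sim, fit = agent_child.spawn(3)
            params = sample_parameters(
                gen_spec.model_id, np.random.default_rng(draw), dists
            )
            table = simulate_agent(
                params, gen_spec, design, seed=_derived_seed(sim), participant_id="mr"
            )
            aics = {}
            for fit_spec, f_child in zip(specs, fit.spawn(len(specs))):
                res = fit_map(table, fit_spec, priors, optimizer_config,
                              seed=_derived_seed(f_child))
                aics[fit_spec.model_id] = res.aic
            lo = min(aics.values())
            tied = [m for m, a in aics.items() if a <= lo]
            for m in tied:
                counts.loc[gen_spec.model_id, m] += 1.0 / len(tied)
    return ConfusionMatrix(
        proportions=counts.div(counts.sum(axis=1), axis=0),
        n_per_row=n_agents_per_model,
        seed=seed,
    )


def _condition_curves(table: pd.DataFrame, trials_per_condition: int) -> np.ndarray:
    """Per-condition go indicator by occurrence index, shape (4, t_per_cond).

    Averages over participants present in the table; occurrence index is the
    within-participant presentation count of each condition.
    """
    df = table.copy()
    df["condition"] = df["required_action"].astype(str) + "_" + df["reward_type"].astype(str)
    df["is_go"] = (df["response"].astype(str) == "go").astype(float)
    df["occurrence"] = df.groupby(["participant_id", "condition"]).cumcount()
    out = np.full((len(CONDITION_LABELS), trials_per_condition), np.nan)
    grouped = df.groupby(["condition", "occurrence"], observed=True)["is_go"].mean()
    for ci, lab in enumerate(CONDITION_LABELS):
        for occ in range(trials_per_condition):
            if (lab, occ) in grouped.index:
                out[ci, occ] = grouped[(lab, occ)]
    return out


def posterior_predictive(
    fits: pd.DataFrame,
    model,
    design: TaskDesign | None = None,
    n_datasets: int = 1000,
    seed: int = 0,
    observed: pd.DataFrame | None = None,
) -> PpcSummary:
    """Simulate ``n_datasets`` cohorts at fitted parameters; summarize go curves.

    ``fits`` holds one row per participant with columns for the model's free
    parameters (e.g. the output of ``fit_cohort`` filtered to one model).
    Returns per-condition trial-by-trial mean p(go) across datasets with
    2.5/97.5 percentile bands, plus pooled per-condition means; when an
    observed cohort table is passed its raw curves ride along for comparison.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    spec = get_model(model)
    design = design or TaskDesign()
    params_list = fits[list(spec.free_parameters)].to_dict("records")
    ss = np.random.SeedSequence(seed)
    t_pc = design.trials_per_condition
    curves = np.empty((n_datasets, len(CONDITION_LABELS), t_pc))
    for d, d_child in enumerate(ss.spawn(n_datasets)):
        tables = []
        for j, (a_child, params) in enumerate(zip(d_child.spawn(len(params_list)), params_list)):
            tables.append(
                simulate_agent(params, spec, design, seed=_derived_seed(a_child),
                               participant_id=f"p{j:04d}")
            )
        curves[d] = _condition_curves(pd.concat(tables, ignore_index=True), t_pc)
    mean = curves.mean(axis=0)
    lo = np.percentile(curves, 2.5, axis=0)
    hi = np.percentile(curves, 97.5, axis=0)
    rows = []
    for ci, lab in enumerate(CONDITION_LABELS):
        for occ in range(t_pc):
            rows.append(
                {"condition": lab, "occurrence": occ, "mean": mean[ci, occ],
                 "ci_low": lo[ci, occ], "ci_high": hi[ci, occ]}
            )
    obs_df = None
    if observed is not None:
        obs = _condition_curves(observed, t_pc)
        obs_df = pd.DataFrame(
            [
                {"condition": lab, "occurrence": occ, "mean": obs[ci, occ]}
                for ci, lab in enumerate(CONDITION_LABELS)
                for occ in range(t_pc)
            ]
        )
    return PpcSummary(
        model_id=spec.model_id,
        n_datasets=n_datasets,
        curves=pd.DataFrame(rows),
        condition_means=pd.Series(mean.mean(axis=1), index=list(CONDITION_LABELS)),
        observed=obs_df,
    )
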