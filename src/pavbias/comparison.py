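"""Model comparison across participants: AIC summaries and model frequency.

Models are compared by the median AIC across participants (smaller is
better) and by model frequency — the proportion of participants for whom a
model attains the lowest AIC. AIC ties within a participant split that
participant's frequency mass equally among the tied models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def aic(log_lik: float, k: int) -> float:
    """Akaike's information criterion, 2k - 2*log_lik."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * log_lik


@dataclass(frozen=True)
class ComparisonTable:
    """Cohort-level model comparison."""

    median_aic: pd.Series          # per model
    frequency: pd.Series           # per model, sums to 1
    best_model: pd.Series          # per participant (first listed among ties)
    n_participants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median_aic": self.median_aic, "frequency": self.frequency}
        ).rename_axis("model_id")

    def summary(self) -> str:
        lines = [
            f"Model comparison over {self.n_participants} participants",
            "model   median AIC   frequency",
        ]
        for mid in self.median_aic.index:
            lines.append(
                f"{mid:>5s}   {self.median_aic[mid]:10.2f}   {self.frequency[mid]:9.4f}"
            )
        return "\n".join(lines)


def compare_models(fits: pd.DataFrame, tie_tol: float = 0.0) -> ComparisonTable:
    """Build the comparison table from cohort fit results.

    ``fits`` must hold one row per participant x model with columns
    participant_id, model_id and aic; every participant needs a fit for
    every model. AICs within ``tie_tol`` of a participant's minimum count
    as tied and split the frequency mass.
    """
    needed = {"participant_id", "model_id", "aic"}
    if not needed <= set(fits.columns):
        raise ValueError(f"fit table needs columns {sorted(needed)}")
    wide = fits.pivot(index="participant_id", columns="model_id", values="aic")
    if wide.isna().any().any():
        holes = [
            (pid, mid)
            for pid, row in wide.iterrows()
            for mid in row.index[row.isna()]
        ]
        raise ValueError(f"missing (participant, model) fits: {holes[:5]}")
    models = list(wide.columns)
    median_aic = wide.median(axis=0)
    freq = pd.Series(0.0, index=models)
    best = {}
    for pid, row in wide.iterrows():
        lo = row.min()
        tied = row.index[row <= lo + tie_tol]
        for mid in tied:
            freq[mid] += 1.0 / len(tied)
        best[pid] = tied[0]
    freq = freq / len(wide)
    return ComparisonTable(
        median_aic=median_aic,
        frequency=freq,
        best_model=pd.Series(best).rename("best_model"),
        n_participants=len(wide),
    )
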