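"""Risk-score survival stratification for a discovered subnetwork.

Each covered patient j receives the score S_j = sum_i beta_i * x_ij over
the subnetwork's genes i, where x_ij is normalized expression and beta_i
the univariate Cox proportional-hazards coefficient of gene i; patients
are split at the mean score into high-risk (S >= mean) and low-risk
(S < mean) groups.  Coefficient estimation is delegated to lifelines;
precomputed coefficients are accepted as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class SurvivalInput:
    """Expression (patients x genes), survival time and event indicator.

    Intended to be restricted to the patients covered by the subnetwork
    under study; index alignment is enforced.
    """

    expression: pd.DataFrame
    time: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.time.index) or not self.expression.index.equals(self.event.index):
            raise ValueError("expression, time and event must share the same patient index")


@dataclass
class RiskStratification:
    scores: dict[str, float]
    mean_score: float
    high: frozenset[str]
    low: frozenset[str]
    coefficients: dict[str, float] | None = None


def fit_univariate_cox(
    data: SurvivalInput, genes: Iterable[str] | None = None
) -> dict[str, float]:
    """Per-gene univariate Cox proportional-hazards coefficients.

    Each gene's expression is fitted alone against overall survival with
    the event indicator as censoring (lifelines, Efron tie handling).
    """
    from lifelines import CoxPHFitter

    genes = list(genes) if genes is not None else list(data.expression.columns)
    betas: dict[str, float] = {}
    for gene in genes:
        if gene not in data.expression.columns:
            raise KeyError(f"no expression column for gene {gene}")
        df = pd.DataFrame(
            {
                "x": data.expression[gene],
                "time": data.time,
                "event": data.event,
            }
        )
        fitter = CoxPHFitter()
        fitter.fit(df, duration_col="time", event_col="event")
        betas[gene] = float(fitter.params_["x"])
    return betas


def risk_scores(
    data: SurvivalInput,
    subnetwork_genes: Iterable[str],
    coefficients: Mapping[str, float],
) -> dict[str, float]:
    """S_j = sum_i beta_i x_ij over the subnetwork genes."""
    genes = list(subnetwork_genes)
    missing = [g for g in genes if g not in coefficients]
    if missing:
        raise KeyError(f"missing Cox coefficients for genes: {missing}")
    missing = [g for g in genes if g not in data.expression.columns]
    if missing:
        raise KeyError(f"missing expression for genes: {missing}")
    block = data.expression[genes]
    if block.isna().any().any():
        bad = block.isna().stack()
        patient, gene = bad[bad].index[0]
        raise ValueError(f"missing expression value for ({patient}, {gene})")
    weights = pd.Series({g: float(coefficients[g]) for g in genes})
    scores = block.mul(weights, axis=1).sum(axis=1)
    return {str(p): float(s) for p, s in scores.items()}


def stratify(
    scores: Mapping[str, float],
    coefficients: Mapping[str, float] | None = None,
) -> RiskStratification:
    """Mean-split into high (S >= mean) and low (S < mean) risk groups."""
    if len(scores) < 2:
        raise ValueError("stratification needs at least 2 patients")
    mean = sum(scores.values()) / len(scores)
    high = frozenset(p for p, s in scores.items() if s >= mean)
    low = frozenset(p for p, s in scores.items() if s < mean)
    return RiskStratification(
        dict(scores), mean, high, low,
        dict(coefficients) if coefficients is not None else None,
    )
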