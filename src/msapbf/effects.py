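"""Maximum-likelihood effect estimation for the selected model.

Fits the bud-failure response against methylation status, clonal age and
their interaction by GLM (binomial-logit on the dichotomized score by
default, Poisson-log for count responses), reports the McFadden adjusted
pseudo-R^2, converts coefficients to odds ratios, and produces the
predicted log-odds / probability curves over chronological age for the
demethylated and methylated states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bayes_loglinear import HierarchicalModel, ModelFrame, _term_block

__all__ = [
    "GlmFit",
    "SeparationError",
    "fit_glm",
    "mcfadden_adjusted_r2",
    "odds_ratio",
    "effect_curves",
]


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)complete separation."""


@dataclass
class GlmFit:
    coefficients: pd.Series
    log_likelihood: float
    null_log_likelihood: float
    k: int  # non-intercept parameters
    family: str  # "binomial-logit" or "poisson-log"
    deviance: float
    converged: bool


def _design_from_records(
    records: pd.DataFrame, model: HierarchicalModel
) -> tuple[np.ndarray, list[str]]:
    x = [np.ones((len(records), 1))]
    names = ["Intercept"]
    for term in model.sorted_terms:
        bx, bn = _term_block(records, term)
        x.append(bx)
        names.extend(bn)
    return np.column_stack(x), names


def fit_glm(
    frame: ModelFrame,
    model: HierarchicalModel,
    family: str = "binomial-logit",
    response: str | None = None,
    bf_threshold: int = 4,
) -> GlmFit:
    """Fit the model by iteratively reweighted least squares.

    For the binomial family the response is the dichotomized bud-failure
    indicator (score >= ``bf_threshold``) unless an explicit ``response``
    column is named.  Raises :class:`SeparationError` when the fit shows
    complete or quasi-complete separation (fitted probabilities pinned at
    0/1), which the record-level BF fits are prone to.
    """
    records = frame.records
    x, names = _design_from_records(records, model)
    if response is not None:
        y = records[response].to_numpy(float)
    elif family == "binomial-logit":
        y = (records["bf_score"] >= bf_threshold).astype(float).to_numpy()
    else:
        y = records["bf_score"].to_numpy(float)

    if family == "binomial-logit":
        fam = sm.families.Binomial()
    elif family == "poisson-log":
        fam = sm.families.Poisson()
    else:
        raise ValueError(f"unknown family {family!r}")

    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, x, family=fam).fit(maxiter=100, tol=1e-10)
        null = sm.GLM(y, np.ones((len(y), 1)), family=fam).fit()

    if family == "binomial-logit":
        mu = res.fittedvalues
        pinned = (mu < 1e-8) | (mu > 1 - 1e-8)
        if pinned.any() and np.abs(res.params).max() > 15:
            raise SeparationError(
                "complete or quasi-complete separation detected: "
                f"{int(pinned.sum())} fitted probabilities pinned at 0/1"
            )
    return GlmFit(
        coefficients=pd.Series(res.params, index=names),
        log_likelihood=float(res.llf),
        null_log_likelihood=float(null.llf),
        k=x.shape[1] - 1,
        family=family,
        deviance=float(res.deviance),
        converged=bool(res.converged),
    )


def mcfadden_adjusted_r2(fit: GlmFit) -> float:
    """McFadden's adjusted pseudo-R^2: 1 - (l_model - k)/l_null."""
    if fit.null_log_likelihood == 0:
        raise ZeroDivisionError("null log-likelihood is zero; index undefined")
    return 1.0 - (fit.log_likelihood - fit.k) / fit.null_log_likelihood


def odds_ratio(coefficients: Mapping[str, float], contrast: Mapping[str, float]) -> float:
    """exp of the contrast-weighted sum of coefficients.

    ``contrast`` maps coefficient names to the change in each covariate,
    e.g. ``{"ChronoAge": 1}`` for a one-unit age increase at the
    demethylated level, or ``{"ChronoAge": 1, "deMet01_1:ChronoAge": 1}``
    at the methylated level.
    """
    total = 0.0
    for name, weight in contrast.items():
        if name not in coefficients:
            raise KeyError(f"unknown coefficient {name!r}")
        total += weight * coefficients[name]
    return math.exp(total)


def effect_curves(
    coefficients: Mapping[str, float],
    age_grid: Sequence[float],
    intercept_name: str = "Intercept",
    demet_name: str = "deMet01_1",
    age_name: str = "ChronoAge",
    interaction_name: str = "deMet01_1:ChronoAge",
) -> pd.DataFrame:
    """Predicted log-odds and probabilities over age for both methylation levels.

    The log-odds are linear in age within each level; the difference of the
    two slopes equals the interaction coefficient.
    """
    b0 = coefficients.get(intercept_name, 0.0)
    b_m = coefficients.get(demet_name, 0.0)
    b_a = coefficients[age_name]
    b_i = coefficients.get(interaction_name, 0.0)
    age = np.asarray(age_grid, float)
    lo0 = b0 + b_a * age
    lo1 = b0 + b_m + (b_a + b_i) * age
    expit = lambda z: 1.0 / (1.0 + np.exp(-z))  # noqa: E731
    return pd.DataFrame(
        {
            "age": age,
            "demethylated_log_odds": lo0,
            "methylated_log_odds": lo1,
            "demethylated_prob": expit(lo0),
            "methylated_prob": expit(lo1),
        }
    )
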