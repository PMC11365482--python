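"""Genetic-architecture model space: enumeration, weighted least squares, AICc.

A model is a subset of the c-matrix effect columns; every model implicitly
contains the grand-mean intercept.  Each model is fit to the cohort means by
generalized least squares with the cohort SEs treated as *known* measurement
standard deviations (weights 1/se^2).  Under that convention the Gaussian
log-likelihood of a fitted model is

    loglik = -1/2 * [ wRSS + sum_j ln(2 pi se_j^2) ]

with wRSS = sum_j (mean_j - fit_j)^2 / se_j^2, which makes likelihoods of
models with different effect subsets directly comparable and the saturated
model well defined.  Model scores use the small-sample-corrected AIC:

    AICc = -2 loglik + 2K + 2K(K+1)/(n - K - 1)

with K = number of regression parameters (intercept + effects) and n the
number of cohorts.  When n - K - 1 <= 0 the correction is undefined; such
models receive +inf AICc so they are listed in reports but carry zero
weight.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelFit",
    "enumerate_models",
    "design_matrix",
    "fit_model",
    "aicc",
    "fit_model_space",
    "model_space_report",
    "RANK_RTOL",
]

#: relative singular-value cutoff below which a design column is dependent
RANK_RTOL = 1e-8


@dataclass(frozen=True)
class ModelFit:
    """One architecture model fitted to a trait's cohort means."""

    effects: tuple[str, ...]
    estimates: dict[str, float]  # includes "intercept"
    estimate_ses: dict[str, float]
    weighted_rss: float
    k_params: int
    loglik: float
    aicc: float
    n_cohorts: int

    @property
    def spec_label(self) -> str:
        return "+".join(self.effects) if self.effects else "(intercept)"


def _full_column_rank(x: np.ndarray, rtol: float = RANK_RTOL) -> bool:
    s = np.linalg.svd(x, compute_uv=False)
    if s.size == 0:
        return True
    return x.shape[1] <= x.shape[0] and int(np.sum(s > s[0] * rtol)) == x.shape[1]


def design_matrix(cmatrix: pd.DataFrame, effects: Sequence[str]) -> np.ndarray:
    """Intercept column prepended to the selected c-matrix columns."""
    n = len(cmatrix)
    if effects:
        return np.column_stack([np.ones(n), cmatrix.loc[:, list(effects)].to_numpy(float)])
    return np.ones((n, 1))


def enumerate_models(
    cmatrix: pd.DataFrame,
    max_effects: int | None = None,
    rank_rtol: float = RANK_RTOL,
) -> list[tuple[str, ...]]:
    """All estimable effect subsets of size 0..max_effects.

    A subset is estimable when the design matrix (intercept + selected
    columns) has full column rank, judged by singular values above
    ``rank_rtol`` times the largest.  ``max_effects`` defaults to
    n_cohorts − 1, the largest size that leaves the intercept estimable.
    Order is deterministic: by subset size, then lexicographic labels.
    """
    if len(cmatrix) < 2:
        raise ValueError("model enumeration needs a c-matrix with at least 2 cohorts")
    if max_effects is None:
        max_effects = len(cmatrix) - 1
    labels = sorted(cmatrix.columns)
    out: list[tuple[str, ...]] = []
    for size in range(0, max_effects + 1):
        for subset in itertools.combinations(labels, size):
            if _full_column_rank(design_matrix(cmatrix, subset), rank_rtol):
                out.append(subset)
    return out


def fit_model(
    effects: Sequence[str],
    cmatrix: pd.DataFrame,
    means: Sequence[float],
    ses: Sequence[float],
) -> ModelFit:
    """Weighted least squares fit of one effect subset to the cohort means.

    ``means`` and ``ses`` follow the c-matrix cohort order.  SEs are known
    measurement SDs: weights are 1/se^2 and parameter covariance is
    (X' W X)^-1 with no residual-variance rescaling.
    """
    effects = tuple(effects)
    y = np.asarray(means, dtype=float)
    se = np.asarray(ses, dtype=float)
    n = len(cmatrix)
    if y.shape != (n,) or se.shape != (n,):
        raise ValueError("need one mean and one SE per c-matrix cohort")
    if np.any(se <= 0):
        raise ValueError(
            "every cohort SE must be positive; supply a positive SE "
            "(a zero SE would give that cohort infinite weight)"
        )
    x = design_matrix(cmatrix, effects)
    if not _full_column_rank(x):
        raise ValueError(
            f"effect subset {effects} is not estimable for this c-matrix "
            "(rank-deficient design); enumerate_models pre-filters these"
        )
    w = 1.0 / se**2
    xtw = x.T * w
    xtwx = xtw @ x
    beta = np.linalg.solve(xtwx, xtw @ y)
    cov = np.linalg.inv(xtwx)
    resid = y - x @ beta
    wrss = float(np.sum(w * resid**2))
    loglik = -0.5 * (wrss + float(np.sum(np.log(2.0 * math.pi * se**2))))
    k = len(effects) + 1
    names = ("intercept",) + effects
    fit = ModelFit(
        effects=effects,
        estimates=dict(zip(names, beta.tolist())),
        estimate_ses=dict(zip(names, np.sqrt(np.diag(cov)).tolist())),
        weighted_rss=wrss,
        k_params=k,
        loglik=loglik,
        aicc=math.nan,
        n_cohorts=n,
    )
    return replace(fit, aicc=aicc(fit, n))


def aicc(fit: ModelFit, n_cohorts: int) -> float:
    """Small-sample-corrected AIC; +inf when the correction is undefined."""
    k = fit.k_params
    if n_cohorts - k - 1 <= 0:
        return math.inf
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_cohorts - k - 1)


def fit_model_space(
    cmatrix: pd.DataFrame,
    means: Sequence[float],
    ses: Sequence[float],
    max_effects: int | None = None,
    specs: Sequence[tuple[str, ...]] | None = None,
) -> list[ModelFit]:
    """Fit every estimable model; pass precomputed ``specs`` to skip enumeration."""
    if specs is None:
        specs = enumerate_models(cmatrix, max_effects=max_effects)
    return [fit_model(spec, cmatrix, means, ses) for spec in specs]


def model_space_report(
    fits: Sequence[ModelFit],
    weights: Sequence[float] | None = None,
    confidence_flags: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """One row per model: effects, K, wRSS, loglik, AICc (+ optional weights)."""
    df = pd.DataFrame(
        {
            "effects": [f.spec_label for f in fits],
            "k_params": [f.k_params for f in fits],
            "weighted_rss": [f.weighted_rss for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": [f.aicc for f in fits],
        }
    )
    if weights is not None:
        df["weight"] = list(weights)
        order = np.argsort(-df["weight"].to_numpy(), kind="stable")
        cum = np.empty(len(df))
        cum[order] = np.cumsum(df["weight"].to_numpy()[order])
        df["cumulative_weight"] = cum
    if confidence_flags is not None:
        df["in_confidence_set"] = list(confidence_flags)
    return df
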