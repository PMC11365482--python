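"""Akaike weights, confidence sets, model averaging and architecture pooling.

Given the AICc of every fitted model, each model i receives the Akaike
weight w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2) with delta_i the AICc
difference to the best model.  The 95% confidence set is the smallest
prefix of the weight-ranked models whose cumulative weight reaches the
confidence level.  Effect estimates are then averaged over the confidence
set with renormalized weights and zero substitution: a model that omits an
effect contributes an estimate of 0 for it (shrinkage averaging).  The
unconditional standard error folds model-selection uncertainty into the
usual sampling SE:

    use(beta) = sum_i w_i * sqrt( se_i^2 + (beta_i - beta_bar)^2 )

Variable importance of an effect is the summed (renormalized) weight of the
confidence-set models that contain it.  An effect is reported as part of
the architecture only when its variable importance exceeds 0.5 *and* its
+-1 SE interval excludes zero; included effects are pooled by category
(additive: Aa, Ca; dominance: Ad; epistatic: AaAa, AaAd, AdAd, AaCa, AdCa;
maternal: Mea, Med) and scaled by absolute value to sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ModelFit

__all__ = [
    "WeightedModelSet",
    "AveragedEffect",
    "ArchitectureSummary",
    "EFFECT_CATEGORY",
    "akaike_weights",
    "model_average",
    "apply_inclusion_criteria",
    "pool_and_scale",
    "averaged_effects_table",
    "architecture_table",
]

#: pooling category of each composite effect
EFFECT_CATEGORY: Mapping[str, str] = {
    "Aa": "additive",
    "Ca": "additive",
    "Ad": "dominance",
    "Mea": "maternal",
    "Med": "maternal",
    "AaAa": "epistatic",
    "AaAd": "epistatic",
    "AdAd": "epistatic",
    "AaCa": "epistatic",
    "AdCa": "epistatic",
}

CATEGORIES = ("additive", "dominance", "epistatic", "maternal")


@dataclass(frozen=True)
class WeightedModelSet:
    """Fitted models with Akaike weights and confidence-set membership."""

    fits: tuple[ModelFit, ...]
    delta: tuple[float, ...]
    weights: tuple[float, ...]
    confidence_flags: tuple[bool, ...]
    confidence_level: float

    @property
    def confidence_set_size(self) -> int:
        return int(sum(self.confidence_flags))

    def confidence_set(self) -> list[tuple[ModelFit, float]]:
        """(fit, renormalized weight) pairs, best model first."""
        pairs = [
            (i, self.weights[i]) for i in range(len(self.fits)) if self.confidence_flags[i]
        ]
        pairs.sort(key=lambda p: (-p[1], p[0]))
        total = sum(w for _, w in pairs)
        return [(self.fits[i], w / total) for i, w in pairs]


@dataclass(frozen=True)
class AveragedEffect:
    """Model-averaged estimate of one composite effect."""

    effect: str
    estimate: float
    unconditional_se: float
    variable_importance: float
    included: bool = False


@dataclass(frozen=True)
class ArchitectureSummary:
    """Pooled architecture proportions for one trait (one summary-table row)."""

    trait: str
    proportions: dict[str, float]  # over CATEGORIES; NaN when nothing included
    included_effects: tuple[AveragedEffect, ...]
    confidence_set_size: int


def akaike_weights(
    fits: Sequence[ModelFit],
    confidence_level: float = 0.95,
) -> WeightedModelSet:
    """Akaike weights from AICc plus the minimal confidence set.

    Infinite-AICc models get weight 0.  The confidence set is the smallest
    prefix of models sorted by descending weight (ties broken by model
    order) whose cumulative weight is at least ``confidence_level``.
    """
    aiccs = np.array([f.aicc for f in fits], dtype=float)
    finite = np.isfinite(aiccs)
    if not finite.any():
        raise ValueError("no model has finite AICc; cannot form Akaike weights")
    delta = np.where(finite, aiccs - aiccs[finite].min(), math.inf)
    raw = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    weights = raw / raw.sum()
    order = sorted(range(len(fits)), key=lambda i: (-weights[i], i))
    flags = [False] * len(fits)
    cum = 0.0
    for i in order:
        flags[i] = True
        cum += weights[i]
        if cum >= confidence_level:
            break
    return WeightedModelSet(
        fits=tuple(fits),
        delta=tuple(delta.tolist()),
        weights=tuple(weights.tolist()),
        confidence_flags=tuple(flags),
        confidence_level=confidence_level,
    )


def model_average(
    wset: WeightedModelSet,
    effect_labels: Sequence[str] | None = None,
    scope: str = "confidence",
) -> list[AveragedEffect]:
    """Zero-substitution model averaging of every effect.

    ``scope`` is "confidence" (average over the confidence set with
    renormalized weights — the default convention) or "all" (average over
    every finite-weight model with the raw weights).
    """
    if scope == "confidence":
        pool = wset.confidence_set()
    elif scope == "all":
        pool = [
            (f, w) for f, w in zip(wset.fits, wset.weights) if w > 0 or math.isfinite(f.aicc)
        ]
    else:
        raise ValueError("scope must be 'confidence' or 'all'")
    if not pool:
        raise ValueError("empty model pool")
    if effect_labels is None:
        seen: dict[str, None] = {}
        for f, _ in pool:
            for e in f.effects:
                seen.setdefault(e)
        effect_labels = sorted(seen)
    out = []
    for eff in effect_labels:
        betas = np.array([f.estimates.get(eff, 0.0) for f, _ in pool])
        ses = np.array([f.estimate_ses.get(eff, 0.0) for f, _ in pool])
        w = np.array([wi for _, wi in pool])
        est = float(np.sum(w * betas))
        use = float(np.sum(w * np.sqrt(ses**2 + (betas - est) ** 2)))
        vi = float(np.sum(w * np.array([eff in f.effects for f, _ in pool])))
        out.append(
            AveragedEffect(
                effect=eff, estimate=est, unconditional_se=use, variable_importance=vi
            )
        )
    return out


def apply_inclusion_criteria(
    effects: Sequence[AveragedEffect],
    vi_threshold: float = 0.5,
    se_multiplier: float = 1.0,
) -> list[AveragedEffect]:
    """Mark effects whose evidence passes both inclusion criteria.

    Included means variable importance strictly above ``vi_threshold`` and
    |estimate| strictly greater than ``se_multiplier`` unconditional SEs
    (the estimate's interval excludes zero).
    """
    return [
        replace(
            e,
            included=(
                e.variable_importance > vi_threshold
                and abs(e.estimate) - se_multiplier * e.unconditional_se > 0
            ),
        )
        for e in effects
    ]


def pool_and_scale(
    effects: Sequence[AveragedEffect],
    trait: str,
    confidence_set_size: int = 1,
) -> ArchitectureSummary:
    """Pool included effects into category proportions scaled to sum to one.

    Each included effect contributes |estimate| to its category; category
    totals are divided by the grand total.  With no included effect every
    proportion is NaN (no reliable architecture inference).
    """
    included = tuple(e for e in effects if e.included)
    if not included:
        props = {c: math.nan for c in CATEGORIES}
    else:
        totals = {c: 0.0 for c in CATEGORIES}
        for e in included:
            totals[EFFECT_CATEGORY[e.effect]] += abs(e.estimate)
        grand = sum(totals.values())
        props = {c: totals[c] / grand for c in CATEGORIES}
    return ArchitectureSummary(
        trait=trait,
        proportions=props,
        included_effects=included,
        confidence_set_size=confidence_set_size,
    )


def averaged_effects_table(
    effects: Sequence[AveragedEffect], trait: str
) -> pd.DataFrame:
    """Delimited-text-ready table of averaged effects for one trait."""
    return pd.DataFrame(
        {
            "trait": trait,
            "effect": [e.effect for e in effects],
            "estimate": [e.estimate for e in effects],
            "unconditional_se": [e.unconditional_se for e in effects],
            "variable_importance": [e.variable_importance for e in effects],
            "included": [e.included for e in effects],
        }
    )


def architecture_table(summaries: Sequence[ArchitectureSummary]) -> pd.DataFrame:
    """One row per trait: category proportions and confidence-set size."""
    return pd.DataFrame(
        {
            "trait": [s.trait for s in summaries],
            **{c: [s.proportions[c] for s in summaries] for c in CATEGORIES},
            "confidence_set_size": [s.confidence_set_size for s in summaries],
        }
    )
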