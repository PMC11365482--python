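"""End-to-end line cross analysis: cohort summaries in, architectures out."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import averaging, models
from .averaging import ArchitectureSummary

__all__ = ["AnalysisConfig", "TraitAnalysis", "analyze_trait", "analyze_summaries"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the analysis; defaults are the standard ones."""

    confidence_level: float = 0.95
    vi_threshold: float = 0.5
    se_multiplier: float = 1.0
    averaging_scope: str = "confidence"  # or "all"
    max_effects: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0, 1)")
        if self.vi_threshold <= 0 or self.se_multiplier <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class TraitAnalysis:
    """Everything the pipeline computed for one trait."""

    trait: str
    fits: tuple[models.ModelFit, ...]
    weighted: averaging.WeightedModelSet
    averaged_effects: tuple[averaging.AveragedEffect, ...]
    architecture: ArchitectureSummary

    @property
    def model_report(self) -> pd.DataFrame:
        return models.model_space_report(
            self.fits, self.weighted.weights, self.weighted.confidence_flags
        )

    @property
    def effects_table(self) -> pd.DataFrame:
        return averaging.averaged_effects_table(self.averaged_effects, self.trait)


def analyze_trait(
    cmatrix: pd.DataFrame,
    trait_summaries: pd.DataFrame,
    trait: str,
    config: AnalysisConfig = AnalysisConfig(),
    specs: Sequence[tuple[str, ...]] | None = None,
) -> TraitAnalysis:
    """Run the full analysis for one trait.

    ``trait_summaries`` must hold one row per c-matrix cohort with columns
    cohort, mean, se.  ``specs`` lets callers reuse a precomputed model
    enumeration across traits.
    """
    missing = set(cmatrix.index) - set(trait_summaries["cohort"])
    if missing:
        raise ValueError(
            f"trait {trait!r}: no summary for cohort(s) {', '.join(sorted(missing))}"
        )
    ordered = trait_summaries.set_index("cohort").loc[cmatrix.index]
    fits = models.fit_model_space(
        cmatrix,
        ordered["mean"].to_numpy(),
        ordered["se"].to_numpy(),
        max_effects=config.max_effects,
        specs=specs,
    )
    wset = averaging.akaike_weights(fits, config.confidence_level)
    avg = averaging.model_average(
        wset, effect_labels=list(cmatrix.columns), scope=config.averaging_scope
    )
    avg = averaging.apply_inclusion_criteria(
        avg, vi_threshold=config.vi_threshold, se_multiplier=config.se_multiplier
    )
    arch = averaging.pool_and_scale(avg, trait, wset.confidence_set_size)
    return TraitAnalysis(
        trait=trait,
        fits=tuple(fits),
        weighted=wset,
        averaged_effects=tuple(avg),
        architecture=arch,
    )


def analyze_summaries(
    cmatrix: pd.DataFrame,
    summaries: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict[str, TraitAnalysis]:
    """Analyze every trait in a cohort-summary table; returns trait → analysis."""
    specs = models.enumerate_models(cmatrix, max_effects=config.max_effects)
    out: dict[str, TraitAnalysis] = {}
    for trait in pd.unique(summaries["trait"]):
        tdf = summaries[summaries["trait"] == trait]
        out[str(trait)] = analyze_trait(cmatrix, tdf, str(trait), config, specs=specs)
    return out
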