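"""Synthetic plant-nested phenotype data with known genetic architectures.

The generator mirrors the structure of a real line cross experiment: each
cohort's expected mean is the grand mean plus the c-matrix row times a true
effect vector; each plant carries a Gaussian random effect around its
cohort mean (shared greenhouse position, developmental state, ...); each
replicate measurement (a leaf) adds independent Gaussian noise around its
plant's level.  Defaults reproduce the study design this package was built
around: five cohorts (P1, P2, F2, BC1, rBC2) with two plants each and
23/14/13/14/21 leaves per cohort.

Because the truth is known, :func:`recovery_experiment` can score the whole
pipeline: how often each true effect is recovered (included in the
architecture), estimate bias, and how often truly absent effects sneak in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import pedigree as ped
from .pipeline import AnalysisConfig, analyze_trait
from . import models, summaries as summ

__all__ = [
    "STUDY_LEAF_COUNTS",
    "SimulationConfig",
    "SimulatedDataset",
    "expected_cohort_means",
    "simulate_cohorts",
    "recovery_experiment",
    "load_simulation_config",
    "write_truth",
]

#: leaves per plant in the emulated design (two plants per cohort;
#: totals 23, 14, 13, 14, 21 across P1, P2, F2, BC1, rBC2)
STUDY_LEAF_COUNTS: Mapping[str, tuple[int, ...]] = {
    "P1": (12, 11),
    "P2": (7, 7),
    "F2": (7, 6),
    "BC1": (7, 7),
    "rBC2": (11, 10),
}


def _default_pedigree() -> dict[str, ped.CohortPedigree]:
    return ped.study_pedigree()


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    sigma_plant is the SD of plant-level random effects (trait units);
    sigma_obs the SD of replicate noise within a plant.  obs_per_plant maps
    cohort → leaves per plant; omitted cohorts fall back to the study leaf
    counts, or to two plants of ``default_obs`` leaves for non-study names.
    """

    true_effects: dict[str, float] = field(default_factory=dict)
    grand_mean: float = 0.0
    sigma_plant: float = 0.5
    sigma_obs: float = 1.0
    pedigrees: dict[str, ped.CohortPedigree] = field(default_factory=_default_pedigree)
    cohorts: tuple[str, ...] = ("P1", "P2", "F2", "BC1", "rBC2")
    obs_per_plant: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in STUDY_LEAF_COUNTS.items()}
    )
    default_obs: tuple[int, ...] = (12, 11)
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_plant < 0 or self.sigma_obs < 0:
            raise ValueError("noise SDs must be non-negative")
        for cohort, counts in self.obs_per_plant.items():
            if any(c < 1 for c in counts):
                raise ValueError(f"cohort {cohort!r}: every plant needs >= 1 observation")

    def cmatrix(self) -> pd.DataFrame:
        cm = ped.build_cmatrix([self.pedigrees[c] for c in self.cohorts])
        unknown = set(self.true_effects) - set(cm.columns)
        if unknown:
            raise ValueError(f"unknown effect label(s): {', '.join(sorted(unknown))}")
        return cm

    def plants_for(self, cohort: str) -> tuple[int, ...]:
        return tuple(self.obs_per_plant.get(cohort, self.default_obs))


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated records plus the generating truth."""

    records: pd.DataFrame  # cohort, plant_id, trait, value
    truth: SimulationConfig
    expected_means: pd.Series  # per cohort


def expected_cohort_means(
    cmatrix: pd.DataFrame, grand_mean: float, true_effects: Mapping[str, float]
) -> pd.Series:
    """Per-cohort expectation: grand mean + c-matrix row · effect vector."""
    unknown = set(true_effects) - set(cmatrix.columns)
    if unknown:
        raise ValueError(f"unknown effect label(s): {', '.join(sorted(unknown))}")
    mu = pd.Series(float(grand_mean), index=cmatrix.index)
    for eff, beta in true_effects.items():
        mu = mu + beta * cmatrix[eff]
    return mu


def simulate_cohorts(config: SimulationConfig) -> SimulatedDataset:
    """Draw one plant-nested dataset; fully reproducible from ``config.seed``.

    Each cohort consumes an independent random stream derived from the seed,
    so adding a cohort does not perturb the others' draws.
    """
    cm = config.cmatrix()
    mu = expected_cohort_means(cm, config.grand_mean, config.true_effects)
    streams = np.random.SeedSequence(config.seed).spawn(len(config.cohorts))
    rows = []
    for cohort, ss in zip(config.cohorts, streams):
        rng = np.random.default_rng(ss)
        for p, n_obs in enumerate(config.plants_for(cohort), start=1):
            level = mu[cohort] + rng.normal(0.0, config.sigma_plant)
            values = level + rng.normal(0.0, config.sigma_obs, size=n_obs)
            for v in values:
                rows.append((cohort, f"{cohort}_plant{p}", config.trait, float(v)))
    records = pd.DataFrame(rows, columns=["cohort", "plant_id", "trait", "value"])
    return SimulatedDataset(records=records, truth=config, expected_means=mu)


def recovery_experiment(
    config: SimulationConfig,
    replicates: int,
    analysis: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Score pipeline recovery of the true architecture over seeded replicates.

    Runs simulate → summarize → fit → average → include for each replicate
    (replicate r uses seed ``config.seed + r``).  Returns one row per effect
    with the true value, mean estimate, bias, and the fraction of replicates
    in which the effect was included; for truly-zero effects that fraction
    is the spurious-inclusion rate.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cm = config.cmatrix()
    specs = models.enumerate_models(cm, max_effects=analysis.max_effects)
    estimates: dict[str, list[float]] = {e: [] for e in cm.columns}
    inclusions: dict[str, int] = {e: 0 for e in cm.columns}
    arch_props: list[dict[str, float]] = []
    for r in range(replicates):
        cfg_r = SimulationConfig(**{**config.__dict__, "seed": config.seed + r})
        data = simulate_cohorts(cfg_r)
        table = summ.summarize_table(data.records, cohort_order=list(config.cohorts))
        res = analyze_trait(cm, table, config.trait, analysis, specs=specs)
        for eff in res.averaged_effects:
            estimates[eff.effect].append(eff.estimate)
            inclusions[eff.effect] += int(eff.included)
        arch_props.append(res.architecture.proportions)
    rows = []
    for e in cm.columns:
        true = config.true_effects.get(e, 0.0)
        mean_est = float(np.mean(estimates[e]))
        rows.append(
            {
                "effect": e,
                "true_value": true,
                "mean_estimate": mean_est,
                "bias": mean_est - true,
                "inclusion_rate": inclusions[e] / replicates,
                "truly_zero": true == 0.0,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["architecture_proportions"] = arch_props
    return report


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a simulation configuration from structured text (YAML)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {
        "true_effects",
        "grand_mean",
        "sigma_plant",
        "sigma_obs",
        "cohorts",
        "obs_per_plant",
        "default_obs",
        "trait",
        "seed",
        "pedigree_file",
    }
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(
            f"{path}: invalid config key(s) {', '.join(sorted(unknown))}; "
            f"valid keys: {', '.join(sorted(valid))}"
        )
    kwargs: dict = {}
    if "pedigree_file" in raw:
        kwargs["pedigrees"] = ped.load_pedigree(raw.pop("pedigree_file"))
    if "cohorts" in raw:
        kwargs["cohorts"] = tuple(raw.pop("cohorts"))
    if "obs_per_plant" in raw:
        kwargs["obs_per_plant"] = {k: tuple(v) for k, v in raw.pop("obs_per_plant").items()}
    if "default_obs" in raw:
        kwargs["default_obs"] = tuple(raw.pop("default_obs"))
    kwargs.update(raw)
    return SimulationConfig(**kwargs)


def write_truth(data: SimulatedDataset, path: str | Path) -> None:
    """Write the generating truth as a YAML sidecar next to the records."""
    cfg = data.truth
    payload = {
        "trait": cfg.trait,
        "grand_mean": cfg.grand_mean,
        "true_effects": dict(cfg.true_effects),
        "sigma_plant": cfg.sigma_plant,
        "sigma_obs": cfg.sigma_obs,
        "seed": cfg.seed,
        "cohorts": list(cfg.cohorts),
        "obs_per_plant": {c: list(cfg.plants_for(c)) for c in cfg.cohorts},
        "expected_means": {c: float(v) for c, v in data.expected_means.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
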