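"""Per-cohort trait means and standard errors from plant-nested measurements.

Multiple leaves (or other replicate measurements) taken from one plant are
not independent draws from the cohort, so cohort statistics are built in
two stages: each plant is first collapsed to its own mean, and the cohort
mean is the unweighted mean of the plant means.  The cohort standard error
combines the within-plant standard deviations:

    SE = sqrt( sum_i  sigma_i^2 / s_i )

over plants i, where sigma_i is the sample SD of plant i's measurements and
s_i the number of measurements from that plant.  Note this is the SE of the
*sum* of plant means; dividing by the number of plants n would give the SE
of their mean, available as :func:`se_of_mean_of_means` but never the
default because downstream weighting must match how the reference SEs were
produced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSummary",
    "cohort_mean",
    "cohort_se",
    "se_of_mean_of_means",
    "plant_statistics",
    "summarize_table",
    "read_records",
    "write_summaries",
    "read_summaries",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = ("cohort", "plant_id", "trait", "value")


@dataclass(frozen=True)
class CohortSummary:
    """Mean, standard error and counts for one (cohort, trait)."""

    cohort: str
    trait: str
    mean: float
    se: float
    n_plants: int
    n_obs: int
    #: per-plant (sigma_i, s_i) pairs entering the SE formula
    per_plant: tuple[tuple[float, int], ...] = ()


def cohort_mean(values_by_plant: Sequence[Sequence[float]]) -> float:
    """Mean of plant means; plants with unequal replicate counts count equally."""
    if not values_by_plant or any(len(v) == 0 for v in values_by_plant):
        raise ValueError("each plant needs at least one observation")
    return float(np.mean([np.mean(v) for v in values_by_plant]))


def cohort_se(per_plant: Sequence[tuple[float, int]]) -> float:
    """Combined standard error sqrt(sum sigma_i^2 / s_i) over plants."""
    if not per_plant:
        raise ValueError("per_plant must be non-empty")
    total = 0.0
    for sigma, s in per_plant:
        if s < 1:
            raise ValueError(f"sample count must be >= 1, got {s}")
        total += (sigma * sigma) / s
    return math.sqrt(total)


def se_of_mean_of_means(per_plant: Sequence[tuple[float, int]]) -> float:
    """SE of the mean of plant means: the combined SE divided by n plants.

    Provided for completeness; the default pipeline uses :func:`cohort_se`.
    """
    return cohort_se(per_plant) / len(per_plant)


def plant_statistics(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, sample SD, count) for one plant's measurements.

    A single-measurement plant has no defined sample SD; it contributes
    sigma = 0 and a warning is logged, since its within-plant variance
    cannot inform the cohort SE.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("a plant needs at least one observation")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite trait value")
    if arr.size == 1:
        logger.warning(
            "plant with a single observation: within-plant SD set to 0"
        )
        return float(arr[0]), 0.0, 1
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def read_records(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a plant-nested phenotype table (cohort, plant_id, trait, value)."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite trait values")
    return df


def summarize_table(
    records: pd.DataFrame,
    cohort_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Collapse phenotype records to one summary row per (cohort, trait).

    Parameters
    ----------
    records
        Long table with columns cohort, plant_id, trait, value.
    cohort_order
        Known cohort labels in reporting order (e.g. the pedigree's).  A
        record cohort absent from this list is an error; traits are ordered
        alphabetically within cohorts.

    Returns
    -------
    DataFrame with columns cohort, trait, mean, se, n_plants, n_obs.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {', '.join(missing)}")
    cohorts_present = list(pd.unique(records["cohort"]))
    if cohort_order is None:
        cohort_order = cohorts_present
    else:
        unknown = [c for c in cohorts_present if c not in set(cohort_order)]
        if unknown:
            raise ValueError(
                f"unknown cohort label(s) not in the pedigree configuration: "
                f"{', '.join(map(str, unknown))}"
            )
    n_cohorts = len(set(cohort_order) & set(cohorts_present))
    rows = []
    for trait in sorted(records["trait"].unique()):
        tdf = records[records["trait"] == trait]
        present = set(tdf["cohort"])
        if len(present) < n_cohorts:
            logger.warning(
                "trait %r present for only %d of %d cohorts", trait, len(present), n_cohorts
            )
        for cohort in cohort_order:
            cdf = tdf[tdf["cohort"] == cohort]
            if cdf.empty:
                continue
            stats = [
                plant_statistics(g["value"].to_numpy())
                for _, g in cdf.groupby("plant_id", sort=True)
            ]
            per_plant = [(sd, s) for _, sd, s in stats]
            rows.append(
                {
                    "cohort": cohort,
                    "trait": trait,
                    "mean": float(np.mean([m for m, _, _ in stats])),
                    "se": cohort_se(per_plant),
                    "n_plants": len(stats),
                    "n_obs": int(sum(s for _, _, s in stats)),
                }
            )
    out = pd.DataFrame(rows, columns=["cohort", "trait", "mean", "se", "n_plants", "n_obs"])
    # stable order: cohort as configured within alphabetical traits
    return out.reset_index(drop=True)


def write_summaries(summaries: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a cohort-summary table; the same format is accepted as direct input."""
    summaries.to_csv(path, sep=sep, index=False)


def read_summaries(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a cohort-summary table (cohort, trait, mean, se[, n_plants, n_obs])."""
    df = pd.read_csv(path, sep=sep)
    needed = ["cohort", "trait", "mean", "se"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
    if (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0, ["cohort", "trait"]].to_records(index=False)
        raise ValueError(
            "standard errors must be positive for weighted fitting; "
            f"offending rows: {list(bad)}. Supply a positive SE for every cohort."
        )
    return df
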