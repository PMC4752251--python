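"""Reference and habitat suitability indices.

The reference suitability index (RSI) is the minimum of the per-province mean
daily adult-female counts over the calibration region: even the least
populated reference province demonstrably sustained a population, so any cell
matching it is suitable.  A cell's habitat suitability index (HSI) is its
mean daily adult count divided by the RSI (a fold change); cells with
HSI < 1/16 are classed unsuitable, [1/16, 1) low, >= 1 high.  Administrative
regions inherit the largest HSI among their cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SuitabilityRecord",
    "HSI_THRESHOLD",
    "reference_suitability_index",
    "habitat_suitability_index",
    "aggregate_region",
    "mean_daily_adults",
]

#: Default HSI threshold below which a cell is classed unsuitable.
HSI_THRESHOLD = 1.0 / 16.0


@dataclass
class SuitabilityRecord:
    cell: object
    mean_adults: float
    HSI: float
    suitability_class: str


def mean_daily_adults(output, burn_in_years: int = 1,
                      high_season_only: bool = False) -> float:
    """Mean daily adult females over the post-burn-in span of a simulation.

    Winter zeros are included by default; ``high_season_only`` restricts the
    average to May-October days.
    """
    df = output.data
    years = sorted(df["date"].dt.year.unique())
    keep = df["date"].dt.year.isin(years[burn_in_years:])
    if high_season_only:
        keep &= df["date"].dt.month.between(5, 10)
    return float(df.loc[keep, "adult"].mean())


def reference_suitability_index(per_region_means: dict) -> tuple:
    """RSI = minimum of the per-region mean daily adult counts.

    Returns ``(RSI, argmin_region)``.
    """
    if not per_region_means:
        raise ValueError("at least one reference region required")
    if any(v < 0 for v in per_region_means.values()):
        raise ValueError("region means must be >= 0")
    region = min(per_region_means, key=per_region_means.get)
    rsi = float(per_region_means[region])
    if rsi == 0.0:
        warnings.warn("reference index is 0; HSI undefined downstream", stacklevel=2)
    return rsi, region


def habitat_suitability_index(cell_mean: float, RSI: float,
                              threshold: float = HSI_THRESHOLD,
                              cell=None) -> SuitabilityRecord:
    """HSI = cell mean / RSI, classed by the threshold."""
    if RSI <= 0:
        raise ValueError("RSI must be > 0")
    if cell_mean < 0:
        raise ValueError("cell mean must be >= 0")
    hsi = cell_mean / RSI
    if hsi >= 1.0:
        cls = "high"
    elif hsi >= threshold:
        cls = "low"
    else:
        cls = "unsuitable"
    return SuitabilityRecord(cell, cell_mean, hsi, cls)


def aggregate_region(cell_hsis, threshold: float = HSI_THRESHOLD) -> tuple:
    """Regional HSI: the maximum over the region's cells (most representative).

    Returns ``(regional_HSI, regional_class)``.
    """
    vals = list(cell_hsis)
    if not vals:
        raise ValueError("region has no cells")
    hsi = float(max(vals))
    if hsi >= 1.0:
        cls = "high"
    elif hsi >= threshold:
        cls = "low"
    else:
        cls = "unsuitable"
    return hsi, cls


def suitability_table(records) -> pd.DataFrame:
    """Tabulate SuitabilityRecords as ``cell, mean_adults, HSI, class``."""
    return pd.DataFrame([{
        "cell": r.cell, "mean_adults": r.mean_adults, "HSI": r.HSI,
        "class": r.suitability_class} for r in records])
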