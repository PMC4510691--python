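"""Two-period change maps and quartile impact/trend classification.

The change map is the cellwise difference of cumulative impact between the
later and earlier period (positive = impact increased), computed on the
comparable stressor subset with both periods normalized against the same
joint reference maxima. Pixels are then classified as high / medium / low
impact (top quartile / middle / bottom quartile of the current impact
distribution) and increasing / no-change / decreasing trend (same rule on
the change distribution). "No change" is the middle 50% band of the change
distribution, not literally zero. Crossing the extreme classes yields the
four management-relevant combinations (high & increasing, high &
decreasing, low & increasing, low & decreasing).

Boundary rule: strict inequalities on both sides — a value exactly equal
to a cutoff falls in the middle class. Percentiles use linear
interpolation between order statistics; thresholds are recorded on the
output so the classes can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Raster, assert_aligned
from .impact import ImpactMap

__all__ = [
    "ChangeMap",
    "ClassMap",
    "change_map",
    "quartile_thresholds",
    "classify",
    "classify_raster",
    "extreme_combinations",
    "area_fractions",
    "LEVEL_CODES",
    "TREND_CODES",
    "COMBO_CODES",
]

LEVEL_CODES = {"low": 0, "medium": 1, "high": 2}
TREND_CODES = {"decreasing": 0, "no_change": 1, "increasing": 2}
COMBO_CODES = {
    "other": 0,
    "high_increasing": 1,
    "high_decreasing": 2,
    "low_increasing": 3,
    "low_decreasing": 4,
}


@dataclass
class ChangeMap:
    """Cellwise t2 - t1 cumulative impact difference (comparable subset)."""

    raster: Raster
    stressor_subset: list[str]
    mode: str


@dataclass
class ClassMap:
    """Categorical impact-level and trend rasters plus the cutoffs used."""

    level: Raster  # category codes per LEVEL_CODES
    trend: Raster  # category codes per TREND_CODES
    level_low_cut: float
    level_high_cut: float
    trend_low_cut: float
    trend_high_cut: float


def change_map(impact_t2: ImpactMap, impact_t1: ImpactMap) -> ChangeMap:
    """Difference of two impact maps (later minus earlier).

    Both maps must share mode, grid and stressor subset; nodata wherever
    either input is nodata.
    """
    if impact_t1.mode != impact_t2.mode:
        raise ValueError(f"mode mismatch: {impact_t1.mode!r} vs {impact_t2.mode!r}")
    if impact_t1.stressor_subset != impact_t2.stressor_subset:
        raise ValueError("stressor subset mismatch between periods")
    assert_aligned([impact_t1.raster, impact_t2.raster])
    diff = impact_t2.raster.values - impact_t1.raster.values
    return ChangeMap(
        raster=Raster(impact_t1.raster.grid, diff, "change"),
        stressor_subset=list(impact_t1.stressor_subset),
        mode=impact_t1.mode,
    )


def quartile_thresholds(raster: Raster) -> tuple[float, float]:
    """25th and 75th percentiles of the valid cells (linear interpolation)."""
    vals = raster.valid_values()
    if vals.size < 4:
        raise ValueError(f"need at least 4 valid cells for quartiles, got {vals.size}")
    low, high = np.percentile(vals, [25.0, 75.0])
    return float(low), float(high)


def _three_way(values: np.ndarray, low_cut: float, high_cut: float) -> np.ndarray:
    out = np.full(values.shape, np.nan)
    valid = np.isfinite(values)
    out[valid] = 1.0  # medium / no-change
    out[valid & (values < low_cut)] = 0.0
    out[valid & (values > high_cut)] = 2.0
    return out


def classify_raster(raster: Raster, low_cut: float, high_cut: float) -> Raster:
    """Three-way classification with strict cutoffs; codes 0/1/2 = below/middle/above."""
    return Raster(raster.grid, _three_way(raster.values, low_cut, high_cut), "category")


def classify(
    impact: ImpactMap,
    change: ChangeMap,
    thresholds: tuple[float, float, float, float] | None = None,
) -> ClassMap:
    """Quartile classification of impact level and change trend.

    Cutoffs default to the 25th/75th percentiles of each map's valid
    cells; pass ``thresholds`` (level_low, level_high, trend_low,
    trend_high) to re-apply recorded cutoffs.
    """
    assert_aligned([impact.raster, change.raster])
    if thresholds is None:
        l_lo, l_hi = quartile_thresholds(impact.raster)
        t_lo, t_hi = quartile_thresholds(change.raster)
    else:
        l_lo, l_hi, t_lo, t_hi = thresholds
    return ClassMap(
        level=classify_raster(impact.raster, l_lo, l_hi),
        trend=classify_raster(change.raster, t_lo, t_hi),
        level_low_cut=l_lo,
        level_high_cut=l_hi,
        trend_low_cut=t_lo,
        trend_high_cut=t_hi,
    )


def extreme_combinations(classmap: ClassMap) -> Raster:
    """Cross the extreme level and trend classes into five categories.

    high & increasing / high & decreasing / low & increasing /
    low & decreasing; every other valid cell is 'other'.
    """
    lev, tr = classmap.level.values, classmap.trend.values
    out = np.full(lev.shape, np.nan)
    valid = np.isfinite(lev) & np.isfinite(tr)
    out[valid] = COMBO_CODES["other"]
    out[valid & (lev == 2) & (tr == 2)] = COMBO_CODES["high_increasing"]
    out[valid & (lev == 2) & (tr == 0)] = COMBO_CODES["high_decreasing"]
    out[valid & (lev == 0) & (tr == 2)] = COMBO_CODES["low_increasing"]
    out[valid & (lev == 0) & (tr == 0)] = COMBO_CODES["low_decreasing"]
    return Raster(classmap.level.grid, out, "category")


def area_fractions(raster: Raster, predicate) -> float:
    """Fraction of valid cells satisfying ``predicate``.

    On an equal-area grid the cell fraction equals the area fraction.
    ``predicate`` is a vectorized callable on the value array, e.g.
    ``lambda v: v > 0``.
    """
    valid = raster.valid_mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid cells")
    hits = np.asarray(predicate(raster.values)) & valid
    return float(hits.sum()) / n
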