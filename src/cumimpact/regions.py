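"""Zonal summaries: per-region means of impact and change, and rankings.

Regions arrive as a single non-overlapping integer-labelled raster plus a
table mapping label to name (overlapping reporting schemes — exclusive
economic zones, ecoregions, large marine ecosystems, high-seas regions —
are handled by running the summary once per scheme). Because the grid is
equal-area, the unweighted mean of valid cells within a region equals the
area-weighted mean, so regions of very different sizes are directly
comparable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .change import ChangeMap
from .grid import Raster, assert_aligned
from .impact import ContributionMap, ImpactMap

__all__ = ["zonal_mean", "build_summary", "rank_regions"]


def zonal_mean(raster: Raster, regions: Raster) -> dict[int, float]:
    """Mean of valid cells per region label.

    Cells valid in the region raster but nodata in ``raster`` are skipped;
    regions with no valid cells are omitted with a warning.
    """
    assert_aligned([raster, regions])
    labels = regions.values
    both = raster.valid_mask & regions.valid_mask
    out: dict[int, float] = {}
    all_labels = np.unique(labels[regions.valid_mask]).astype(int)
    lab = labels[both].astype(int)
    vals = raster.values[both]
    sums = np.bincount(lab, weights=vals, minlength=all_labels.max() + 1 if all_labels.size else 1)
    counts = np.bincount(lab, minlength=all_labels.max() + 1 if all_labels.size else 1)
    for r in all_labels:
        if counts[r] == 0:
            warnings.warn(f"region {r} has no valid cells in {raster.semantics} raster; omitted", stacklevel=2)
            continue
        out[int(r)] = float(sums[r] / counts[r])
    return out


def _zonal_counts(mask_raster: Raster, regions: Raster) -> dict[int, int]:
    both = mask_raster.valid_mask & regions.valid_mask
    lab = regions.values[both].astype(int)
    out: dict[int, int] = {}
    for r, n in zip(*np.unique(lab, return_counts=True)):
        out[int(r)] = int(n)
    return out


def build_summary(
    impact: ImpactMap,
    change: ChangeMap | None,
    contributions: list[ContributionMap],
    regions: Raster,
    region_table: pd.DataFrame,
    change_contributions: list[ContributionMap] | None = None,
) -> pd.DataFrame:
    """One row per region: cell counts, cumulative and per-stressor means.

    Columns: ``region_id``, ``name``, ``n_cells``, ``mean_impact``, one
    ``impact_<stressor>`` column per contribution map, and — when a change
    map is supplied — ``mean_change``, ``fraction_increasing`` and
    ``change_<stressor>`` columns. Rows are sorted by descending
    ``mean_impact`` (ties by region_id). Per-stressor impact means sum to
    the cumulative mean per region (additivity of contributions).
    """
    contrib_ids = [c.stressor_id for c in contributions]
    missing = set(contrib_ids) - set(impact.stressor_subset)
    if missing:
        raise ValueError(f"contributions not in the impact stressor subset: {sorted(missing)}")
    names = region_table.set_index("region_id")["name"]
    imp_means = zonal_mean(impact.raster, regions)
    counts = _zonal_counts(impact.raster, regions)
    rows = []
    for rid, m in imp_means.items():
        rows.append(
            {
                "region_id": rid,
                "name": names.get(rid, f"region_{rid}"),
                "n_cells": counts.get(rid, 0),
                "mean_impact": m,
            }
        )
    df = pd.DataFrame(rows).set_index("region_id")
    for c in contributions:
        means = zonal_mean(c.raster, regions)
        df[f"impact_{c.stressor_id}"] = pd.Series(means)
    if change is not None:
        ch_means = zonal_mean(change.raster, regions)
        df["mean_change"] = pd.Series(ch_means)
        frac = {}
        both = change.raster.valid_mask & regions.valid_mask
        lab = regions.values[both].astype(int)
        pos = (change.raster.values[both] > 0).astype(float)
        for r in np.unique(lab):
            sel = lab == r
            frac[int(r)] = float(pos[sel].mean())
        df["fraction_increasing"] = pd.Series(frac)
        for c in change_contributions or []:
            means = zonal_mean(c.raster, regions)
            df[f"change_{c.stressor_id}"] = pd.Series(means)
    df = df.sort_values(["mean_impact", "region_id"], ascending=[False, True]).reset_index()
    return df


def rank_regions(summary: pd.DataFrame, column: str, direction: str = "desc") -> list[int]:
    """Region ids ordered by ``column``; ties broken by region_id (ascending)."""
    if column not in summary.columns:
        raise KeyError(f"unknown column {column!r}")
    if direction not in ("asc", "desc"):
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
    df = summary.sort_values(
        [column, "region_id"], ascending=[direction == "asc", True], kind="stable"
    )
    return df["region_id"].astype(int).tolist()
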