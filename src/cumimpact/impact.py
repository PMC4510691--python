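"""The cumulative impact model.

Per pixel p, each habitat i present there receives the vulnerability-
weighted sum of normalized stressor intensities,

    s_i(p) = sum_j mu_ij * D_j(p),

and the cumulative impact I_C(p) averages these per-habitat scores over
the habitats present (``mode='mean'``, the current method) or sums them
(``mode='sum'``, the legacy method that over-counts where habitats
overlap vertically). On pixels hosting exactly one habitat the two modes
coincide. Pixels where no habitat is present are nodata — impact over no
ecosystem is undefined, and reporting zero there would bias regional
means. The model is strictly additive across stressors: the per-stressor
contribution maps of :func:`stressor_contributions` sum cellwise to the
cumulative map.

:func:`impact_oracle` is a literal triple loop over (cell, habitat,
stressor) kept deliberately naive; it exists to cross-check the
vectorized path in tests and refuses grids larger than 64 x 64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Raster, assert_aligned
from .layers import HabitatLayer, NormalizedLayer
from .vulnerability import VulnerabilityMatrix

__all__ = [
    "ImpactMap",
    "ContributionMap",
    "cumulative_impact",
    "stressor_contributions",
    "impact_oracle",
]

_MODES = ("mean", "sum")


@dataclass
class ImpactMap:
    raster: Raster
    mode: str
    stressor_subset: list[str]
    period: str


@dataclass
class ContributionMap:
    stressor_id: str
    raster: Raster
    mode: str
    period: str


def _check_inputs(
    stressors: list[NormalizedLayer],
    habitats: list[HabitatLayer],
    weights: VulnerabilityMatrix,
    mode: str,
) -> str:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if not stressors:
        raise ValueError("at least one stressor layer required")
    if not habitats:
        raise ValueError("at least one habitat layer required")
    periods = {s.period for s in stressors}
    if len(periods) > 1:
        raise ValueError(f"stressor layers mix periods: {sorted(periods)}")
    unknown_s = [s.stressor_id for s in stressors if s.stressor_id not in weights.stressor_ids]
    if unknown_s:
        raise KeyError(f"stressors missing from weight matrix: {unknown_s}")
    unknown_h = [h.habitat_id for h in habitats if h.habitat_id not in weights.habitat_ids]
    if unknown_h:
        raise KeyError(f"habitats missing from weight matrix: {unknown_h}")
    assert_aligned([s.raster for s in stressors] + [h.raster for h in habitats])
    return next(iter(periods))


def cumulative_impact(
    stressors: list[NormalizedLayer],
    habitats: list[HabitatLayer],
    weights: VulnerabilityMatrix,
    mode: str = "mean",
) -> ImpactMap:
    """Vectorized per-pixel cumulative impact.

    A cell is valid iff every stressor layer and every habitat layer holds
    data there and at least one habitat is present; elsewhere the output
    is nodata.
    """
    period = _check_inputs(stressors, habitats, weights, mode)
    grid = stressors[0].raster.grid
    sub = weights.subset(
        habitat_ids=[h.habitat_id for h in habitats],
        stressor_ids=[s.stressor_id for s in stressors],
    )
    mu = sub.weights.to_numpy()  # (m habitats, n stressors)

    d = np.stack([s.raster.values for s in stressors])  # (n, R, C)
    e = np.stack([h.raster.values for h in habitats])  # (m, R, C)
    valid = np.isfinite(d).all(axis=0) & np.isfinite(e).all(axis=0)

    d0 = np.where(np.isfinite(d), d, 0.0)
    e0 = np.where(np.isfinite(e), e, 0.0)
    # per-habitat scores s_i = sum_j mu_ij D_j, then weight by presence
    s_hab = np.tensordot(mu, d0, axes=([1], [0]))  # (m, R, C)
    num = np.einsum("mrc,mrc->rc", e0, s_hab)
    n_present = e0.sum(axis=0)
    valid &= n_present > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num / n_present if mode == "mean" else num
    out = np.where(valid, vals, np.nan)
    # guard tiny negative round-off on all-zero inputs
    out = np.where(np.isfinite(out) & (out < 0) & (out > -1e-12), 0.0, out)
    return ImpactMap(
        raster=Raster(grid, out, "impact"),
        mode=mode,
        stressor_subset=[s.stressor_id for s in stressors],
        period=period,
    )


def stressor_contributions(
    stressors: list[NormalizedLayer],
    habitats: list[HabitatLayer],
    weights: VulnerabilityMatrix,
    mode: str = "mean",
) -> list[ContributionMap]:
    """Per-stressor impact decomposition.

    Contribution j is the cumulative impact recomputed with only stressor
    j; because the model is additive, contributions sum cellwise to the
    full cumulative map. Validity masks match the full map: a cell nodata
    in any stressor is nodata in every contribution.
    """
    full = cumulative_impact(stressors, habitats, weights, mode)
    valid = full.raster.valid_mask
    out = []
    for s in stressors:
        single = cumulative_impact([s], habitats, weights, mode)
        vals = np.where(valid, single.raster.values, np.nan)
        out.append(
            ContributionMap(
                stressor_id=s.stressor_id,
                raster=Raster(full.raster.grid, vals, "impact"),
                mode=mode,
                period=full.period,
            )
        )
    return out


def impact_oracle(
    stressors: list[NormalizedLayer],
    habitats: list[HabitatLayer],
    weights: VulnerabilityMatrix,
    mode: str = "mean",
) -> ImpactMap:
    """Reference implementation: explicit loops over the model definition.

    Small grids only (<= 64 x 64); intended exclusively for tests.
    """
    period = _check_inputs(stressors, habitats, weights, mode)
    grid = stressors[0].raster.grid
    if grid.n_rows > 64 or grid.n_cols > 64:
        raise ValueError(f"oracle limited to 64x64 grids, got {grid.shape}")
    out = np.full(grid.shape, np.nan)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            ok = all(np.isfinite(s.raster.values[r, c]) for s in stressors) and all(
                np.isfinite(h.raster.values[r, c]) for h in habitats
            )
            if not ok:
                continue
            present = [h for h in habitats if h.raster.values[r, c] == 1]
            if not present:
                continue
            scores = []
            for h in present:
                s_i = 0.0
                for s in stressors:
                    s_i += weights.weight(h.habitat_id, s.stressor_id) * s.raster.values[r, c]
                scores.append(s_i)
            out[r, c] = sum(scores) / len(scores) if mode == "mean" else sum(scores)
    return ImpactMap(
        raster=Raster(grid, out, "impact"),
        mode=mode,
        stressor_subset=[s.stressor_id for s in stressors],
        period=period,
    )
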