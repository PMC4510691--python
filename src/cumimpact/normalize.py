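"""Stressor normalization: log transform, joint two-period rescaling,
single-period (legacy) rescaling and coarse-to-fine block spreading.

Raw stressor layers arrive in arbitrary non-negative units. Each layer is
log(x+1)-transformed (binary layers excepted — a structure either exists
or it does not) to damp extreme right-tail outliers, then divided by the
maximum transformed value observed across *both* time periods so the two
periods share one reference point and scores are comparable through time.
The resulting D_j lie in [0, 1].

After the joint rescale the result is provably invariant to the logarithm
base — log_b(x+1) / log_b(M+1) cancels the base — so natural log is used
and the choice is cosmetic (and tested as such).
"""

from __future__ import annotations

import warnings

import numpy as np

from .grid import Grid, Raster, assert_aligned
from .layers import NormalizedLayer, StressorLayer

__all__ = [
    "log_transform",
    "joint_rescale",
    "single_period_rescale",
    "apply_reference_max",
    "block_spread",
    "normalize_stressors",
]


def log_transform(layer: StressorLayer, base: float | None = None) -> Raster:
    """log(x+1) transform of a stressor layer; identity for binary layers.

    ``base`` defaults to the natural log; any base gives identical results
    after joint rescaling. Nodata propagates.
    """
    vals = layer.raster.values
    if layer.raster.n_valid and float(np.nanmin(vals)) < 0:
        raise ValueError(f"stressor {layer.stressor_id!r} has negative values")
    if layer.is_binary:
        return layer.raster.copy()
    out = np.log1p(vals)
    if base is not None:
        out = out / np.log(base)
    return Raster(layer.raster.grid, out, "intensity")


def _max_valid(raster: Raster) -> float:
    v = raster.valid_values()
    return float(v.max()) if v.size else 0.0


def joint_rescale(
    layer_t1: Raster,
    layer_t2: Raster,
    stressor_id: str = "",
) -> tuple[NormalizedLayer, NormalizedLayer]:
    """Divide both periods' transformed layers by their common maximum.

    The divisor M is the highest valid cell value across either period;
    when M > 0 at least one output cell equals exactly 1, and when M = 0
    (both layers all zero) both outputs are all-zero with
    ``reference_max = 0`` rather than a division error.
    """
    assert_aligned([layer_t1, layer_t2])
    m = max(_max_valid(layer_t1), _max_valid(layer_t2))
    out = []
    for period, layer in (("t1", layer_t1), ("t2", layer_t2)):
        scaled = layer.values / m if m > 0 else np.where(np.isfinite(layer.values), 0.0, np.nan)
        out.append(
            NormalizedLayer(
                stressor_id=stressor_id,
                period=period,
                raster=Raster(layer.grid, scaled, "normalized"),
                reference_max=m,
            )
        )
    return out[0], out[1]


def single_period_rescale(layer: Raster, stressor_id: str = "", period: str = "t1") -> NormalizedLayer:
    """Legacy mode: divide a layer by its own period maximum."""
    m = _max_valid(layer)
    scaled = layer.values / m if m > 0 else np.where(np.isfinite(layer.values), 0.0, np.nan)
    return NormalizedLayer(
        stressor_id=stressor_id,
        period=period,
        raster=Raster(layer.grid, scaled, "normalized"),
        reference_max=m,
    )


def apply_reference_max(layer: Raster, reference_max: float, stressor_id: str = "", period: str = "t1") -> NormalizedLayer:
    """Rescale a transformed layer by a previously recorded reference maximum.

    Values exceeding the reference (a later period surpassing the recorded
    joint maximum) are clipped to 1 with a warning — the alternative is
    redoing the rescaling across all years.
    """
    if reference_max < 0:
        raise ValueError("reference_max must be non-negative")
    if reference_max == 0:
        scaled = np.where(np.isfinite(layer.values), 0.0, np.nan)
    else:
        scaled = layer.values / reference_max
        over = np.isfinite(scaled) & (scaled > 1.0)
        if over.any():
            warnings.warn(
                f"{int(over.sum())} cell(s) exceed the recorded reference_max "
                f"({reference_max}); clipping to 1. Rescaling across all periods "
                "should be redone with an updated reference.",
                stacklevel=2,
            )
            scaled = np.clip(scaled, None, 1.0)
    return NormalizedLayer(
        stressor_id=stressor_id,
        period=period,
        raster=Raster(layer.grid, scaled, "normalized"),
        reference_max=reference_max,
    )


def block_spread(coarse: Raster, factor: int) -> Raster:
    """Evenly spread each coarse cell's value over a factor x factor block.

    The coarse value is copied unchanged to every fine cell it covers (the
    value is a density-like score, so spreading preserves the mean); the
    fine grid has factor-times the rows and columns and cell_size/factor.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return coarse.copy()
    g = coarse.grid
    fine_grid = Grid(
        n_rows=g.n_rows * factor,
        n_cols=g.n_cols * factor,
        cell_size=g.cell_size / factor,
        cell_area=g.cell_area / factor**2,
        origin_x=g.origin_x,
        origin_y=g.origin_y,
        crs_tag=g.crs_tag,
        nodata=g.nodata,
    )
    fine = np.kron(coarse.values, np.ones((factor, factor)))
    return Raster(fine_grid, fine, coarse.semantics)


def normalize_stressors(
    stressors: dict[str, list[StressorLayer]],
    mode: str = "joint",
) -> dict[str, list[NormalizedLayer]]:
    """Transform and rescale a two-period stressor stack.

    ``mode='joint'`` (default) divides each stressor by its two-period
    maximum; ``mode='single'`` reproduces the legacy per-period rescaling.
    """
    if mode not in ("joint", "single"):
        raise ValueError(f"mode must be 'joint' or 'single', got {mode!r}")
    t1, t2 = stressors["t1"], stressors["t2"]
    ids1 = [s.stressor_id for s in t1]
    ids2 = [s.stressor_id for s in t2]
    if ids1 != ids2:
        raise ValueError("period stacks list different stressors")
    out: dict[str, list[NormalizedLayer]] = {"t1": [], "t2": []}
    for s1, s2 in zip(t1, t2):
        r1, r2 = log_transform(s1), log_transform(s2)
        if mode == "joint":
            n1, n2 = joint_rescale(r1, r2, stressor_id=s1.stressor_id)
        else:
            n1 = single_period_rescale(r1, stressor_id=s1.stressor_id, period="t1")
            n2 = single_period_rescale(r2, stressor_id=s2.stressor_id, period="t2")
        out["t1"].append(n1)
        out["t2"].append(n2)
    return out
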