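"""Typed wrappers tying rasters to stressor / habitat identity.

Depth classes follow the vertical structure of the water column used in
cumulative impact assessment: a single well-mixed layer down to 60 m, a
separate surface-pelagic habitat below 60 m, and three distinct layers
(benthic, deep pelagic, surface pelagic) below 200 m.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grid import Raster, RasterValidationError

__all__ = [
    "StressorLayer",
    "NormalizedLayer",
    "HabitatLayer",
    "DEPTH_CLASSES",
    "SHALLOW_LIMIT_M",
    "DEEP_LIMIT_M",
]

#: Depth at which surface waters split off as a separate pelagic habitat.
SHALLOW_LIMIT_M = 60.0
#: Depth below which benthic, deep-pelagic and surface-pelagic layers coexist.
DEEP_LIMIT_M = 200.0

#: depth class -> (min_depth_exclusive, max_depth_inclusive_or_None) admissible band, metres below sea level
DEPTH_CLASSES = {
    "nearshore_mixed": (0.0, SHALLOW_LIMIT_M),
    "surface_pelagic": (SHALLOW_LIMIT_M, None),
    "deep_pelagic": (DEEP_LIMIT_M, None),
    "deep_benthic": (DEEP_LIMIT_M, None),
}


@dataclass
class StressorLayer:
    """Raw non-negative intensity raster for one stressor in one period."""

    stressor_id: str
    period: str  # "t1" or "t2"
    raster: Raster
    is_binary: bool = False
    comparable: bool = True

    def __post_init__(self) -> None:
        if self.period not in ("t1", "t2"):
            raise ValueError(f"period must be 't1' or 't2', got {self.period!r}")
        if self.raster.semantics != "intensity":
            raise RasterValidationError(
                f"stressor layer {self.stressor_id!r} requires intensity semantics, got {self.raster.semantics!r}"
            )
        if self.is_binary:
            vals = self.raster.valid_values()
            bad = (vals != 0) & (vals != 1)
            if bad.any():
                raise RasterValidationError(
                    f"binary stressor {self.stressor_id!r} has non-binary values"
                )


@dataclass
class NormalizedLayer:
    """A stressor layer rescaled to [0, 1] (the D_j of the impact model).

    ``reference_max`` is the transformed maximum used as divisor — the
    joint two-period maximum in the default mode — recorded even when the
    layer is all zeros so the normalization is auditable and re-appliable.
    """

    stressor_id: str
    period: str
    raster: Raster
    reference_max: float

    def __post_init__(self) -> None:
        if self.raster.semantics != "normalized":
            raise RasterValidationError(
                f"normalized layer {self.stressor_id!r} requires normalized semantics, got {self.raster.semantics!r}"
            )
        if self.reference_max < 0:
            raise ValueError("reference_max must be non-negative")


@dataclass
class HabitatLayer:
    """Binary presence raster for one habitat (the E_i of the impact model)."""

    habitat_id: str
    depth_class: str
    raster: Raster

    def __post_init__(self) -> None:
        if self.depth_class not in DEPTH_CLASSES:
            raise ValueError(
                f"unknown depth class {self.depth_class!r}; expected one of {sorted(DEPTH_CLASSES)}"
            )
        if self.raster.semantics != "presence":
            raise RasterValidationError(
                f"habitat layer {self.habitat_id!r} requires presence semantics, got {self.raster.semantics!r}"
            )
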