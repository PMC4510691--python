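"""Synthetic seascape generator.

Produces gridded inputs with the statistical structure the cumulative
impact analysis assumes, so every downstream stage is testable without any
real data: spatially autocorrelated non-negative stressor fields with
per-stressor temporal trends, a binary offshore-structures layer,
depth-stratified habitat stacks, a Voronoi region tessellation and a
vulnerability weight matrix carrying the designated derivation columns.

Autocorrelated fields are built by convolving white noise with an
isotropic Gaussian kernel of width ``smoothness`` and exponentiating the
result. The exponentiation yields log-normal-like positive fields with
heavy right tails, mimicking the outlier-dominated distributions of real
stressor data that motivate the log transform applied downstream.

Every generator is a pure function of (config, seed): the same
configuration yields bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import Grid, Raster
from .layers import DEPTH_CLASSES, HabitatLayer, StressorLayer

__all__ = [
    "SeascapeConfig",
    "STRESSOR_REGISTRY",
    "HABITAT_REGISTRY",
    "DEEP_HABITATS",
    "stressor_registry_frame",
    "habitat_registry_frame",
    "generate_bathymetry",
    "generate_stressors",
    "generate_habitats",
    "generate_regions",
    "generate_weight_matrix",
    "generate_seascape",
]

# ---------------------------------------------------------------------------
# Default registries: 19 stressors (12 comparable across periods, one binary)
# and 20 habitats across the four depth classes.
# ---------------------------------------------------------------------------

#: (stressor_id, category, is_binary, comparable, default trend t1 -> t2)
STRESSOR_REGISTRY: list[tuple[str, str, bool, bool, float]] = [
    ("demersal_destructive", "fishing", False, True, 0.85),
    ("demersal_nondestructive_high_bycatch", "fishing", False, True, 0.90),
    ("demersal_nondestructive_low_bycatch", "fishing", False, True, 0.90),
    ("pelagic_high_bycatch", "fishing", False, True, 0.85),
    ("pelagic_low_bycatch", "fishing", False, True, 0.90),
    ("sst_anomaly", "climate", False, True, 1.35),
    ("uv_radiation", "climate", False, True, 1.25),
    ("nutrient_input", "land_based", False, True, 1.20),
    ("organic_pollution", "land_based", False, True, 1.15),
    ("direct_human", "land_based", False, True, 1.10),
    ("shipping", "ocean_based", False, True, 1.10),
    ("benthic_structures", "ocean_based", True, True, 1.00),
    ("ocean_acidification", "climate", False, False, 1.30),
    ("sea_level_rise", "climate", False, False, 1.20),
    ("inorganic_pollution", "land_based", False, False, 1.00),
    ("light_pollution", "land_based", False, False, 1.10),
    ("artisanal_fishing", "fishing", False, False, 0.95),
    ("invasive_species", "ocean_based", False, False, 1.05),
    ("ocean_pollution", "ocean_based", False, False, 1.05),
]

#: (habitat_id, depth_class). The first habitat of the nearshore_mixed,
#: surface_pelagic and deep_pelagic classes covers its whole admissible
#: band, guaranteeing every ocean cell hosts at least one habitat while
#: cells in the 60-200 m band host exactly one (surface pelagic waters).
HABITAT_REGISTRY: list[tuple[str, str]] = [
    ("shallow_soft_benthic", "nearshore_mixed"),
    ("shallow_hard_benthic", "nearshore_mixed"),
    ("coral_reef", "nearshore_mixed"),
    ("seagrass", "nearshore_mixed"),
    ("mangrove", "nearshore_mixed"),
    ("salt_marsh", "nearshore_mixed"),
    ("rocky_reef", "nearshore_mixed"),
    ("kelp_forest", "nearshore_mixed"),
    ("rocky_intertidal", "nearshore_mixed"),
    ("beach", "nearshore_mixed"),
    ("mudflat", "nearshore_mixed"),
    ("suspension_feeder_reef", "nearshore_mixed"),
    ("surface_pelagic_waters", "surface_pelagic"),
    ("deep_pelagic_waters", "deep_pelagic"),
    ("deep_soft_benthic", "deep_benthic"),
    ("deep_hard_benthic", "deep_benthic"),
    ("seamount", "deep_benthic"),
    ("canyon", "deep_benthic"),
    ("deep_water_coral", "deep_benthic"),
    ("hydrothermal_vent", "deep_benthic"),
]

#: Habitats whose sea-level-rise vulnerability is zeroed: deep benthic and
#: pelagic water-column classes, where shoreline inundation has no meaning.
DEEP_HABITATS: tuple[str, ...] = tuple(
    h for h, cls in HABITAT_REGISTRY if cls in ("deep_benthic", "deep_pelagic")
)

#: Auxiliary weight columns carried by the raw (pre-derivation) matrix.
NUTRIENT_SOURCE_COLS = ("nutrient_oligotrophic", "nutrient_eutrophic")


def stressor_registry_frame() -> pd.DataFrame:
    return pd.DataFrame(
        STRESSOR_REGISTRY,
        columns=["stressor_id", "category", "is_binary", "comparable", "trend"],
    )


def habitat_registry_frame() -> pd.DataFrame:
    return pd.DataFrame(HABITAT_REGISTRY, columns=["habitat_id", "depth_class"])


@dataclass
class SeascapeConfig:
    """Knobs of the synthetic seascape.

    Defaults mirror the structure of the global assessment this pipeline
    emulates: 19 stressors of which 12 are comparable across the two
    periods, 20 habitats over four depth classes, one binary
    offshore-structures stressor, and climate stressors trending upward
    while most fishing stressors trend downward.
    """

    n_rows: int = 80
    n_cols: int = 80
    cell_size: float = 1000.0  # metres; cell_area = 1 km^2
    n_stressors: int = 19
    n_comparable: int = 12
    n_habitats: int = 20
    seed: int = 0
    smoothness: float = 6.0  # autocorrelation length, in cells
    trend_per_stressor: list[float] = field(default_factory=list)
    binary_stressor_ids: tuple[str, ...] = ("benthic_structures",)
    depth_range: tuple[float, float] = (-150.0, 3500.0)  # metres; <= 0 is land
    n_regions: int = 8
    noise_refresh: float = 0.15  # sigma of the fresh log-scale noise in period 2
    field_sigma: float = 1.0  # log-scale spread of stressor fields
    binary_prevalence: float = 0.05  # ocean fraction occupied by binary structures

    def __post_init__(self) -> None:
        if self.n_comparable > self.n_stressors:
            raise ValueError("n_comparable cannot exceed n_stressors")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")
        if self.n_habitats < 4:
            raise ValueError("need at least 4 habitats to populate all depth classes")
        ids = {s[0] for s in STRESSOR_REGISTRY[: self.n_stressors]}
        unknown = set(self.binary_stressor_ids) - ids
        if unknown and self.n_stressors == len(STRESSOR_REGISTRY):
            raise ValueError(f"binary_stressor_ids not in registry: {sorted(unknown)}")
        if not self.trend_per_stressor:
            self.trend_per_stressor = [s[4] for s in STRESSOR_REGISTRY[: self.n_stressors]]
        if len(self.trend_per_stressor) != self.n_stressors:
            raise ValueError("trend_per_stressor length must equal n_stressors")
        if any(t < 0 for t in self.trend_per_stressor):
            raise ValueError("trend multipliers must be non-negative")

    @property
    def grid(self) -> Grid:
        return Grid(n_rows=self.n_rows, n_cols=self.n_cols, cell_size=self.cell_size)

    def stressor_table(self) -> pd.DataFrame:
        """Registry rows in effect, with comparability re-flagged so exactly
        ``n_comparable`` of the first ``n_stressors`` stressors are comparable."""
        df = stressor_registry_frame().head(self.n_stressors).copy()
        order = np.argsort(~df["comparable"].to_numpy(), kind="stable")
        flags = np.zeros(len(df), dtype=bool)
        flags[order[: self.n_comparable]] = True
        df["comparable"] = flags
        df["is_binary"] = df["stressor_id"].isin(self.binary_stressor_ids)
        df["trend"] = list(self.trend_per_stressor)
        return df

    def habitat_table(self) -> pd.DataFrame:
        return habitat_registry_frame().head(self.n_habitats)


# ---------------------------------------------------------------------------
# Field helpers
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially autocorrelated field."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=smoothness, mode="wrap")
    sd = z.std()
    if sd == 0:  # pathological tiny grid
        return z
    return (z - z.mean()) / sd


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_bathymetry(config: SeascapeConfig) -> Raster:
    """Smooth depth field spanning ``depth_range``.

    A monotone west-east gradient plus autocorrelated noise, affinely
    rescaled to span the requested range exactly, so every depth band the
    range covers (land <= 0 m, nearshore <= 60 m, 60-200 m, > 200 m) is
    guaranteed non-empty.
    """
    lo, hi = config.depth_range
    if lo >= hi:
        raise ValueError(f"degenerate depth_range: min {lo} >= max {hi}")
    grid = config.grid
    rng = _child_rng(config.seed, 0)
    cols = np.linspace(0.0, 1.0, grid.n_cols)[np.newaxis, :]
    gradient = np.broadcast_to(cols, grid.shape)
    noise = _smooth_noise(rng, grid.shape, config.smoothness)
    raw = gradient + 0.15 * noise
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    depth = lo + raw * (hi - lo)
    return Raster(grid, depth, "depth")


def ocean_mask(bathymetry: Raster) -> np.ndarray:
    """Cells with positive depth; everything else is land."""
    return bathymetry.values > 0


def generate_stressors(
    config: SeascapeConfig, bathymetry: Raster
) -> dict[str, list[StressorLayer]]:
    """Two period-indexed stressor stacks, ``{"t1": [...], "t2": [...]}``.

    Continuous stressors are log-normal-like autocorrelated fields; period
    2 equals period 1 scaled by the stressor's trend multiplier and (when
    ``noise_refresh > 0``) perturbed by fresh multiplicative noise. Binary
    stressors are thresholded to {0, 1} with period-2 prevalence scaled by
    the trend. Land cells are nodata.
    """
    if bathymetry.grid != config.grid:
        raise ValueError("bathymetry grid does not match config grid")
    table = config.stressor_table()
    ocean = ocean_mask(bathymetry)
    grid = config.grid
    out: dict[str, list[StressorLayer]] = {"t1": [], "t2": []}
    for k, row in enumerate(table.itertuples(index=False)):
        rng = _child_rng(config.seed, 1, k)
        base_noise = _smooth_noise(rng, grid.shape, config.smoothness)
        trend = float(row.trend)
        if row.is_binary:
            # occupancy from the top tail of the smooth field; trend scales prevalence
            p1 = config.binary_prevalence
            p2 = min(1.0, trend * p1)
            vals = base_noise[ocean]
            q1 = np.quantile(vals, 1.0 - p1) if p1 > 0 else np.inf
            q2 = np.quantile(vals, 1.0 - p2) if p2 > 0 else np.inf
            f1 = (base_noise > q1).astype(np.float64)
            f2 = (base_noise > q2).astype(np.float64)
        else:
            f1 = np.exp(config.field_sigma * base_noise)
            if config.noise_refresh > 0:
                fresh = _smooth_noise(rng, grid.shape, config.smoothness)
                f2 = trend * f1 * np.exp(config.noise_refresh * fresh)
            else:
                f2 = trend * f1
        for period, f in (("t1", f1), ("t2", f2)):
            v = f.copy()
            v[~ocean] = np.nan
            out[period].append(
                StressorLayer(
                    stressor_id=row.stressor_id,
                    period=period,
                    raster=Raster(grid, v, "intensity"),
                    is_binary=bool(row.is_binary),
                    comparable=bool(row.comparable),
                )
            )
    return out


def generate_habitats(config: SeascapeConfig, bathymetry: Raster) -> list[HabitatLayer]:
    """Depth-stratified binary habitat stack.

    Presence is confined to each habitat's admissible depth band. The
    first habitat listed for the nearshore-mixed, surface-pelagic and
    deep-pelagic classes covers its entire band so that no ocean cell is
    habitat-free; the remaining habitats are patchy (present where an
    autocorrelated field exceeds its 60th percentile within the band).
    """
    if bathymetry.grid != config.grid:
        raise ValueError("bathymetry grid does not match config grid")
    table = config.habitat_table()
    depth = bathymetry.values
    ocean = ocean_mask(bathymetry)
    grid = config.grid
    seen_class: set[str] = set()
    layers: list[HabitatLayer] = []
    for k, row in enumerate(table.itertuples(index=False)):
        lo, hi = DEPTH_CLASSES[row.depth_class]
        band = ocean & (depth > lo)
        if hi is not None:
            band &= depth <= hi
        full_cover = row.depth_class not in seen_class and row.depth_class != "deep_benthic"
        seen_class.add(row.depth_class)
        if full_cover:
            presence = band.astype(np.float64)
        else:
            rng = _child_rng(config.seed, 2, k)
            f = _smooth_noise(rng, grid.shape, config.smoothness)
            cut = np.quantile(f[band], 0.6) if band.any() else np.inf
            presence = (band & (f > cut)).astype(np.float64)
        presence[~ocean] = np.nan
        layers.append(
            HabitatLayer(
                habitat_id=row.habitat_id,
                depth_class=row.depth_class,
                raster=Raster(grid, presence, "presence"),
            )
        )
    return layers


def generate_regions(
    config: SeascapeConfig, bathymetry: Raster | None = None
) -> tuple[Raster, pd.DataFrame]:
    """Voronoi tessellation of the grid into ``n_regions`` labelled zones.

    Labels are 1..n_regions; land cells (when a bathymetry is supplied)
    are nodata. Returns the label raster and a table mapping label to a
    synthetic region name.
    """
    grid = config.grid
    n_cells = grid.n_rows * grid.n_cols
    if config.n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if config.n_regions > n_cells:
        raise ValueError(f"n_regions ({config.n_regions}) exceeds cell count ({n_cells})")
    rng = _child_rng(config.seed, 3)
    idx = rng.choice(n_cells, size=config.n_regions, replace=False)
    seed_rc = np.column_stack(np.unravel_index(idx, grid.shape)).astype(np.float64)
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    d2 = (rr[..., None] - seed_rc[:, 0]) ** 2 + (cc[..., None] - seed_rc[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1).astype(np.float64) + 1.0
    if bathymetry is not None:
        labels[~ocean_mask(bathymetry)] = np.nan
    table = pd.DataFrame(
        {
            "region_id": np.arange(1, config.n_regions + 1),
            "name": [f"region_{i:02d}" for i in range(1, config.n_regions + 1)],
        }
    )
    return Raster(grid, labels, "region_label"), table


def generate_weight_matrix(config: SeascapeConfig, raw: bool = False):
    """Synthetic habitat x stressor vulnerability weight matrix.

    Weights are drawn uniformly in [0, 4]. With ``raw=True`` the matrix is
    returned pre-derivation: it carries the oligotrophic and eutrophic
    nutrient source columns, and the low-bycatch, nutrient-input and
    sea-level-rise columns still hold their undervived draws. The default
    (``raw=False``) applies the standard derivation pipeline — low-bycatch
    = 0.75 x high-bycatch, nutrient input = mean of the two source
    columns, sea-level-rise zeroed for deep habitats — and drops the
    source columns, yielding exactly ``n_habitats x n_stressors`` weights.
    """
    from .vulnerability import VulnerabilityMatrix, apply_default_derivations

    table = config.stressor_table()
    habitats = config.habitat_table()["habitat_id"].tolist()
    stressor_ids = table["stressor_id"].tolist()
    cols = stressor_ids + [c for c in NUTRIENT_SOURCE_COLS]
    rng = _child_rng(config.seed, 4)
    weights = rng.uniform(0.0, 4.0, size=(len(habitats), len(cols)))
    mat = VulnerabilityMatrix.from_arrays(habitats, cols, weights)
    if raw:
        return mat
    return apply_default_derivations(mat, stressor_ids=stressor_ids)


@dataclass
class Seascape:
    """Bundle of all synthetic inputs for one configuration."""

    config: SeascapeConfig
    bathymetry: Raster
    stressors: dict[str, list[StressorLayer]]
    habitats: list[HabitatLayer]
    regions: Raster
    region_table: pd.DataFrame
    weights: "object"  # VulnerabilityMatrix


def generate_seascape(config: SeascapeConfig) -> Seascape:
    """Generate the complete synthetic input set for ``config``."""
    bathy = generate_bathymetry(config)
    stressors = generate_stressors(config, bathy)
    habitats = generate_habitats(config, bathy)
    regions, region_table = generate_regions(config, bathy)
    weights = generate_weight_matrix(config)
    return Seascape(config, bathy, stressors, habitats, regions, region_table, weights)
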