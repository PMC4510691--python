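# Methods

## Model and assumptions

The package scores cumulative human impact per pixel as the average, over
the habitats present in that pixel, of vulnerability-weighted sums of
normalized stressor intensities. The model is strictly linear and
additive: no stressor interactions (synergy or antagonism) and no
threshold responses are represented — contributions of individual
stressors therefore decompose the cumulative map exactly, which is both a
reporting feature and a testable invariant. Habitat extent is static:
both periods share one habitat stack, so all temporal change in scores is
attributable to change in stressor intensities.

The averaging denominator is the number of habitats *present in the
pixel*, not the global habitat count; dividing by the global count would
make a pixel's score depend on habitats that do not occur there. Pixels
that are water but host no habitat are nodata rather than zero — a zero
would silently dilute regional means with cells where impact is
undefined.

A `sum` aggregation mode (totalling instead of averaging per-habitat
scores) is retained for comparison with the older approach it replaces.
Where exactly one habitat is present the two modes are identical; the
mean is never larger than the sum. Both facts are asserted in the test
suite.

## Normalization

Each non-binary stressor layer is log(x+1)-transformed and then divided
by the maximum transformed value over the valid ocean cells of **both**
periods (joint rescaling), so the periods are measured against a common
reference and scores are comparable through time. Binary structure layers
skip the transform — presence is already 0/1, and dividing by a maximum
of 1 is the identity. The log base is immaterial after rescaling
(log_b(x+1)/log_b(M+1) cancels b); natural log is used and the invariance
is verified numerically across bases e, 10 and 2 at 1e-12. The maximum is
taken over valid ocean cells only, since land is outside the analysis
domain. A `single` mode normalizes each period to its own maximum,
reproducing the legacy behaviour for method comparisons. When a stored
reference maximum is re-applied to data that exceed it (a later period
surpassing the recorded joint maximum), values are clipped to 1 with a
warning — the honest alternative is re-running the joint rescale over all
periods, and the warning says so.

Coarse-resolution inputs are brought to the analysis resolution by block
spreading: the coarse value is copied unchanged to every fine cell it
covers (value-as-density convention), which preserves the spatial mean.

## Vulnerability weights

Weights μ_ij ≥ 0 live in a habitat × stressor matrix with per-cell
provenance tags. Three derivation rules adapt a generic weight set to the
mapped stressor layers: low-bycatch demersal nondestructive fishing
weights are 0.75 × the high-bycatch weights; nutrient-input weights are
the arithmetic mean of oligotrophic and eutrophic water-quality weights;
sea-level-rise weights are zeroed for a configurable set of deep
habitats (default: the deep-benthic and deep-pelagic registry classes),
where shoreline inundation is meaningless. Each rule is pure, idempotent
and touches only its target column; the zeroing reports how many cells it
actually changed.

The synthetic weight generator has to satisfy two contracts at once: the
final matrix must be exactly habitats × stressors, while the derivation
rules need oligotrophic/eutrophic source columns that are not stressors.
It therefore produces either a *raw* matrix carrying the two auxiliary
source columns (for exercising the derivation pipeline) or, by default,
the post-derivation matrix restricted to the registry's stressor columns.

## Classification

Impact level and change trend are each classed by the 25th and 75th
percentiles of the map's own valid-cell distribution, with linear
interpolation between order statistics (the dominant percentile
convention; recorded in the output so alternatives are auditable) and
strict inequalities on both sides, so a value equal to a cutoff falls in
the middle class. "No change" is thus the middle 50% band of the change
distribution, not literally zero. On tie-free data each extreme class
holds exactly 25% of cells. Thresholds are computed over all valid ocean
cells of the full map, not per region, and on an equal-area grid the raw
and area-weighted pixel distributions coincide. In the orchestrated
pipeline both the level and the trend quartiles are taken on the
comparable-subset maps — the same score scale the change map uses — so
the two classifications describe one consistent quantity.

## Synthetic seascape

The generator emulates the *structure* of real multi-stressor data, not
any particular region: spatially autocorrelated fields are white noise
convolved with an isotropic Gaussian kernel of width `smoothness`
(default 6 cells) and exponentiated, giving log-normal-like positive
fields whose heavy right tails mimic the outlier problem the log
transform addresses. Bathymetry is a monotone gradient plus
autocorrelated noise rescaled to span `depth_range` (default −150 m to
3500 m), guaranteeing land (depth ≤ 0, masked everywhere downstream) and
all three water-column bands (≤ 60 m single well-mixed layer; > 60 m
separate surface-pelagic habitat; > 200 m benthic, deep-pelagic and
surface-pelagic layers). Period-2 stressors are period-1 scaled by a
per-stressor trend multiplier times fresh multiplicative log-scale noise
(`noise_refresh`, default 0.15; zero makes the per-cell ratio exactly the
trend). The binary structures layer is the top tail of a smooth field at
`binary_prevalence` (default 5% of ocean), with period-2 prevalence
scaled by the trend. Regions are a Voronoi tessellation of seeded random
points.

The default registry fixes the structural counts the analysis design
assumes — 19 stressors (five commercial-fishing classes, climate,
land-based and ocean-based classes, one binary structures layer), 20
habitats across the four depth classes, 12 stressors flagged comparable
across periods. Default trends put climate stressors up (~1.25–1.35),
most fishing down (~0.85–0.9) and land-based stressors mildly up, echoing
the qualitative pattern of recent global change; the magnitudes are
round numbers chosen once, not fitted to anything. One habitat per
pelagic/nearshore depth class covers its whole admissible band so no
ocean cell is habitat-free, and the 60–200 m band (surface pelagic only)
guarantees single-habitat pixels for the mean/sum equivalence check.

What the generator does **not** emulate: realistic coastline geometry,
coast-distance decay of land-based stressors, any real stressor's units
or magnitudes, sea-ice dynamics, and inter-stressor spatial correlation.
Passing tests therefore demonstrate the correctness of the scoring,
normalization, classification and summary machinery under realistic
*statistical* structure — they say nothing about any real region's impact
values.

## Numerical choices

All rasters are float64 with NaN as the in-memory nodata (a finite
sentinel plus a GDAL nodata tag on disk); nodata propagates through every
operation, and any misalignment of grid metadata is rejected up front
naming the first differing field. The vectorized impact engine is checked
cellwise against a deliberately naive triple-loop oracle at 1e-10 on
random instances with arbitrary presence/nodata patterns; contribution
additivity is held to 1e-9. Equal-weight accumulations use double
precision throughout. Degenerate inputs are defined, not errors: an
all-zero stressor pair rescales to all zeros with reference_max 0; a
constant raster has equal quartile cutoffs (everything classes as
medium); an empty deep-habitat set leaves the weight matrix unchanged.
Region means use per-column valid masks: a cell valid for impact but
nodata for change counts toward the impact mean only. Ranking ties break
by region id for stable, reproducible tables.

Problem sizes: tests run on grids between 1×1 and 100×100 and the default
demonstration seascape is 80×80 with the full 19-stressor/20-habitat
registry; the orchestrated pipeline caps grids at 2000×2000 to keep the
single-process, in-memory design honest. Determinism is end-to-end: every
random draw derives from one integer seed via independent child
generators, and the pipeline manifest records SHA-256 checksums so
bitwise reproducibility is checkable.

## Known limitations

Linear additive scoring ignores documented nonlinear and interactive
ecosystem responses; habitat extent is static between periods; the
equal-area contract is carried by metadata, with no reprojection or
resampling between coordinate systems; regions must be non-overlapping
within one label raster (overlapping reporting schemes are run as
separate summaries); and the synthetic seascape's realism limits are
listed above.
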