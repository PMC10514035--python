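# Methods

## Model and assumptions

GCCM treats two co-registered spatial variables X and Y as observation
functions of a single underlying dynamical system, observed once in
space rather than repeatedly in time.  By the generalized embedding
theorem, a set of observation functions of a smooth dynamical system can
reconstruct its attractor up to a one-to-one map.  Here the observation
functions of a focal unit are its own value and summaries of its spatial
lags, so each unit contributes one point of a reconstructed "shadow
manifold" per variable.  If X drives Y, the full system state — including
X's — is recoverable from Y's observations, so the cross-map from Y's
manifold to X's values ("Y xmap X") succeeds and improves as the library
of candidate neighbor states densifies; the reverse map has no such
guarantee.  The operational criterion is therefore *convergence*:
cross-map skill that rises with library size and is significant at the
largest library.

The method assumes the fields arise from coupled dynamics with enough
nonlinearity that state-space proximity is informative.  It does not
handle purely stochastic linear fields (no state space to reconstruct),
and it cannot by itself distinguish a weak feedback causation from the
"mirroring" of a strongly enslaved effect variable; bidirectional verdicts
carry an explicit caveat for this reason.

## Embedding and distances

- **Embedding dimension L** (default 4; benchmark protocol 5): the state
  holds the focal value plus L−1 ring summaries.  Units whose rings are
  incomplete (raster borders, per-direction mode) or empty (polygon
  components) yield invalid states that never enter neighbor searches.
  `select_embedding_dimension` sweeps candidate L values and keeps the
  one maximizing full-library skill, ties toward the smaller L.
- **Ring summaries**: rasters default to the anisotropy-aware
  per-direction vector (each ring compared direction by direction, in a
  fixed row-major offset order shared by all cells); an isotropic
  ring-mean alternative is available and is the only choice for polygons,
  whose ring memberships vary in size.  In ring-mean mode a raster and
  its queen-contiguity polygon twin produce identical embeddings, which
  the tests exploit as a cross-check.
- **State distance**: the mean of the focal absolute difference and one
  per-ring term (per-direction: mean absolute difference over the
  directions both states observe; ring-mean: absolute difference of the
  ring means).  With complete states this is a weighted L1 distance and
  is computed with a vectorized city-block kernel; states with tolerated
  missing directions fall back to the pairwise definition.
- **Neighbor weights**: exponential in distance relative to the nearest
  neighbor, normalized to sum to one.  When the nearest distance is below
  1e−12 the exact matches take all the weight — the limit of the
  exponential rule, avoiding a 0/0.
- **Ties** at the (L+1)-th neighbor break toward the smaller unit index
  (stable sort over libraries stored in ascending index order), making
  every prediction deterministic.

## Libraries, aggregation, significance

Raster libraries are side×side windows slid at stride max(1, side/2);
polygon libraries are seeded random unit subsets, with the full support
used verbatim when the size equals the unit count.  At most
`max_windows_per_size` libraries are kept per size (seeded uniform
subsample).  Per size, the curve records the unweighted mean of defined
skills across libraries and the median prediction count n; p-values and
Fisher-z confidence intervals are computed from that aggregated (ρ, n).
Predictions default to every valid unit of the full support, so n is the
count of predicted units, not the library size.

An optional **exclusion radius** r removes library states within the
first r lag rings of the focal unit (Chebyshev distance on rasters, graph
distance on polygons) from that unit's neighbor candidates — the spatial
analogue of the Theiler window in temporal embedding.  Neighboring units
share most of their ring cells, so without exclusion the nearest
state-space neighbors are trivially the nearest spatial neighbors and
spatial autocorrelation masquerades as dynamical proximity.  Default 0
(the focal unit itself is always excluded); the benchmark protocol uses
r = L−1, the embedding's own spatial extent.

The convergence rule is: final ρ above the initial ρ, and one-sided
p < α at the largest library.  `trend_alpha` optionally tightens this
with a one-sided Mann–Kendall test (Kendall's τ of ρ against library
size), so a single lucky endpoint cannot establish convergence; the
benchmark protocol uses trend_alpha = 0.05.

## Linearity removal

Cross-mapping targets nonlinear structure; a strong linear correlation
between the pair lets the trivial linear map dominate both directions and
hide the asymmetry.  When enabled, the designated effect variable is
replaced by its OLS residual on the cause (missing where either input is
missing).  Residualizing **both** variables on each other is deliberately
not done: x − c·y is a function of y by construction, so two-sided
residualization injects each variable's signal into the other's embedding
and empirically inverts the recovered asymmetry on the synthetic
benchmark.  The noise-robustness experiment skips detrending entirely,
because the injected noise is scaled per observation (η ∝ |y|) and its
amplitude pattern would survive residualization as spurious
cause-correlated signal.

## Synthetic systems

`simulate_coupled_lattice` runs two logistic maps on a grid, coupled
X→Y with strength `beta_xy` inside the growth term, mixed spatially by
diffusive Moore-neighborhood averaging (weight 0.2), with additive
Gaussian observation noise (sd 0.02) and clipping to [0, 1]; the final
sweep is the cross-sectional snapshot.  Growth rates are r_x = 3.55 and
r_y = 4.0: the driver sits at the edge of chaos and yields a spatially
coherent field, while the fully chaotic response keeps expansive
conditional dynamics and is not enslaved by the β = 0.3 forcing.  This
regime choice is load-bearing — with a periodic response map (e.g. the
textbook r = 3.5) the same coupling produces generalized synchronization:
the fields correlate at ~0.8, both cross-maps saturate, and the system
exemplifies the strongly-coupled/mirroring case rather than a recoverable
unidirectional one.  Burn-in is 40 sweeps; the seed fixes everything.

`simulate_independent_fields` provides the null (white or
Gaussian-smoothed independent fields from disjoint seed streams);
`simulate_polygon_system` runs the same coupled dynamics on a
jittered-grid polygon tiling whose shared-vertex jitter preserves the
underlying queen contiguity, exercising the vector-data path end to end.

What the generator does **not** emulate: real-data marginal
distributions, anisotropic or long-range spatial dependence,
heteroscedastic observation error, and confounding by a third variable.
Passing the synthetic benchmarks therefore shows the machinery recovers
known coupling under the stated dynamics, not that any particular field
pair in nature will behave as cleanly.

## Benchmark protocol and problem sizes

The reference experiments in `gccm.benchmark` fix one analysis protocol:
effect detrended on cause, L = 5, exclusion radius 4, window sides
5:40:5 with at most 3 windows per size, Mann–Kendall-tightened
convergence at level 0.05.  Problem sizes are desk-scale by design:
40×40 lattices (1024 valid states) for direction recovery and noise
degradation with 10 realizations each, 100 pairs of 20×20 grids for null
calibration, and the full-support library only for the noise curve, where
intermediate sizes add nothing to the measured endpoint.

Under the fixed β = 0.3 coupling the mirroring is real: in roughly a
quarter of realizations the reverse map converges weakly (final skill
~0.1) and the honest verdict is "bidirectional, leading X→Y" rather than
the exact unidirectional call; the benchmark therefore reports both the
exact-verdict rate and the leading-direction-correct rate.  The
skill-vs-coupling relation is monotone below β ≈ 0.1 and saturates above
— the tests assert monotonicity only on the rising range.

## Numerical and degenerate-input choices

- Missing data are NaN throughout; nodata tags of ASCII grids and
  GeoTIFFs map to NaN on read and back on write.
- Undefined skill (fewer than 3 predictions, or zero variance on either
  side) raises `UndefinedSkillError` — it is never silently reported
  as 0.  A window whose skill is undefined is dropped from the per-size
  aggregate; a size with no defined windows fails loudly.
- |ρ| = 1 returns p = 0 (or 1) from `significance` and is rejected by
  `confidence_interval`.
- Constant fields embed to identical states; all distances are 0 and the
  exact-match weight rule applies, but skill is then undefined by the
  zero-variance rule.
- Seeds: every stochastic component (simulators, library subsampling,
  noise injection) takes an explicit integer seed; identical
  configuration and seed reproduce results bit for bit.

## Known limitations

Queen contiguity is the only built-in polygon adjacency (arbitrary
adjacency is accepted via edge lists); rook, distance-band and k-nearest
weights are out of scope, as are time-lagged or mixed spatio-temporal
embeddings, shapefile input, surrogate-based significance, and
multiple-testing correction across many variable pairs.  Significance
treats predicted units as independent observations, which overstates
evidence on strongly autocorrelated fields — one reason the benchmark
adds the exclusion radius and the trend test rather than trusting the
t-test alone.
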