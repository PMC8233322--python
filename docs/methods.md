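# Methods

`crustflux` models the storage and export of microbial cells and cellular
carbon in the weathering crust — the porous, water-saturated near-surface
layer of ablating glacier ice — and the delivery of that material to
supraglacial streams. This note records the models, their assumptions, the
defaults and why they were chosen, and what the synthetic data can and cannot
tell you.

## Slug-test conductivity (hydraulics)

Bail-recharge (slug) tests in shallow auger holes are inverted with the
Hvorslev basic-time-lag method. The water-level displacement is assumed to
recover exponentially, `h(t) = h0·exp(−t/T0)`, and the conductivity follows
from the hole geometry:

    K = r² · ln(L/R) / (2·L·T0)

with casing radius `r`, effective intake radius `R` and intake length `L`.
Assumptions: quasi-steady radial flow to an unlined cylindrical intake in a
homogeneous, isotropic medium; hole storage dominated by the casing. The
shape factor `ln(L/R)/(2L)` is the standard one for an intake of length
`L >> R`; because slug-test formulas differ between texts, the geometry is an
explicit, swappable input (`AugerHole`) rather than a hard-coded constant,
with `R = r` by default (unlined hole in ice).

Numerical choices:

* the fit is ordinary least squares of `ln(h/h0)` on `t`;
* the first 2 samples are excluded by default (bail turbulence), as are
  samples below 10% of the initial displacement, where sensor noise dominates
  the log-residuals;
* a record is *complete* only if the head falls to `exp(−1)·h0` within the
  record (one basic time lag actually observed). Incomplete records keep
  their `T0` fit but report `K = NaN` and are excluded from campaign
  summaries — partial recoveries do not support a confident estimate.

`K` is reported in m d⁻¹ at every interface; seconds exist only inside the
fit. The estimator is scale-equivariant (stretching time by `s` divides `K`
by `s`), which the suite asserts.

## Darcian throughflow

Saturated transport through the crust is plain Darcy flow: throughflow
(pore-water) velocity `v_t = K·Δh/ϕ` with surface slope `Δh` (m m⁻¹) as the
hydraulic gradient and effective porosity `ϕ`; specific discharge through a
1 m-wide vertical strip of saturated crust of thickness `d` is
`q = v_t·ϕ·d = K·Δh·d` (m³ d⁻¹ m⁻¹). Defaults are the study-site values:
`K = 0.28 m/d`, `Δh = 0.022`, `ϕ = 0.22`, `d = 0.29 m`, giving
`v_t = 0.028 m/d` and `q ≈ 0.0018 m³/d`. The water table is assumed static
over the day: no unsaturated-zone flow, no transient storage.

## Cell census

Census tables carry one row per depth-integrated water sample with total
abundance and six size-fraction abundances (cells mL⁻¹). Conventions:

* Samples above 1×10⁵ cells mL⁻¹ (strict inequality) are *flagged* as
  outliers — bloom-adjacent or particle-rich water — never deleted, so any
  statistic can be recomputed with outliers included by flipping one flag.
* The six classes default to edges (1, 2, 6, 10, 15) µm with a 0.5 µm
  analytical lower limit. The interior edges 2 and 6 µm are configuration
  defaults, not measurements; every downstream biomass number is computed
  from the configured scheme, so changing the edges propagates everywhere.
* Cells below the 10 µm edge are nominal bacteria (and archaea), 10–15 µm
  nominal algae, and the open-ended >15 µm class is carried separately
  because it can dominate carbon totals.
* The sub-micron class is retained in counts and biomass by default (small
  cells are real, though large viruses may inflate it); it can be dropped via
  the scheme.
* Class proportions in summaries are computed per sample and then averaged,
  weighting each sample equally.
* The conductivity–abundance relation is fitted as OLS of `ln(abundance)` on
  `K` (an exponential decay `A·exp(−λK)`), with `r²` reported on the log
  scale. Outlier pairs are excluded; non-positive abundances are dropped and
  counted.

## Biomass conversion

Four conversion schemes, applied per size class and summed over the mix:

| scheme | bacteria | algae |
|---|---|---|
| constant, low | 11 fg C cell⁻¹ | 153 fg C cell⁻¹ |
| constant, high | 20 fg C cell⁻¹ | 260 fg C cell⁻¹ |
| allometric `M = c·Vᵃ` | c = 162, a = 0.91 | c = 109, a = 0.991 |
| biovolume ratio | 560 fg C µm⁻³ | 110 fg C µm⁻³ |

Biovolumes use idealised shapes: sub-micron cells are spheres; larger
bacteria are rods (hemispherical-ended cylinders) with a default length:width
ratio of 2 (typical bacterial geometry; no single published value, hence
configurable); algae are 10 µm diameter cylinders. Class lengths are bin
midpoints; the open >15 µm class is pinned at 27.5 µm, the typical length of
the filamentous alga *Ancylonema nordenskiöldii*. At these geometries the
per-class ordering constant-low < constant-high < allometric < biovolume-ratio
holds for every class, so the method ordering of any mixture is fixed — a
useful mix-independent invariant that the suite asserts.

Per-area loads integrate abundance over the saturated pore volume:
`load = abundance·10⁶ mL m⁻³·d·ϕ` (cells m⁻²). Unit constants
(1 fg = 10⁻¹⁸ kg, 1 m³ = 10⁶ mL, 1 km² = 10⁶ m²) are module-level and
covered by a unit-audit test.

Growth uses unconstrained exponential doubling from an antecedent abundance
`C0` (default 2.3×10³ cells mL⁻¹, the lowest observed concentration): the
first-day increment is `C0·(2^(1/T_d) − 1)` for doubling time `T_d` (presets
1, 4 and 11 days span published supraglacial communities). No logistic
(density-limited) growth is modelled — there is no well-constrained carrying
capacity for these communities — so multi-day accumulation extrapolations are
upper-bound-flavoured.

## DEM conditioning and routing

Standard raster hydrology with glacier-specific parameters:

* **Detrend**: moving 31×31 local plane fit (least squares per window,
  clipped at edges), splitting the surface into low- and high-frequency
  parts that reconstruct the input exactly.
* **Smooth**: Gaussian kernel of 11 cells with the half-width spanning two
  standard deviations (σ = 2.5 cells), normalised convolution under nodata.
* **Fill**: priority-flood depression filling with a 0.51 m depth threshold —
  the maximum depth found in a survey of cryoconite holes, which sit in
  shallow topographic sinks. Depressions deeper than the threshold
  (crevasse-like) are retained untouched and act as internal flow sinks.
  Depth is measured pour level to basin minimum. Shallow pits nested inside
  a retained deep sink are left unfilled; the sink already terminates flow
  there, and the operation remains idempotent.
* **D8**: steepest descent over 8 neighbours, gradient ties broken
  deterministically by the lowest direction code in the order E, SE, S, SW,
  W, NW, N, NE. Flats (plateaus created by filling) drain by breadth-first
  assignment toward the nearest equal-elevation cell that already drains —
  i.e. toward the pour point. Cells that still cannot drain (minima of
  retained sinks) are reported per-cell and treated as internal outlets, so
  accumulation over all outlets always equals the valid area.
* **Streams**: accumulation ≥ 165 m² (the threshold that best matched
  visible channels on the reference imagery). Stream cells are masked out of
  interfluve statistics rather than elevation-carved; the purpose of
  "burning" here is interfluve flow-path measurement, not re-routing.
* **Flow distance**: along the D8 path (cardinal steps = cell size, diagonal
  = √2×), zero on stream cells, infinite where a path exits the grid without
  meeting a stream. Along-flowpath (not Euclidean) distance is used because
  the quantity of interest is the interstitial travel path; the Euclidean
  alternative would only shorten distances.
* **Bank geometry**: the bank strip is the interfluve within 1 m flow
  distance of a stream ("drains immediately"); bank length = bank area /
  bank width. Mean distance-to-stream averages over finite interfluve
  distances.

Grids are row-major, origin upper-left, cell-centre registered, NaN nodata;
there is no projection handling (synthetic/local grids only). Raster I/O is
ESRI ASCII grid, a plain-text format read and written by the package.

## Flux model

Daily export: `flux = q·bank_length·10⁶·abundance` (cells d⁻¹). The printed
bank area of 6.84×10⁴ m² with a 1 m bank width is interpreted as
6.84×10⁴ m of discharging bank — the reading under which the flux arithmetic
reproduces the published chain — and `bank_width` is an explicit parameter.
Catchment area, when not given, is bank area / bank fraction (default 14%),
and conversely.

Seasonal export integrates the daily flux over the bare-ice window of
duration `b_i` days centred on DOY 196 (July 15), scaling each day by
`depth(t)/d_max`: export is proportional to the saturated cross-section, and
the crust deepens and decays over the season. The depth model is a raised
cosine,

    depth(t) = min(d_max, (g·b_i/2)·(1 − cos(2π(t − t_start)/b_i)))

with growth coefficient `g = 0.0076` m per day of duration and
`d_max = 0.29` m, so the peak depth is `0.0076·b_i` for `b_i` below ~38 days
and plateaus at 0.29 m beyond. This is one consistent realisation of the
qualitative description (grow from zero, peak bounded, decay symmetrically);
it is isolated behind `CrustDepthModel` so an alternative parameterisation
can be swapped without touching the integrator. Depths are sampled at daily
midpoints of the window. For `b_i = 68` the mean depth fraction is ≈0.66 of
the plateau, giving a seasonal export of ≈1.25×10¹⁴ cells at the mean
velocity — about 11% below the published 1.4×10¹⁴, consistent with the
depth-curve form being under-determined.

In-situ accumulation converts the growth increment to kg C km⁻² d⁻¹ through
the same load and mix machinery; the balance `accumulation − export` is
reported with an "accumulating" flag. Regional upscaling applies the
seasonal integral per catchment with its own `b_i` and sums; in-stream
transit to moulins is treated as lossless (sub-day transit times). Seasonal
"delivery fraction" is implemented as the fraction of interfluve cells whose
flow distance is within `v_t × season_days` (default 70 days) — an inference
about how seasonal reach is defined, stated here because it is not spelled
out elsewhere.

## Synthetic data: what it emulates, and what it does not

All inputs are generated, seeded and bit-reproducible:

* **Recharge curves** are exactly exponential for a known `K` (plus optional
  Gaussian head noise), so estimator round-trips have a known truth. Real
  records carry non-exponential early-time behaviour and sensor drift that
  the generator does not produce.
* **Census tables** draw totals from a lognormal moment-matched to mean
  2.28×10⁴ / sd 1.91×10⁴ cells mL⁻¹ (positive, right-skewed; the
  distributional family is a modelling choice, not an observed fact), with
  Bernoulli "bloom" samples from a separate lognormal (median 3×10⁵) that
  robustly exceed the outlier threshold. Size splits are multinomial on
  per-sample Dirichlet proportions (concentration 50) around the mix
  (19, 50, 15, 8, 5, 3)% — sub-micron and 1–2 µm shares at their observed
  means, ~7% spread on the dominant class, algae below 10% of cells. The
  ~1% of background lognormal mass above 10⁵ cells mL⁻¹ is deliberately not
  truncated (truncation would bias the mean ≈4% low), so flagged fractions
  slightly exceed the bloom rate.
* **DEMs** are an east-dipping plane at 2.2% slope plus correlated Gaussian
  roughness (3-cell correlation length, 3 cm amplitude), shallow bowls for
  cryoconite-like pits, and one meandering channel carved 5 cm deep with
  strictly descending bed so a stream is always extractable. The synthetic
  stream network is sparser than the reference catchment's, so its bank
  fraction (~2–3%) and mean distance-to-stream (~17 m) are *not* calibrated
  to the field values (14%, 7.24 m); routing correctness is instead
  established by brute-force oracle equality on small grids, and the field
  bank geometry enters the flux model as an explicit input.
* **Catchment tables** use lognormal areas (median 0.5 km²), the constant
  14% bank fraction, and uniform bare-ice durations in 40–90 days.

Passing tests therefore demonstrate the correctness of the estimators and
the flux arithmetic under known truth, and the reproduction of the published
worked-value chain from its stated inputs — not the recovery of
field-data-dependent quantities (Table-style carbon values under the
unpublished field size mix, the field DEM's bank geometry), which are
asserted only as orderings, envelopes and order-of-magnitude containment.

## Problem sizes

Default sizes keep every run light: 96×96 DEMs (pure-Python priority flood
and routing complete in well under a second), 83-sample censuses, 47–78
simulated slug tests, 795 catchments in the regional table. These match the
study scale where one exists (sample and catchment counts) and are otherwise
the package's own choices.

## Known limitations

* The slug-test formula is one member of a family; if the field analysis
  used a different shape factor, `K` shifts by a constant factor
  (configurable through `AugerHole`).
* The cosine depth model's exact functional form is under-determined; the
  seasonal integrals inherit ~10–20% structural uncertainty.
* Flow through the unsaturated crust and micro-channels is not modelled;
  export estimates are a saturated-zone baseline.
* Regional areas are a user input: published regional figures quote both
  ~1.38×10³ km² and ~14×10³ km² for the western ablation zone, and the
  package does not adjudicate between them.
* No in-stream transformation, cryoconite productivity, or bio-albedo
  feedback is computed; cited values for those appear only as comparison
  numbers in the analysis narratives.
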