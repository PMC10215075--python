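# Methods

`mcfrw` simulates hindered water diffusion inside a single mineralized
collagen fibril (MCF) with a three-stage pipeline: an explicit
collagen–apatite obstacle model, an ensemble of obstructed Gaussian random
walks, and mean-squared-displacement (MSD) / tortuosity analysis of
first-passage sub-trajectories along the fibril axis. This note records
the model, its assumptions, the numerical choices, and what the tests do
and do not demonstrate.

## Geometry model

The fibril is a cylinder of radius 100 nm and length 1000 nm; axes are
named W, T (equatorial) and L (the fibril axis). Two obstacle families
fill it:

**Apatite platelets** are rectangular parallelepipeds whose edge lengths
are drawn from Gaussians truncated to the ranges reported for bone
mineral: thickness 2–5 nm, width 5–90 nm, length 50–170 nm. The standard
deviation defaults to range/6, and the pre-truncation means are calibrated
(truncated-normal mean inversion) so the *realized* means equal the model
averages of 41.80 nm (width), 3.55 nm (thickness) and 94.51 nm (length).
Platelets tile a staggered lattice: cross-section pitches are mean
dimension plus the inter-platelet gaps a_W = 13.19 nm and a_T = 2.35 nm;
the axial pitch follows the staggered-arrangement relation
(ℓ + a_L)/2 = D_period with D_period = 67 nm, so columns repeat every
134 nm (a_L = 39.49 nm for the mean length) and alternate platelet layers
are shifted by one half pitch (67 nm). These pitches make the bulk mineral
volume fraction

    (41.80 · 3.55 · 94.51) / (54.99 · 5.90 · 134.0) = 0.3226,

the physiological mineralization degree (~32%) the model is built to
represent.

Because independently sampled dimensions occasionally exceed the lattice
pitch (about 9% of width-neighbour pairs), interpenetrating neighbours are
trimmed symmetrically at their contact plane — each facing side loses half
the overlap, along the stacking axis identified by the smallest
penetration *relative to the combined half-extents*. This mimics crystals
growing until they abut, and costs only ~0.5% mineral volume; resampling
offending dimensions instead would bias the width distribution low by
several percent.

The crystal lattice carries no registration with the (arbitrary) envelope
axis: a seeded uniform random phase shifts the whole lattice in W, T and
L. Without it, a privileged alignment (e.g. a column centred on the axis)
biases the enclosed fraction by about one percentage point. Platelets
partially outside the envelope are kept and implicitly clipped — every
point outside the envelope is blocked anyway — which preserves the bulk
fraction; dropping them would carve a platelet-wide rim out of the mineral
(the `boundary="drop"` option remains available). Realized Monte-Carlo
fractions come out at 0.32 ± 0.005 across seeds.

**Tropocollagen molecules** are L-parallel cylinders of diameter 1.23 nm
on a hexagonal lattice with 1.6 nm centre spacing, axially continuous
(the 67 nm gap/overlap banding of real collagen is not modelled). The
lattice is implicit and infinite: the union of platelets with the full
cylinder lattice is set-identical to "cylinders fill the non-mineral
space, clipped at platelet faces", and lattice sites outside the envelope
can never affect a point that is not already envelope-blocked. The
spacing is the single knob that dominates residual porosity: with the
default, water occupies the interstitial channels (inradius ≈ 0.31 nm,
free cross-section ≈ 46%) and the gaps between platelet faces.

**Perturbation.** Starting from the aligned lattice, 6·10⁶ single-platelet
trial moves (uniform translations up to 1 nm per axis, rotations up to 1°
about a random axis) disorder the structure. A move is rejected if it
would (i) create platelet–platelet overlap (separating-axis test against a
static neighbour list, pruned by cached world bounding boxes), (ii) tilt
the platelet's long axis more than 20° from the fibril axis, (iii) push
the platelet outside the envelope beyond its as-built protrusion, or
(iv) carry it more than 5 nm from its built position. The displacement cap
keeps the perturbation a local disorder rather than platelet diffusion
(and bounds the neighbour list); without it the lattice melts over ~8000
moves per platelet. In the dense stack the 20° bound is rarely saturated —
typical realized inclinations are a few degrees, with maxima at the bound.

## Random walk

Per-coordinate step lengths follow σ = sqrt(2 D₀ Δt) with
D₀ = 2.66·10⁻⁹ m²/s (bulk water at 27 °C) and Δt = 2·10⁻¹⁰ s, giving
σ ≈ 1.03 nm — smaller than the thinnest obstacle (the 1.23 nm collagen
cross-section). Because σ is close to that limit, acceptance tests the
entire step segment (slab test against platelets, 2D circle test against
cylinders), not just the endpoint, so steps cannot tunnel through thin
obstacles.

Walkers start uniformly on the un-blocked part of the L = 0 disc and run
until they first cross a stop plane (the upper extremity by default). Two
rejection policies exist:

* `stay` (default): one proposal per time step; a blocked proposal leaves
  the particle in place for that step. This blocked-move dynamics slows
  the walk in proportion to the local rejection rate (≈ 80% in the default
  geometry) and is what produces effective diffusivities an order of
  magnitude below D₀ — consistent with the procedural description of the
  method ("the particle stays at the current location") and with the
  hindered diffusivity scale the model is meant to reproduce.
* `resample`: rejected proposals are redrawn within the same time step.
  Obstruction then acts only through path geometry, and the effective
  diffusivity cannot drop far below D₀; the option is retained for
  comparison studies.

A walker exceeding 10⁴ consecutive rejections raises a trapped-walker
error (only reachable in pathological geometries such as the sealed-box
fixture). The lower extremity (L < 0) and the lateral envelope are
blocking, i.e. the fibril surface is impermeable; propagation of water in
from the lateral surface is outside this model's scope.

Positions may be recorded every `record_stride` steps; the stride only
thins the recording (the MSD slope and coarse-grained tortuosity are
stride-independent at the strides used) and bounds memory for
fibril-spanning walks that take ~10⁷ steps.

## Analysis

**Diffusivity.** For each (sub-)trajectory the time-averaged MSD over all
overlapping pairs is computed with the standard FFT decomposition
(O(N log N); positions are centred first, which conditions the
large-offset sums — the estimator agrees with the literal double loop to
~10⁻¹² relative). An ordinary least-squares line over the lag window
1…⌊N/10⌋ (early lags carry the best pair statistics; the window is
configurable and R² is recorded) gives MSD = β₀ + β₁t, and the Einstein
relation in three dimensions gives D = β₁/6, converted from nm²/s to
m²/s.

**Tortuosity** is effective path length over the start-to-end chord. A
Brownian path has no intrinsic length — the raw sum of recorded segments
grows without bound as recording gets finer — so any finite tortuosity
implies a measurement scale. `tortuosity()` defaults to the exact sum
over recorded positions (so textbook cases like a right-angle path giving
√2 hold), while quote sweeps coarse-grain the path at the axial
structural period, 67 nm, before summing: the walk is anchored at its
start, the anchor advances each time the walker first moves 67 nm away
from it, and the final position closes the path. Below that scale path
length measures Brownian roughness; at it, path length measures the
structural detours the obstacle lattice imposes, which is the quantity of
interest. The resolution is a parameter of `quote_sweep`.

**Quote sweeps.** Reference quotes sit at multiples of the 134 nm
building block (134 … 938 nm). A sub-trajectory is the prefix of a walk
up to its *first* recorded crossing of a quote plane (first passage, not
last visit). Per quote, tortuosity and D are computed for every reaching
sub-trajectory and averaged; 95% confidence intervals use Student's t on
the mean. Quotes that no trajectory reaches are reported with a zero
count and NaN means — never silently dropped into averages. Note the
short-quote D is selection-biased high (walkers that reach a nearby plane
quickly are the locally fast ones); this bias fades for distant quotes
and is part of why the mean D declines along the fibril.

## Problem sizes and what the tests show

The package's standard study is 1000 trajectories; the bundled
verification runs are scaled to desk size: free-diffusivity recovery uses
200 × 5000 free steps (recovers D₀ within statistical error when started
far from the blocking floor — walkers started *on* the L = 0 plane feel
the floor and measure low, which is physical, not an estimator bias);
the axial profile uses 30 fibril-spanning walks; the bottom-quote
maximum-tortuosity statistic uses 1000 short walks. With those sizes the
model yields mean tortuosity rising monotonically ~10× between the 134 nm
and 938 nm quotes, a mean D decline of a few tens of percent, hindered D
of order 10⁻¹⁰ m²/s, and a bottom-quote maximum tortuosity of order ten —
the max statistic is volatile at this ensemble size and sits at the low
edge of its expected band.

Synthetic fixtures (empty medium, single box, slab maze with staggered
apertures, sealed cavity, zero-scatter lattice) each have a closed-form or
by-construction property; passing them validates the estimator chain and
collision handling, not the biological fidelity of the geometry. The
model idealizes crystals as boxes and collagen as continuous cylinders,
ignores particle–particle interactions, bound-water exchange and the
collagen D-banding, and treats the fibril surface as impermeable; results
speak to steric hindrance by the arrangement, not to chemistry.

## Numerical details

* Lengths are nm, time s internally; D is reported in m²/s (factor
  10⁻¹⁸).
* Collision queries go through a uniform-grid spatial index (10 nm cells,
  CSR layout) for platelets and closed-form lattice indexing for
  collagen; both are verified against index-free brute-force oracles on
  10⁴ random queries.
* All randomness is seeded: geometry build, perturbation and each
  trajectory derive independent 31-bit seeds; the compiled kernels use
  the legacy Mersenne Twister, which the pure-Python engine reproduces
  draw-for-draw, so both engines yield bit-identical trajectories.
* Overlap tests use the 15-axis separating-axis theorem with a 10⁻⁹
  tolerance; trims leave a 10⁻³ nm clearance so touching neighbours are
  not counted as overlapping.
* Degenerate inputs raise typed errors (`ParameterError`,
  `GeometryError`, `TrappedWalkerError`, `UndefinedTortuosityError`)
  rather than returning sentinel values; undefined statistics surface as
  NaN with a zero count.
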