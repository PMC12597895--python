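# Methods

## Scope and model

`spatialabm` studies how the *initialization* of a spatial tumor–immune
agent-based model (ABM) shapes its emergent dynamics. The model is a
deliberately minimal off-lattice 2D ABM with three cell types and
asymmetric rules:

* **cancer** (malignant epithelium) — divides, subject to contact
  inhibition, and undergoes apoptosis; does not move actively;
* **CD8** (cytotoxic T cells) — migrate by a persistent random walk and
  execute timed attacks that probabilistically kill cancer cells; they
  neither divide nor die;
* **healthy** (healthy epithelium) — mechanically present but inert: it
  neither divides, dies, nor moves.

All cells are soft discs that repel on overlap. Because only cancer cells
change the population and only T cells act on them, every difference
between runs that share parameters is attributable to the initial spatial
arrangement — which is the point of the exercise.

### Mechanics

Overdamped pairwise repulsion. For a pair at center distance `d` with
summed radii `R = r_i + r_j`, each member is displaced away from the other

    dx = dt_mech * repulsion_strength * (1 - d/R)^2        for d < R

per mechanics sub-step. Coincident centers (d = 0) separate along a
deterministic pseudo-random axis derived by hashing the two agent ids, so
replays are exact. Domain walls reflect. Cells locked in an attack do not
move. There is no adhesion: the model represents space competition only.

Overlaps present in an initial state (e.g. a measured tissue whose spot
centroids coincide) are *not* resolved at initialization; the first
mechanics steps relax them. This keeps t = 0 exactly equal to the data.

### Time stepping

Two nested clocks, as in standard center-based frameworks: mechanics
sub-steps of `dt_mech` minutes inside phenotype epochs of `dt_phen`
minutes. Each epoch runs `dt_phen/dt_mech` mechanics sub-steps, then
migration, then division/death, then attacks, in that fixed order (the
order is a convention; determinism requires one). All stochastic events
are Bernoulli draws with probability `rate x dt_phen` from a single
per-replicate `numpy` PCG64 stream, agents visited in id order. Configs
with `rate x dt_phen > 1` for any rate are rejected before the run starts.

### Migration

Non-attacking CD8 cells redraw their heading uniformly on the circle with
probability `dt_phen / persistence_time` and advance
`motility_speed x dt_phen`. The discrete-time mean-squared displacement
has the closed form

    MSD(n) = (v dt)^2 [ n + 2 sum_{k=1}^{n-1} (n-k) a^k ],   a = 1 - dt/tau

which the test suite checks against simulated walkers.

### Division, apoptosis, contact inhibition

A cancer cell divides only if at most `max_neighbors_for_division` other
agents lie within `contact_scale x 2r` of it; the daughter is placed one
radius away at a uniform angle and the mechanics relaxes the overlap.
Contact inhibition through a neighbor-count threshold is the simplest
testable surrogate for competition for physical space. Apoptosis removes
the cell and frees any attacker locked on it.

At mechanically relaxed confluence (16 µm spacing) an interior cell has
5–6 neighbors within the 20 µm contact distance, so the shipped threshold
of 4 makes confluent tissue quiescent while holes opened by death or
killing re-enable division around them — the feature that produces the
well-mixed plateau (below).

### Attacks

A free CD8 cell with at least one untargeted cancer cell within
`contact_scale x (r_i + r_j)` begins an attack with probability
`attack_rate x dt_phen`, targeting the nearest eligible cancer cell (ties
to the lowest id). Pairing is exclusive and one-to-one; both members are
immobilized. The timer advances each epoch; when it reaches
`attack_duration` the target dies with `kill_probability` and the pair
dissolves either way. "Ongoing attacks" at a snapshot is the number of
live pairs.

## Initialization strategies

* `init_well_mixed` — every type uniform by area in one disc.
* `init_structured` — cancer and healthy interleaved uniformly in an inner
  disc (one epithelial compartment), CD8 uniform in a surrounding annulus.
* `init_spatial_informed` — one agent per measured cell at its affinely
  transformed coordinates; **no jitter, no resampling**. The default
  transform only translates the measured centroid to the origin; with an
  explicit identity transform output equals input bit-for-bit. Cells
  sharing a spot centroid stay coincident (mechanics separates them).
* `abundance_placement` — for non-spatial tables: each type receives
  `round(total_n x share)` seats by the largest-remainder method
  (lexicographic tie-break, so totals are exact and deterministic) and is
  sampled uniformly in its assigned geometry.

Disc/annulus sampling uses the inverse-CDF radius (`r = R sqrt(u)` etc.),
verified by Kolmogorov–Smirnov uniformity tests on the squared-radius
pivot.

## Spatial readouts

**Cross-pair correlation function.** For center type C and target type T,

    g_k = (1/N_C) * sum_i n_i(k) / (lambda_T * a_k)

with `n_i(k)` the number of T cells in the annular bin `[r_k, r_{k+1})`
around center i, `a_k` the bin's area and `lambda_T = N_T / domain_area`.
Bins default to 0–200 µm in 10 µm steps. **No boundary edge correction is
applied**: annuli truncated by the domain boundary bias g downward at
large r. The documented reading (and the tests) therefore use interior
configurations — bins short relative to the distance of the centers from
the boundary — where the estimator is unbiased under complete spatial
randomness. Snapshots without centers yield masked (NaN) heatmap columns.

**Components.** The neighbor graph joins any two agents within
`contact_scale x (r_i + r_j)`; cancer clustering is measured on the
subgraph induced by cancer cells (a cancer–healthy–cancer chain is two
components, matching the "cancer cells per component" readout). The
component CDF weights by cell count: F(s) = fraction of cancer cells in
components of size <= s.

**Replicate aggregation.** Time series aggregate pointwise (mean, sample
SD with ddof = 1; SD = 0 for a single replicate). Component CDFs are
aligned on the union of observed sizes by right-continuous step
interpolation before averaging — the natural convention for empirical
CDFs; no smoothing.

## Synthetic tissue generator

`generate_pdac_like_sample` emulates the architecture of an
immune-infiltrated pancreatic ductal adenocarcinoma (PDAC) biospecimen:
a solid malignant core (cancer on a jittered triangular lattice at 16 µm
spacing, i.e. near-confluent epithelium), healthy epithelium uniform in an
annulus hugging the core, and CD8 cells whose radius is Normal(core
radius, border SD) truncated to r > 0 — immune density peaked at the
malignant border. Default sizes (1500 cancer / 800 healthy / 600 CD8,
350 µm core, 130 µm border SD, 300 µm healthy ring, 2 µm jitter) give a
~2,900-cell sample that one replicate simulates in about a minute; they
are *synthetic stand-ins*, not measurements. The healthy ring is sparse
(about a fifth of confluent density — epithelium mixed with unmodeled
stroma), leaving the malignant front room to expand; the immune band is
wide enough that border pressure does not extinguish that front.

What the generator deliberately does **not** reproduce: transcript counts
or any expression data, spot-level mixing, irregular tumor boundaries,
stromal heterogeneity, or the real sample's abundances. Tests passing on
this sample demonstrate that the pipeline preserves and propagates spatial
structure — not that the model is calibrated to real PDAC tissue.

## Default parameterization and calibration

The shipped defaults (all configurable) are:

| parameter | value | units |
|---|---|---|
| cancer division rate | 0.02 | 1/h |
| cancer apoptosis rate | 0.001 | 1/h |
| max neighbors for division | 4 | count (within 20 µm) |
| CD8 motility speed | 8 | µm/min |
| CD8 persistence time | 10 | min |
| attack rate | 0.005 | 1/min in contact |
| attack duration | 30 | min |
| kill probability | 0.425 | per completed attack |
| contact scale | 1.25 | x summed radii |
| cell radius (all types) | 8 | µm |
| repulsion strength | 10 | µm/min at full overlap |
| dt_mech / dt_phen | 0.5 / 6 | min |
| save interval | 60 | min |
| domain | [-800, 800]^2 | µm |
| well-mixed disc radius | 420 | µm |
| structured disc / annulus | 460 / 460–660 | µm |

Rates sit in the range used by center-based tumor-immune models (division
times of days, T-cell speeds of µm/min, attack engagements of tens of
minutes). Within that range the free constants were **calibrated as a
set** so that the three default scenarios reproduce the qualitative
behavior the model is meant to exhibit — well-mixed: sharp early decline
stabilizing near 90% of the initial cancer count; structured and
spatial-informed: net growth with progressive immune infiltration — and
they are part of the package's contract: the acceptance checks run them
as-is. The calibration logic: the low attack rate with a moderate kill
probability makes T-cell killing proportional to *contact exposure*, so
the volumetrically exposed well-mixed tumor takes early losses that
border-exposed tumors do not; the contact-inhibition threshold of 4 makes
those losses self-limiting because each kill re-enables division around
the hole it opens.

## Numerical choices

* Probabilities are first-order (`rate x dt`); products above 1 are
  configuration errors, detected before a run starts.
* Mechanics sub-steps reuse a cached candidate-pair list with an 8 µm
  search margin; the cache is rebuilt whenever accumulated motion could
  bring an unseen pair into overlap, so results are identical to a fresh
  neighbor search each sub-step.
* Attack timers use `>= duration - 1e-9` to absorb float accumulation.
* Reflection only touches coordinates that actually left the domain, so a
  frozen system replays bit-identically.
* `cells.csv` floats are written with shortest round-trip repr and read
  back with exact (`round_trip`) parsing.
* Division and death draws within one epoch are independent; death draws
  apply to the pre-division population (a cell can divide and die in the
  same epoch; its daughter survives).
* The save grid is uniform (`save_interval_min`, default 60 min, must be a
  multiple of `dt_phen`); a run wanting denser early output simply lowers
  the interval.

## Known limitations

* 2D only; no diffusible substrates, chemotaxis, exhaustion, or cell-cycle
  structure. T cells migrate blindly — enrichment at tumors emerges purely
  from engagement-immobilization.
* The cross-PCF carries the documented edge-effect bias at ranges
  comparable to the centers' distance from the boundary.
* The plateau/growth contrast between scenarios is a property of the
  shipped parameter set; other parameterizations of the same model can
  produce tumor extinction or unbounded growth (the calibration scans in
  the development history map that landscape).
* Measured tables are consumed as labels + coordinates only; expression
  matrices are out of scope.
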