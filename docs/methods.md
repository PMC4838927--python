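# Methods

## The system being modelled

Two isolated 25-square micro-aquaria (PDMS chips, squares 480 um wide,
120 um deep, joined by 90 x 90 um passages) each confine one population
of motile, blue-light-responsive microalgae: dish A holds ~400
*Euglena gracilis*-like cells, dish B ~1300 *Chlamydomonas
reinhardtii*-like cells.  Each dish sits in an optical feedback loop
that images the cells' swimming traces once per 1.47 s cycle, reduces
the trace image to 25 per-square pixel counts (the *trace momentum*,
TM), and projects a blue illumination pattern back onto the chip.  The
two loops are interlinked: each dish's TM dataset determines the
*other* dish's next illumination pattern.  `algalink` is a computational
twin of that closed loop: the optics, cameras and LAN transport are
replaced by an in-process exchange (with an optional ±1-cycle jitter),
and the cells by stochastic agents.

The two interlink rules are implemented exactly as operated:

* **Two-state flipping (oscillation).**  The 24 non-centre squares are
  split into two interleaved groups of 12 (parity checkerboard; the
  published record fixes only the counts 12/12 and the always-dark
  centre, so the checkerboard — under which every neighbour of a
  group-I square is group-II or centre — is this package's choice).
  When a dish's imbalance ratio (TM_I − TM_II)/(TM_I + TM_II) reaches
  the prefixed threshold in magnitude, the TM-dominant group is lit in
  the counter-dish at the next step.  The rule is level-triggered and
  idempotent; both dishes start on group I.
* **Ranking (separation).**  Dish B is lit on the squares holding the
  12 lowest TMs of dish A; dish A on the 12 highest TMs of dish B.
  All 25 squares participate; ties resolve to the lower square index.

A run is 4000 steps (98 min); the feedback is suspended during the
first and last 500 steps.

## Agent models

Both species advance in 0.147 s sub-ticks, ten per feedback cycle, so
the fastest cell (100 um/s) moves well below the passage scale per
tick.  Per-cell speeds and body sizes are drawn once at initialisation,
uniformly over the published trait ranges (Euglena: 30–90 um/s,
body 20–100 um; Chlamydomonas: 20–100 um/s, body 10–30 um), because
cell-to-cell variability is an explicit feature of the real system.

**Euglena (dish A).**  In darkness a cell swims ballistically at its
own speed with weak heading diffusion (0.3 rad/sqrt(s)) and reflects
specularly off walls with ±0.3 rad jitter.  Under blue light it
switches instantly to on-site tumbling, modelled as isotropic Brownian
displacement (⟨|Δx|²⟩ = 4·D·dt) with the heading re-randomised every
tick; tumbling cells drift and occasionally find a passage, which is
the only escape channel.  A dark swimmer whose step would carry it into
a lit square turns back at the illumination border with probability
`euglena_border_turn_prob`.  Because squares connect only through
passages (shorter than one tick's travel), border turning physically
happens at passage mouths.

**Chlamydomonas (dish B).**  Cells are two-state: resting cells are
stationary; active cells random-walk (heading noise 1.5 rad/sqrt(s)).
Light drives resting → active at rate `k_act`; darkness drives
active → resting at rate `k_rest`; both are exact exponential-law
Bernoulli steps, 1 − exp(−k·dt).  The real cells escape illumination by
swimming against the bottom-mounted light source, i.e. vertically, and
therefore fail to find the lateral passages; this third dimension is
collapsed into a 2-D exit-damping rule: while a cell's square is lit,
passage-crossing attempts succeed only with probability 0.1.

Cell–cell collisions, hydrodynamics, phototaxis, gravitaxis, division
and circadian modulation are not modelled.

## Trace imaging and TM

The raster covers the 2760 x 2760 um chamber at 4 um/pixel (a square is
120 x 120 px), which resolves the smallest body (10 um = 2.5 px) at
modest memory cost.  A cycle's trace is the union of ink disks of
radius `width/2 + 2 um` stamped at ≤4 um spacing along each agent's
sub-tick polyline; the half-pixel dilation keeps sub-pixel strokes
visible, matching thresholded video in which any cell marks at least
its own silhouette.  A stationary agent marks its body footprint;
resting Chlamydomonas contribute their (small) static footprint each
cycle (configurable off).  TM is computed per cycle from that cycle's
binary image only; overlapping traces count once, so TM saturates at
high activity — the same saturation the experiment shows when dish B's
ratio plateaus near ±0.45.

**Stroke widths.**  Swimming Euglena are stroked at their body width
(0.2 × body length); active Chlamydomonas at their diameter.  Tumbling
Euglena are stroked at `0.7 × body width`.  This factor is a deliberate
modelling choice: a tumbling cell pivots nearly on-site, so the area it
inks per cycle must be *comparable to but smaller than* its swimming
trace.  If tumbling inked a full-width Brownian path, the instantaneous
lit/dark trace-area contrast alone would swing the group ratio past any
threshold ≤ 0.4 within one cycle and the oscillation period would
collapse to twice the phase delay at every threshold — whereas in the
real system the TM response of dish A is dictated by the *escape time*
of the cells, with the period rising from 1.6 to 12 min across
thresholds.  Keeping the tumbling trace slightly below the swimming
trace makes cell migration, not the mode switch, carry the TM signal.

## Calibration

Free parameters with no published value were fitted to the published
closed-loop observables, staged as:

1. `euglena_tumble_D` and `euglena_border_turn_prob` against the two
   period anchors (6.5 min at threshold 0.40; 1.6 min at 0.05).  The
   diffusivity sets the drain rate of lit squares; the border-turn
   probability sets the re-entry flux and hence the saturation level of
   the ratio, which dominates the period near threshold 0.40.
2. `chlamy_k_act` (= `chlamy_k_rest`) against the phase-delay anchor
   (0.43 min at threshold 0.40): the delay is the time dish B's ratio
   needs to traverse the threshold after its pattern flips, set almost
   entirely by the switching rates.

Shipped defaults: D = 950 um²/s, border-turn 0.4, tumble stroke 0.7,
k_act = k_rest = 0.055 /s, exit damping 0.1.  With these, full-scale
runs give period 6.2 ± 0.2 min and delay 0.42 min at threshold 0.40,
period 1.60 min at 0.05, and a ranking-mode coincidence plateau of 23.2
with 92 % of squares agreeing — all inside the anchors' tolerances.
The fitted D is an *effective* drift, larger than a single tumbling
cell's thermal diffusivity; it absorbs unmodelled directed components
of the real escape.  Calibration used the documented seed list
(101/202/303); verification and the acceptance script use fresh seeds.
`algalink calibrate` re-runs the staged search (reduced populations of
100/325 by default for speed).

## Numerical choices and conventions

* Coordinates: origin at the outer upper-left corner, x right, y down,
  um.  Region ownership is half-open (a square owns its low edges), so
  point classification is total and single-valued.
* Wall handling resolves each offending axis separately (specular fold
  about the crossed wall plane); diagonal corner cuts freeze the cell
  for one tick and reverse it.  Containment is verified after every
  reflection; the fallback keeps the step total.
* RNG: one master seed spawns independent per-dish streams
  (`numpy` `SeedSequence`), so dish A's trajectory is unchanged by
  dish B's settings.
* Ranking ties go to the lower square index; the undefined ratio 0/0
  is treated as "no flip"; threshold crossing is inclusive (|r| ≥ T).
* Period is measured between consecutive dish-B flips back to group I
  (two alternating flips = one full cycle); delay pairs each dish-B
  flip with the next dish-A flip in the half-open window up to the
  following dish-B flip.  SDs are population SDs over cycles.
* Times are exact step × 1.47 s products; printed round-offs of the
  original timeline (e.g. 12.2 vs 12.25 min for step 500) are not
  chased.

## What the simulation does and does not show

The generator reproduces the *conditions* of the experiment — the
geometry, counts, trait ranges, cycle timing and feedback rules — and a
behavioural family rich enough to express the published phenomenology.
Passing the anchored checks shows that run-and-tumble escape plus
two-state photo-activation, coupled only through per-square trace
statistics, quantitatively generates the observed oscillation periods,
phase delays and separation/clustering.  It does not show that the
fitted single-cell parameters are predictive of real cells: several
parameter combinations could express the same closed-loop observables,
and real cells add adaptation, circadian drift (the experimenters' own
explanation for their scattered periods), sensitisation, and
hydrodynamics that this model omits.  Quantities not used as anchors
(duty-ratio histograms, top-3 pattern frequencies) are trial-specific
in the original record and are computed but not targeted.

A known limitation: the gradual aggregation of the non-illuminated
squares into a *single* tightly clustered domain, reported for most of
the original separation trials, does not emerge robustly here — the
simulated ranking loop reaches and holds the mirrored high-coincidence
state (coincidence ≈23, ≥90 % agreement) with its lit set in frequent
dynamic transition, but the mean lit/unlit boundary count stays near
the random-pattern level instead of decreasing.  The real clustering is
thought to ride on second-order spatial correlations of the Euglena
escape (cells accidentally entering a lit square from an adjacent dark
one flip its illumination), which the shipped behavioural family
evidently under-expresses.  Cluster and boundary metrics are provided
and oracle-tested, but no clustering *emergence* is asserted.

## Problem sizes

Full-scale runs (400 + 1300 agents, 4000 steps, 10 sub-ticks, ~55 s
each on one CPU) are used for all anchored observables.  The period–
threshold monotonicity sweep and the calibration search use reduced
runs (100/325 agents, 2000–2400 steps), which preserve the ordering of
periods across thresholds at a quarter of the cost.
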