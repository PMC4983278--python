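# Methods

## The problem

Decades of acid rain loaded Central European forest soils with sulfur.
After SO₂ emissions collapsed (in Austria from 385 000 t in 1980 to
17 000 t in 2013, a whole-percent decline of 95 %), soils keep releasing
previously stored S, so seepage output can exceed deposition input for
years — delaying pH recovery.  Around a beech stem this history is laid
out in space: stemflow concentrates deposition into a small infiltration
zone downhill of the trunk, so columns nearer the stem received both a
*higher historic load* and *more water*.  The extra water flushes them
toward a new input–output steady state sooner, so the downhill transect
acts as a false chronosequence that lets load and time be untangled.
`stemsoil` implements this budget model and the soil-chemistry gradient
analysis used to evaluate it, exercisable entirely on synthetic data.

## Routing (`stemsoil.routing`)

Stand-area stemflow S is split over the downhill columns with routing
fractions (defaults 50/25/17/10/0 % at 27/55/100/150/300 cm; the 2 %
excess over 100 % is kept as-is and warned about — a strict mode rejects
sums above 1.05).  The routed share is concentrated onto the column's
infiltration area:

    SF_local = fraction × SF_stand × A_crown / A_column      [kg S ha⁻¹ yr⁻¹]
    input    = TF + SF_local

Infiltration areas are not observable from published data, so the
default geometry assigns each downhill column the annulus between the
midpoints to its neighbouring sampled distances (innermost annulus
starting at the stem surface, radius 25 cm; outermost ending at the
crown-projection radius √(A_crown/π)).  This is a reproducible,
fully overridable convention, not a measured quantity.  Uphill columns
(negative distance) get routing fraction 0 — stemflow runs downhill —
and inherit the annulus of their mirror radius.

The same fraction is applied to stemflow water, keeping solute and
water routing consistent, which yields the water time factor
`(TF + SF_local)/TF ≥ 1` and the steady-state delay

    delay = round-half-up(base_delay / factor),   base_delay = 12 yr.

This rule was chosen because it maps monotone factors ending at 1
({3, 2, 12/7, 4/3, 1}) exactly onto the published delay sequence
{4, 6, 7, 9, 12}; explicitly supplied delays take precedence.

## Trajectories and recovery (`stemsoil.recovery`)

For one column with 1983 load `L`, anchor-year (2013) input `I` and
output `O`, and delay `d`:

* input: linear from `(1983, L)` to `(2013, I)`, held constant
  afterwards (`input_after_anchor="constant"`; an extrapolating
  alternative, clipped at 0, is switchable);
* output: plateau at `L` (maximal output = maximal input, after the
  roughly constant 1973–1983 emissions) through `1983 + d`, linear to
  `(2013, O)`, then — default `output_after_anchor="track-input"` — the
  same slope until the line meets the input (or zero), following the
  input thereafter.  `constant` and `extrapolate` alternatives exist
  because the post-2013 construction is genuinely open;
* recovery: the first year strictly after the plateau with
  output ≤ input (ties count).  A column never exceeding its input is
  `always-balanced`; one still a net source at the horizon (default
  2050) is `not-recovered`.

`track-input` is the only post-anchor rule under which the degenerate
case (delay 0, `O = I`) makes output ≡ input, which we treat as the
defining sanity check of the construction.

**Regime note.** With the anchor endpoints held fixed, the recovery year
is non-decreasing in the historic load `L` exactly when `O ≤ I` — i.e.
when the column has already turned into a (marginal) net sink by the
anchor year, and the crossing happened on the 1983–2013 segment.  When
`O > I`, the post-anchor output slope `(O − L)/(2013 − 1983 − d)`
steepens with `L`, so a higher load would cross the constant input line
*earlier*.  The published qualitative result (higher historic load →
later recovery) therefore lives in the net-sink regime, and the default
scenarios and the monotonicity checks use `O < I` (defaults `I = 10`,
`O = 8` kg S ha⁻¹ yr⁻¹ — invented anchors; the real anchor fluxes are in
companion studies and are not reproduced here).

`cumulative_net_s` integrates (output − input) with the trapezoidal rule
on the annual nodes, which is exact for the piecewise-linear series;
positive totals mean net S release (source), in kg S ha⁻¹.

## Gradient analysis (`stemsoil.gradients`)

* Element stores: `concentration (mg g⁻¹) × bulk density (g cm⁻³) ×
  thickness (cm) × 0.1 → t ha⁻¹`, per half-open horizon [top, bottom) cm,
  optionally scaled by (1 − stone fraction); no coarse-fragment
  correction is applied unless that column is present.  Profile stores
  sum the five canonical horizons (0–3, 3–10, 10–20, 20–30, 30–50 cm);
  gaps are an error naming the missing horizon.
* Distance gradients: downhill values sorted by distance, verdict
  increasing/decreasing/non-monotone using non-strict comparisons with a
  1e-9 tie tolerance; an all-flat profile is reported explicitly as
  "non-monotone: flat"; uphill samples are listed separately.
* Temporal deltas: late − early per aligned (site, distance, horizon)
  cell, replicates averaged first; unmatched cells raise an error
  listing the offenders; missing values are dropped with a logged count,
  never imputed.
* Acidification front: with deltas ordered by depth, the front is the
  boundary between the deepest recovered horizon (Δ ≥ 0) and the first
  deeper acidifying one (Δ < 0), provided all deeper horizons acidify.
  Conventions: all Δ ≥ 0 → no front (profile recovered); all Δ < 0 →
  front at 0 cm (the whole profile still acidifies, so the front sits at
  the surface — this makes fronts comparable between near-stem and
  between-trees columns); alternating signs → flagged, no depth.
* IDW maps: inverse-distance weighting with default power 2, all samples
  used, exact-hit threshold 1e-9 cm.  Chosen for determinism; it cannot
  overshoot the sample range.  No kriging/variogram fitting (out of
  scope).
* `log_distance_gradient_fit`: OLS of a variable against ln(distance)
  over downhill samples of one horizon, reporting the fitted
  near-to-far change (gradient amplitude) and its standard error.

## Synthetic data (`stemsoil.synthetic`)

The generator encodes the study's qualitative patterns as noiseless
expectations plus optional independent Gaussian cell noise (no spatial
autocorrelation), fully determined by a seed:

* 1983 pH rises with downhill distance, linear in log-distance by
  default (steep change near the stem; a linear shape is switchable),
  amplitude `ph_far_1983 − ph_stem_1983` = 6.5 − 3.5 = 3.0 units —
  the bound "up to three units" is enforced on the config.  The
  amplitude attenuates with depth (factors 1.0…0.4).  Uphill columns sit
  outside the stemflow track and take the far-field value.
* 2010 topsoil pH runs from 5.5 at the stem to 5.0 at 3 m, so the
  topsoil delta is positive near the stem and negative at 150–300 cm.
  Below the topsoil, a per-distance count of "recovered" horizons
  (3/2/1/0/0 at 27/55/100/150/300 cm; 0 uphill) gains +0.2 pH, and all
  deeper horizons lose `deep_acidification_shift` (−0.4) — the
  acidification front sits deeper near the stem.
* Exchangeable Ca/Mg concentrations are depleted toward the stem with
  depth-increasing weights, so profile stores increase downhill
  (far-field store defaults: Ca 6.0, Mg 0.8 t ha⁻¹ — invented levels)
  and the deep-soil loss dominates near the stem.
* Total S concentration is uniform, so every profile stores exactly
  `s_profile_target` (default 0.85 t ha⁻¹, inside the published
  0.7–1.0 range), distance-flat by construction.  C stores ≈ 85 t ha⁻¹
  with C:N = 12.
* Grids are radially symmetric realizations of the topsoil profile with
  the stem at the origin; deposition histories wrap the deterministic
  trajectories, with noise clipped at 0.

What passing tests on these data do **not** show: real soils have
spatially correlated noise, inter-site differences, bulk-density
variation within horizons, and 1983 measurements digitized from figures;
the generator reproduces structure and printed ranges, never any real
site's values.

## Problem sizes and numerical choices

Default simulations are small by design: 68-year annual trajectories,
6 × 5 survey cells per year (× replicates), 200-trial parameter-recovery
runs with 20 replicates each, and 1000-replicate Monte-Carlo checks of
the noisy recovery year — all complete in seconds.  Noise defaults to 0
(opt-in), replicates to 1.  Generated values are clipped into the type
invariants (pH ∈ (2, 9), bulk density ∈ (0.1, 2.5), concentrations ≥ 0)
with a logged count.  Trajectory ties at exact float equality count as
recovered; the plateau end is carried as metadata and only inferred from
the leading constant run when absent.

## Known limitations

* The published recovery years (2034/2029/2020; the 2006 sink switch at
  27 cm) depend on anchor fluxes from companion field studies that are
  not printed anywhere we can consume; the package reproduces the
  *construction* and its qualitative ordering, not those calendar years.
* Annual resolution only; no storm-event hydrology, no process-based
  sulfate adsorption/desorption or organic-S mineralization kinetics —
  the budget model is phenomenological.
* No canopy interception model: stand-level TF/SF are inputs.
* No significance testing of gradients and no geostatistics; figures are
  the user's concern (dense-grid CSV export only).
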