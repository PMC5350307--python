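# Methods

## Model structure and assumptions

`reedcarbon` tracks two carbon pools of a monospecific *Phragmites australis*
stand over one growing season (April 1 – October 31, 214 days): the
aboveground shoot stock `PaC` and the belowground rhizome/root stock `PbC`,
both areal densities in gC m⁻². The stand is treated as horizontally
homogeneous; there is no litter or soil pool as tracked state (dead and
decayed carbon leaves the system), no nutrient limitation, and no
spatial structure across reed platforms and ditches.

Eight processes connect the pools to each other and to the atmosphere:

| process | form | source pool | θ |
|---|---|---|---|
| photosynthesis | logistic × Michaelis–Menten (CO₂, light) | PaC | 1.09 |
| translocation (transfer) | first-order | PaC | 1.07 |
| reactivation (react) | first-order | PbC | 1.07 |
| shoot respiration | first-order | PaC | 1.07 |
| rhizome respiration | first-order | PbC | 1.09 |
| shoot mortality | first-order | PaC | 1.05 |
| standing-litter decay | first-order | PaC | 1.05 |
| rhizome mortality | first-order | PbC | 1.05 |

Every rate is multiplied by an Arrhenius factor θ^(T − 20 °C), so all
processes accelerate with warming but at different sensitivities:
assimilation and rhizome respiration respond most strongly (θ = 1.09),
mortality and decay least (θ = 1.05). Translocation and reactivation are
internal exchanges and cancel exactly in the whole-plant carbon balance;
this is asserted per-step in the tests.

The carrying capacity of the shoot pool is the model's link to water
management: a tent function of water depth `d`,
`CarryaC(d) = carrya_max · (waterdepth_max − |d − depth_opt|/2) / waterdepth_max`,
peaking at the suitable growth depth (0.8 m, equal to the 7.3 m minimum
ecological level on the Dagu datum minus the 6.5 m zero-depth datum) and
declining linearly and symmetrically either side. The single continuous
formula is used everywhere; its value at the optimum is `carrya_max`
exactly, so no special-case branch is needed. It is floored at 1 gC m⁻²
so the logistic factor (1 − PaC/CarryaC) stays finite at any depth.

Reactivation is applied year-round. Because rhizome remobilisation is
biologically an early-season process, an optional gate
(`react_window_end`, a day index after which the flux is zero) is
available but off by default; the default follows the printed first-order
form with no time dependence.

## Integration and numerics

The update is explicit (forward) Euler with dt = 1 day — the scheme the
state equations are written in and the default of graphical
system-dynamics tools. `dt` is configurable to any value that divides one
day evenly; forcing is held constant within a day, and the trajectory
reports end-of-day states plus day-mean fluxes so the daily mass balance
Δ(PaC+PbC) = Σ(boundary fluxes)·1 d holds to round-off at any dt. A
robustness test halves dt and requires end-of-season stocks to move by
less than 1% (measured ≈ 0.03–0.07% under defaults). Stocks are clamped
at zero after each step with a logged warning; under default parameters
clamping never triggers.

## Parameters

Defaults (units g g⁻¹ d⁻¹ unless noted): initial stocks PaC₀ = 103,
PbC₀ = 1650 gC m⁻²; carrya_max = 2450 gC m⁻²; depth_opt = 0.8 m;
waterdepth_max = 1.8 m; CO₂ half-saturation 300 ppm; light half-saturation
6 MJ m⁻² d⁻¹; transratio = 0.20; mortalrate_pa = mortalrate_pb = 0.001;
decayrate_pa = 0.005; reference temperature 20 °C (fixed). These are the
published calibrated values for Baiyangdian reed stands.

Three rates have no published value — the reactivation rate `reratio` and
the two maintenance-respiration rates `mrespiratio_pa` / `mrespiratio_pb`.
They default to 0.005 g g⁻¹ d⁻¹, a mid-range first-order loss rate for
perennial macrophyte tissue, and are the natural calibration targets; their
calibration bounds are [0, 0.05]. All other bounds follow the published
ranges (`DEFAULT_BOUNDS`). With these defaults the belowground pool grows
well beyond its initial magnitude by October — the strong translocation
rate (0.20 d⁻¹) dominates rhizome losses — so absolute belowground values
should be read as index numbers until the respiration/reactivation rates
are calibrated against field data; the phenology (August shoot peak,
October rhizome peak) and all scenario contrasts are insensitive to this.

## Synthetic forcing

The generator emulates a temperate continental monsoon growing season:
daily air temperature is an annual sinusoid (mean 13 °C, amplitude 15 °C,
peak at day-of-year 196, i.e. mid-July) plus i.i.d. Gaussian noise
(σ = 2 °C) from a seeded generator; solar radiation is constant at
14.67 MJ m⁻² d⁻¹ (the published value, read as a daily mean — the 6 MJ
half-saturation constant only makes sense on a daily scale); CO₂ is
constant at 400 ppm; water depth is a base level plus stepwise management
segments, clamped at 0 m. Noise is applied to temperature only.

What this does *not* emulate: autocorrelated synoptic weather, cloud-driven
radiation variability, the CO₂ seasonal cycle, or hydrographs with gradual
stage changes. Passing tests therefore demonstrate the process structure
and its directional responses, not skill against any particular year's
meteorology; scenario results are read as signs, orderings and recovery
patterns, never as percent figures transferable to the field.

## Scenario engine

A scenario is a depth policy; its baseline is the identical forcing with
depth held at the suitable growth depth, so every trajectory difference is
attributable to the policy. Scores are daily percent changes
100·(X_scen − X_base)/X_base per pool (undefined and flagged on any day the
baseline stock is zero), with season extremes, peak months and end-of-season
stocks summarised. Season windows are the standard temperate-zone months —
spring Apr 1–May 31, summer Jun 1–Aug 31, fall Sep 1–Oct 31 — and are
configurable; the winter harvest period lies outside the simulated window
and is not represented. The standard catalogue crosses the four windows
with offsets ±0.1/±0.3/±0.5/±0.8 m, raises and drawdowns run separately
(32 scenarios, ≈ 1 s).

## Calibration

The objective is the sum of squared residuals between simulated and
observed stocks at the observation dates, both compartments pooled;
optional per-compartment variance normalisation equalises the leverage of
the rhizome pool (≈ 10× the shoot pool in magnitude). Minimisation is
derivative-free Nelder–Mead within box bounds, from 8 seeded starts by
default (the default parameter vector plus uniform draws within bounds);
non-convergence is flagged and the best point returned. Simplex
tolerances are 10⁻⁶ on both parameters and objective — comfortably below
the precision sparse noisy stock data can support, without letting noisy
objectives run every start to the iteration cap. The default free
set is {transratio, reratio, mrespiratio_pa, mrespiratio_pb, decayrate_pa};
Arrhenius bases and Michaelis–Menten constants stay fixed.

The harness is verified by parameter recovery: monthly observations
sampled from a run with known truth must return the hidden translocation
rate essentially exactly when noiseless, and with median error within 20%
across 20 seeded replicates under 5% multiplicative observation noise.
Recovery of a single parameter does not establish joint identifiability of
the full free set — respiration and reactivation rates trade off against
each other on sparse data — which is why the fit report marks parameters
that land on a bound.

## Determinism and problem sizes

All randomness (forcing noise, calibration starts, observation noise) flows
through seeded `numpy` generators; identical configuration and seed give
bitwise-identical CSV outputs. The test suite and the acceptance script run
on a 214-day season, a 32-scenario catalogue, and 20 calibration
replicates of a single free parameter — sizes chosen so the whole suite
completes in a few minutes on one CPU while still exercising every code
path at the full season length.

## Known limitations

- No litter/soil pools, methane pathway or carbon-emission bookkeeping;
  carbon leaving the plant is not tracked further.
- The carrying capacity responds to depth instantaneously; real stands
  integrate water stress over days to weeks.
- Forward Euler at dt = 1 day is adequate for the default rates (verified
  by step-halving) but can overshoot the carrying capacity by one step's
  growth when rates are pushed to their upper bounds.
- The belowground pool's absolute trajectory depends on three uncalibrated
  rates (see Parameters); conclusions should rest on contrasts between
  scenarios, which share those rates.
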