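# Methods

## The attribution question and the model's answer

The package asks: how much of the change in agricultural topsoil
(0–30 cm) organic carbon between 1919 and 2018 would the climate record
alone produce, holding land use, management and carbon-input regime fixed?
The answer is constructed per site from four ingredients: a five-pool
first-order turnover model stepped monthly under climate-dependent rate
modifiers; an analytical steady-state initialisation that ties the
present-day observed stock to an equilibrium carbon input; a backcast that
integrates the model through the historical climate in reverse; and two
input scenarios that bracket how net primary production (NPP) may have
co-varied with climate.

Because every monthly update is *affine* in the pool vector and linear in
the carbon input, three things follow that the implementation leans on:
the periodic steady state under a 12-month cycle is a single 4×4 linear
solve; the equilibrium input for a target stock is one division; and mass
balance (input − CO₂ = change in active stock) holds to rounding error at
every step, which the tests assert at 1e-10 per month.

## Turnover parameterisation

Standard published constants, all injectable through `RothCParams` so an
alternative set can be supplied bit-exactly:

| quantity | value | unit |
|---|---|---|
| decomposition rates k (DPM, RPM, BIO, HUM) | 10, 0.3, 0.66, 0.02 | yr⁻¹ |
| temperature factor a | 47.91/(1+exp(106.06/(T+18.27))), 0 below −18.27 °C | – |
| moisture factor b | 1 → 0.2 linearly beyond 0.444 of the deficit capacity | – |
| deficit capacity | (20 + 1.3·clay − 0.01·clay²)·depth/23; ÷1.8 bare | mm |
| open-pan fraction of PET | 0.75 | – |
| cover factor c | 0.6 vegetated, 1.0 bare | – |
| CO₂/(BIO+HUM) split x | 1.67·(1.85 + 1.60·e^(−0.0786·clay)) | – |
| retained split | 46% BIO, 54% HUM | – |
| DPM:RPM input ratio | 1.44 arable, 0.67 grassland | – |
| inert pool | IOM = 0.049·SOC^1.139 | Mg C ha⁻¹ |

Topsoil depth defaults to 30 cm; the 23 cm reference deficit capacity is
scaled by depth/23. Moisture accounting is chronological: excess rain
pays the deficit down, dry months deepen it up to the capacity; under bare
soil the deficit cannot grow past capacity/1.8 but an existing larger
deficit persists. The deficit at the start of the simulation is the
periodic value of the climatological year — hydrology does not begin in
January 1919 — which also makes a trendless forcing exactly periodic from
the first month.

MIAMI NPP uses the coefficients as printed in its source here:
NPP_T = 3000/(1+exp(1.315−0.0119·T)), NPP_P = 3000·(1−exp(−0.0000664·P)),
NPP = min. Only NPP *ratios* enter the pipeline, so the unit cancels; the
tests assert schedule invariance under rescaling. With these coefficients
the precipitation branch half-saturates only near 10⁴ mm, so NPP is
water-limited except in very wet climates (≳4000 mm at temperate
temperatures); the synthetic world's wettest zones are therefore the
temperature-limited ones.

## Spin-up

The present-day stock is assumed to be the equilibrium of the reference
climate — deliberately, to exclude any land-use legacy from the
attribution. The reference cycle is built from the full 1919–2018 series.
Rather than averaging the climate and then computing modifiers, the
spin-up averages the *monthly propagators*: the update matrix is linear in
the survival fractions exp(−k·a·b·c/12), so the per-calendar-month mean
survival gives the exact mean propagator (exact under serial independence
of months). This matters because the moisture factor is a nonlinear,
thresholded function of precipitation: the steady state of the
mean-climate cycle is *not* the attractor of the noisy century, and
anchoring there leaves a trend-independent transient of up to ±1 Mg C ha⁻¹
at deficit-prone sites that would contaminate the attributed change. With
the mean-propagator anchor the residual artifact, measured on a trendless
but noisy savannah world, is below 0.1 Mg C ha⁻¹.

The anchor phase matches the integration direction: the backcast departs
from the fixed point of the *reversed* reference cycle, so a trendless
series leaves the stock exactly unchanged (the tests require
|Δ| < 1e-6 Mg C ha⁻¹; achieved ≈ 1e-12).

`invert_cinput` computes IOM from the target stock, solves the unit steady
response once, and divides. A 2000-year brute-force run agrees with the
analytical steady state to better than 0.01%, and a 1000-year replay from
the inverted equilibrium holds the target stock to 0.1%.

## The backcast, and why it is not a literal inversion

Two readings of "run the model backwards" exist:

1. **Algebraic inversion** of each monthly affine update, reversing time
   exactly. This is implemented (`rothc.backward_active`) but *cannot* be
   iterated month-by-month over a century: each backward month multiplies
   floating-point error by exp(k·a·b·c/12) per pool — about e¹⁰⁰⁰ over
   1200 months for DPM — and in fact the exact preimage of an arbitrary
   end state is astronomically large, because the forward dynamics forget
   fast-pool history within months. The function therefore inverts the
   *whole-horizon* affine map x_T = P·x₀ + q by singular-value-truncated
   least squares about a reference state: directions the dynamics still
   remember are matched exactly, forgotten directions stay at the
   reference, and their contribution to a replayed end state is below
   machine precision by construction. For any end state that is reachable
   by a forward run, forward∘backward is the identity to ~1e-12 relative
   (asserted at 1e-6 in the tests); for unreachable end states no bounded
   reconstruction can do better than leaving the unreachable fast-pool
   component as a residual.

2. **Time-reversed integration**: run the ordinary decaying dynamics
   through the climate months in reverse chronological order, so that a
   warming history is experienced as cooling. This is what the pipeline's
   `backcast_site` does. It is unconditionally stable, keeps pools
   non-negative, and under a warming century reconstructs higher past
   stocks — the attributed loss — with magnitudes limited by the slow
   pools' memory, which is the scientifically meaningful behaviour.

Stocks are stored at 1919 (start of period) and at the ends of 1929,
1939, …, 2009 and 2018. Centennial change Δ₁₀₀ = SOC(2018) − SOC(1919);
relative change uses the reconstructed 1919 stock as denominator. The
1968 stock used by the split-period rates is interpolated linearly between
the 1959 and 1969 marks. Input scenarios: `const` applies Cin_equi every
year; `var` scales by NPP(t)/NPP_ref (period mean), so the var schedule's
century mean equals Cin_equi identically. Annual inputs are distributed
over months by the vegetation-cover weights (uniform allocation is
available).

## Synthetic world

The generator emulates the statistical structure of the real driving data
at desk scale; it does not attempt spatial correlation or geography.
Defaults (the study conditions): 500 sites across ten Köppen zones on a
regular grid; zone-dependent SOC means rising towards cold zones
(15–110 Mg C ha⁻¹, clipped to 10–150); clay ~N(22, 12) clipped to 2–60%;
70% arable / 30% grassland. Climate per site: sinusoidal seasonality
around the zone normal, secular warming drawn as N(1.03, 0.35) °C/century
(the 1.03 matches the observed mean trend at the assessed points;
the spread represents spatial heterogeneity of land warming), zero-mean
precipitation trends with 5%/century site spread, monthly noise of 0.6 °C
and 25% CV. PET is standard Thornthwaite (per-year heat index, no
day-length correction), so PET co-trends with warming at a few %/°C.
Monthly cover weights are a wrapped Gaussian around midsummer whose width
shrinks with latitude; a month counts as covered above a 0.05 weight.

Zone normals are realistic mid-range values with two deliberate wet
choices: rainforest (Af, 5500 mm) and subpolar maritime (Cfc, 4000 mm)
are wet enough to sit on the temperature-limited NPP branch given the
printed MIAMI coefficients, so both limitation branches are exercised.

What the synthetic world does not carry over from real data: spatially
correlated climate fields, observed precipitation/water-balance trend
patterns, real Köppen geography, management or land-use change. Passing
tests therefore demonstrate internal consistency and the mechanisms of the
attribution — not the real-world magnitudes, which depend on the actual
climate record. One documented consequence: under uniform synthetic
warming with stationary precipitation the savannah zone (Aw) *gains*
carbon on average (+0.8 Mg C ha⁻¹), because its dry-season moisture
limitation of decay deepens (mean b −5.3% between century halves) faster
than temperature accelerates decomposition (mean a +2.6%) — the same
moisture-limited-decay mechanism that produces gains in drying regions in
the full analysis. All other zones lose carbon under both scenarios.

## Geothermal validation protocol

The warming-gradient module reproduces the validation design: estimate the
equilibrium input from the unwarmed reference stock and a 1998–2018
climatology, then add each warming increment (0.6, 1.8, 3.9, 9.9, 16.3,
40 °C) to every monthly temperature and solve the new periodic steady
state, keeping the reference input (`const`) or rescaling it by annual
MIAMI NPP (`var`). The measured Icelandic stocks and station weather are
not public in printed form, so the module ships a clearly labelled
*synthetic* cold-maritime fixture (MAT 5 °C, damped seasonal cycle,
3900 mm — wet enough to be NPP temperature-limited, as the protocol
presumes for this cold site); real observations can be supplied as a CSV
of (delta, stock) replicates. Relative RMSE is normalised by the mean
observation (per-point normalisation available). Soil: 8% clay,
grassland input partition.

## Reporting and statistics

Zone summaries use unweighted means and sample standard deviations (n−1)
per zone × scenario, in conventional Köppen table order; empty zones are
logged and omitted. Driver regressions are ordinary least squares over
all 2⁷−1 non-empty subsets of {initial SOC, MAT, MAP, water balance,
ΔMAT, ΔMAP, Δwater-balance}, selected by minimal AIC; "Δ" is the OLS slope
of the annual series × 100 years. Exact collinearity is resolved by
dropping the offending predictor with a warning; residual quantiles
(5/25/50/75/95%) are attached rather than any automated normality
rejection. Zone-level observations are the default (site-level optional).
Spatial aggregation averages per-site changes over half-open 0.1° cells
registered to multiples of the cell size; output is CSV plus a plain
single-band float TIFF.

## Numerical choices and degenerate inputs

- Backward SVD truncation: relative cutoff 1e-10 on singular values of the
  horizon propagator; for a 12-month horizon everything is retained (the
  inverse is exact), for a century only the slow directions survive.
- Steady-state solve fails (singular I − A) only if decomposition is zero
  all year; this raises rather than returning a pseudo-solution.
- Negative reconstructed pools are flagged per site, never clipped.
- Negative precipitation/PET, gap months (reported by year-month and
  site), cover weights not summing to 1, stocks at or below IOM, and NPP_ref
  = 0 (input scaling undefined) all raise with context.
- Problem sizes: the default world is 500 sites × 1200 months (≈20 s for
  both scenarios); brute-force oracles in the tests use 1000–2000
  simulated years at single sites.

## Known limitations

- Steady-state initialisation is an idealisation; the attribution is
  conditional on it, and the anchor-consistency transient (see Spin-up) is
  suppressed but not exactly zero under serially correlated moisture.
- No CO₂ fertilisation of NPP, by design; no land-use change, erosion,
  management, or sub-monthly dynamics; no microbial or acclimation
  extensions to first-order kinetics.
- Thornthwaite PET is temperature-driven and tends to overstate the PET
  response to warming relative to radiation-based formulations; the
  moisture-channel effects in the synthetic world should be read with that
  in mind.
- The Köppen label of a synthetic site is assigned by configuration, not
  re-derived from its generated climate.
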