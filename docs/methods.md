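# Methods

## Balance model and booking conventions

The package closes, for each element (TN, TP, DSi, TOC, and optionally
the dissolved N and P fractions), reservoir and calendar year,

    L_R + L_DD + L_At (+ transfers) = L_Out + R(E),

with all loads in metric tonnes per year. Retention `R(E)` is derived,
never supplied, so the closure `input − output − retention = 0` holds
exactly for every budget the pipeline emits; it is validated in the
budget constructor. Negative retention is reported as *elimination*, as a
percentage of input; the two percentage fields are mutually exclusive. A
zero input with nonzero output leaves both percentages undefined and
flags the budget instead of dividing by zero.

Transfers inside a cascade — the hypolimnetic supply of a downstream
reservoir and reverse pumping — are booked symmetrically: the pumped load
is an input of the upstream reservoir *and* an output of the downstream
one in the same year. Under this booking the cascade-level balance, whose
input counts only external sources and whose output is the final
outflow, is algebraically invariant to pumping magnitude and timing, and
the complex retention telescopes to the sum of the partial retentions.
This is the only booking under which pumping affects partial balances
without affecting the complex, which is the physically correct behaviour
for a closed recirculation. Groundwater exchange and cyanobacterial
N-fixation have no terms: the model targets reservoirs outside
groundwater influence with mesotrophic, fixation-poor plankton.

Dates are calendar dates; the balance year is the calendar year. Leap
days are ingested and summed like any other day, but the unit-conversion
constant in stock-change and areal-rate arithmetic is fixed at 365 days
so that the conversion is identical across years.

## Loads

Daily load = concentration (g m⁻³) × daily mean discharge (m³ s⁻¹) ×
86400/10⁶ (t day⁻¹); annual loads are sums of daily loads, never mean
concentration × mean flow, which is biased when concentration covaries
with discharge. Concentrations between sampling days are interpolated;
three estimators are exposed because the choice is a genuine degree of
freedom in load estimation:

* **linear** (default) — linear in time, nearest value extended beyond
  the sampled span. The minimal-assumption estimator.
* **step** — previous-sample hold, appropriate for concentrations that
  change at discrete events.
* **flow_stratified** — ordinary least squares of concentration on
  log-discharge evaluated on the daily hydrograph, plus a
  linearly-interpolated residual correction. The correction makes the
  method exact at sampling days (an invariant shared by all three
  methods, so observed values are never contradicted); when samples lie
  on the regression line it reduces to the plain fit.

Load uncertainty combines component percentage errors *additively*
(sampling 15, analysis 2, flow 2 → ±19 %), a deliberately conservative
cumulative error; retention uncertainty, in tonnes, is propagated by root
mean square over the absolute errors of the loads entering the
difference. The two schemes are distinct on purpose: the first bounds a
single estimated quantity, the second combines independent errors of a
sum/difference.

Loads are kept at full precision internally; rounding to whole tonnes and
whole percent (half-up) happens only in presentation code.

## Sedimentation and ledgers

Phosphorus anchors deposition because it lacks a gaseous phase:

    ΔP    = (P_{n+1} − P_n)·V_R/Δt · 365/10⁶   (t yr⁻¹)
    N_sed = (P_ret − ΔP)·(N:P)
    C_sed = N_sed·(C:N)

ΔP is antisymmetric in its concentration pair and telescopes: summing
ΔP·Δt/365 over consecutive intervals gives the total stock change —
both properties are tested. The sediment N:P and C:N mass ratios are
*required configuration*; the shipped defaults (N:P = 3.03, C:N = 11.8)
are reconstructions back-computed from a published 110 t N / 1300 t C
deposition pair and should be replaced with measured values for any real
application.

Deposition is split between the backwater and lacustrine zones by a
configurable fraction (default 2/3 into the backwater, where roughly
twice as much sediment accumulates). Presentation rounding of the shares
is *reconciled*: the backwater share is rounded half-up to the element's
reporting unit (1 t for N, 10 t for C by default) and the lacustrine
share absorbs the difference, so shares always sum to the rounded total.

Denitrification enters as areal rate × effective area, both
configuration: empirical rates for such systems fall around
4–5 g N m⁻² yr⁻¹, and the effective sediment area need not equal the
nominal surface area (different published load/rate pairs imply
effective areas between ~17.5 and ~22 km² for the reference system, so
neither value is hard-coded as correct).

The ledgers close exactly by construction: retention − Σ named terms −
indefinite = 0. The nitrogen ledger partitions retention into
sedimentation and denitrification; the phosphorus ledger splits TP
retention into biomass-mediated (equal to phosphate retention, on the
assumption that retained phosphate passes through phytoplankton) and
directly-settling particulate P; the carbon ledger confronts retained TOC
with stoichiometric deposition, attributing any excess to autochthonous
production. Residuals are reported, not suppressed — a negative
indefinite nitrogen term, for instance, indicates nitrogen leaving
storage through coupled nitrification–denitrification.

## Stoichiometric diagnostics

Molar ratios use atomic masses N 14.007, P 30.974, Si 28.086, C 12.011.
A zero denominator yields an undefined (flagged) ratio, never infinity.
Thresholds are configuration with empirical defaults: DSi depletion below
0.7 g m⁻³ (strict inequality — a value at the threshold is not
depleted), N excess above molar N:P = 16, and silicon limitation when
depletion coincides with Si:N < 1.07 and Si:P < 17.2. The Pearson screen
classifies two-sided significance into p < 0.001/0.01/0.05 tiers
(two-sided is the conventional choice absent a directional hypothesis);
cells with n < 3 or a constant series are undefined, and non-significant
cells are displayed as dashes.

## Synthetic campaign generator

The generator emulates a hypolimnetically coupled two-reservoir cascade:
upper reservoir 502 × 10⁶ m³ (depth 22 m, HRT 215 d, mean supply
35 m³ s⁻¹, three major affluents carrying 90 % of the water plus three
minor), lower reservoir 10 × 10⁶ m³ (depth 5 m, HRT 6 d, 90 % fed by the
upper one's outflow), sporadic reverse pumping (default two 4-day events
per year at 20 m³ s⁻¹).

Flows: sinusoidal season with an early-spring maximum (amplitude 0.4,
peak around day 80) × lognormal day noise (CV 0.3). The inter-reservoir
and dam-outflow series are defined from the inflows, perturbed by a small
annual storage drift (CV 2 %), so the cascade water balance closes to
within that drift and hydraulic retention (W_ret) varies between years.

Chemistry: per-element true annual external inputs default to TN 1700,
TP 90, DSi 2150, TOC 2700 t yr⁻¹ with riverine shares 0.87/0.81/0.81/0.90
(the remainder booked as direct-drainage and atmospheric side loads,
split 90/10 between the reservoirs). Daily true concentrations are shaped
— TOC with a positive discharge dependence (c ∝ Q^0.4, reflecting the
strong TOC–flow coupling such systems show), N and P flow-independent and
non-seasonal (their loads being dominated by point/nonpoint sources), DSi
with a winter maximum and a summer epilimnetic drawdown deep enough to
cross the 0.7 g m⁻³ threshold — then scaled per route and year so the
true loads hit their targets exactly. Outflow concentrations are scaled
to impose true retention fractions (defaults: upper 0.15/0.25/0.15/0.12
for TN/TP/DSi/TOC, lower 0.02), applied to each reservoir's external
throughput so that pumping recirculates mass without creating or
destroying it; the complex-level truth is therefore pumping-invariant by
construction.

The observed dataset samples the daily truth at a jittered cadence: gaps
of 7 + 35·Beta(3,1) days (support 1–6 weeks, mean ≈ 33 d, hence ~33
visits per 3 years) with lognormal, mean-one measurement noise
(CV 15 %, mirroring the dominant sampling-error component). Setting the
mean gap to the window minimum degenerates to a fixed cadence (weekly,
daily), and zero noise with daily sampling reproduces true loads to
machine precision — the lossless limit used as a pipeline self-test.

What the generator does *not* emulate: rainfall–runoff dynamics and storm
hysteresis, rating-curve errors, within-reservoir spatial gradients,
sediment diagenesis, or ecological feedbacks between limitation and
uptake. Passing recovery tests therefore demonstrate that the estimation
chain is unbiased and adequately precise under the stated noise model,
not that real campaigns achieve the same accuracy.

## Problem sizes and numerical choices

Tests run the default three-year scenario (≈1100 days × 12 routes); the
Monte-Carlo recovery check uses 100 seeds of that scenario for total
nitrogen, for which the median absolute complex-retention-percentage
error is required to stay within 5 points and ≥95 % of estimated annual
loads within the ±19 % band. Budget and ledger closures are asserted at
1e−9 relative; the Pearson screen is checked against a direct
covariance-quotient evaluation at 1e−12. Half-up rounding uses decimal
arithmetic on the float's shortest repr, avoiding binary-representation
surprises at .5 ties.

## Known limitations

* Direct-drainage and atmospheric side loads are accepted as given
  scalars; their upstream estimation models are out of scope.
* No infilling of missing discharge days: gaps are errors, listing the
  missing days, not silently interpolated.
* Sub-annual (seasonal) balances are not reported; the periodization of
  the correlation screen is whatever reservoir-period table the user
  supplies.
* The flow-stratified estimator fits a single global
  concentration–log-discharge relation; no seasonal stratification of the
  rating is attempted.
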