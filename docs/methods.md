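# Methods

## Scope and model structure

`aquafoot` computes the green/blue/grey water footprint of irrigated crops
by two routes that share only the reference-ET series: a field-record route
(weather forcing → crop ET → footprint per harvest) and a raster route
(land-surface temperature → ET fraction → seasonal ET → footprint per
pixel). Both express results as m³ of water per tonne of yield. The package
deliberately stops at the simplified surface energy balance: ET fraction is
a linear rescaling of LST between two anchor temperatures, with no
aerodynamic resistance, roughness or iterative sensible-heat closure.

## Weather branch

**Reference ET.** The daily Penman-Monteith form with the grass-reference
aerodynamic coefficient 900 s m⁻¹ K and wind coefficient 0.34. The slope of
the saturation vapour-pressure curve Δ(T) and the psychrometric constant
γ(z) use the standard closed forms; γ defaults to a station elevation of
400 m (configurable) via the barometric pressure profile. Negative ETo
(possible under strong advection inputs) is clipped to zero. When a weather
table already carries measured ETo (e.g. from an eddy-covariance product),
that column is used as-is.

**Effective rainfall.** P_eff = P·(125 − 0.2 P)/125, applied per day and
clipped to [0, P]. The quadratic peaks at 312.5 mm/day, far above any
physically relevant daily total here; the clip removes the descending
branch from concern.

**Crop coefficients.** Profiles carry four stage lengths and four stage
values. Stage lengths are rescaled proportionally (largest-remainder
rounding, minimum one day per stage) to the field's actual sowing-harvest
span, because recorded field seasons are routinely shorter than tabulated
profile totals. The daily curve is flat at Kc_ini, ramps linearly to Kc_mid
across development (day j of n takes Kc_ini + (Kc_mid − Kc_ini)·j/n, so the
ramp lands on Kc_mid exactly at the stage boundary and the midpoint of an
even-length stage equals the tabulated development value), is flat at
Kc_mid, then ramps to Kc_late. Alternatives (ramping from day 0, or
centring samples at half-days) shift values by <0.01 Kc; the chosen
convention is the one whose midpoint reproduces the standard tabulated
development coefficients.

**Leaching requirement.** f = ECw/(5·ECe − ECw) uses the shallow (8 cm)
soil EC; converting the dimensionless fraction to a depth uses the
gross-application identity LR = CWR·f/(1 − f), i.e. the leaching water is
the fraction f of the gross application CWR + LR. This pairing of EC depth
and conversion is the only one that reproduces all four bundled maize field
records exactly, which is why it is the default. The identity
LR/(CWR + LR) = f holds exactly before rounding and is property-tested.
The bundled carrot leaching records do not reconcile under any tabulated EC
depth and are not used as checks.

**Grey water.** Single pollutant (nitrate), flat leach fraction α = 0.10 of
the applied rate AR, ambient standard C_max = 11.5 mg l⁻¹, natural
background 0. AR is a required input with a default of 125 kg ha⁻¹ used
only for synthetic runs — it is a plausible fertigation rate that puts grey
depths in the range of the bundled field records, not itself a recorded
value.

## Unit conventions

Physically, 1 mm of depth over 1 ha is 10 m³, and `convention="equation"`
(the default everywhere) uses that factor. The bundled reference
water-footprint table, however, reconciles with its own depth table only
under a factor of 100 m³ ha⁻¹ mm⁻¹; `convention="table"` exists to
reproduce those published numbers and every result object carries the flag
saying which convention produced it. The two differ by exactly ×10 on every
volume, which is asserted in tests. Similarly, the single nonzero green
component in the reference table reconciles from the raw rain-event depth
(8.9 mm), not from its effective-rainfall transform (8.77 mm); the
reproduction module therefore feeds the raw event depth, while the default
pipeline partitions with P_eff as defined.

## Raster branch

**Anchors.** The hot/cold anchor rule is this package's own: the cold
anchor is the mean LST of the coldest 1% among densely vegetated pixels
(SAVI above its 90th percentile inside the crop mask), the hot anchor the
mean of the hottest 1% among sparsely vegetated pixels (SAVI below its 10th
percentile scene-wide). All percentiles are configurable, provenance
(pixel counts, percentiles) is logged per scene, and a scene whose anchors
invert raises rather than producing negative fractions. Fixed anchors can
be supplied instead (the synthetic generator's 320 K / 295 K defaults),
which is how exact-recovery tests avoid conflating anchor estimation with
inversion. ETf is clipped to [0, 1].

**Seasonal upscaling.** Season days are partitioned by nearest scene date
(ties to the earlier scene) and each period contributes its ETo *total*
times the scene's ETf — the total, not the mean, is what keeps ET_lgp in mm.

**Yield.** Ordinary least squares of recorded yield on peak-season SAVI,
fitted on a seeded 60% split with diagnostics (R², RMSE%, NSE, MBE%)
reported for both splits; the published per-crop coefficients also ship as
ready-made models. Predictions are floored at 0, and pixels under a 1 t/ha
yield floor are masked before the WF division so border pixels cannot blow
up the footprint.

## Synthetic generator

The generator emulates the reference study conditions: a 13-month arid
climatology (monthly ETo 155-530 mm averaging 328.5 mm, annual rain 13.6 mm
in two events), six circular 50 ha fields (four maize, two carrot) on a
120×120 grid of 30 m pixels, and a 16-day scene cadence. Monthly ETo is
spread uniformly across each month's days (only monthly totals are
climatological inputs), so monthly sums are exact by construction;
temperatures and wind hold their monthly values. Inside an in-season field,
SAVI is the Kc curve affinely mapped so the initial stage sits at 0.10 and
the mid-season plateau at the per-crop peak (0.456 maize, 0.416 carrot);
LST encodes ETf_true = Kc/Kc_mid between the anchors; reflectance is
phenomenological (red fixed at 0.10, NIR solved from the target SAVI).
Background pixels carry SAVI 0.05 and LST at the hot anchor. Optional
Gaussian noise applies to LST and reflectance.

What passing recovery tests show: the SSEB inversion, upscaling and
accounting arithmetic are exact and mutually consistent. What they do not
show: performance on real scenes, where anchors must be estimated from
imperfect extremes, SAVI-LST coupling is not deterministic, atmospheres and
clouds intervene, and daily ETo varies within months. The generator makes
no attempt at radiative transfer, soil heterogeneity, or cloud gaps.

## Evaluation

R² is the squared Pearson correlation of the linear fit, RMSE and MBE are
the root-mean-square and mean signed differences with the fixed sign
convention predicted − observed, NSE = 1 − SSE/SST, and percentage forms
normalise by the observed mean. The p-value is the F-test of the simple
regression. A constant observed series makes R²/NSE undefined and raises;
crops with a single paired field are reported with their stats flagged
undefined rather than fabricated.

## Numerical and reporting choices

Rasters are float32 single-band TIFFs with nodata −9999 on a simple
north-up square-pixel grid; nodata propagates through every raster
operation. The float32 round-trip limits file-based agreement to ~1e-5
relative; exact-recovery tests therefore run in memory at float64.
Rounding to the reference tables' precision (integer m³ t⁻¹, two decimals
for green) happens only at the reporting layer. Pipeline stages are
deterministic given the run seed, which is the single source of randomness
(field salinity draws, scene noise, regression splits).

## Problem sizes

Tests and examples use the full default configuration (120×120 grid,
~25 scenes, 13 months of daily weather) — the whole pipeline runs in
seconds — with an 8×8 grid only for the per-pixel loop-equivalence oracle,
where the quadratic scalar loop is the slow reference, not the method.

## Known limitations

No soil-water balance, rooting dynamics or deficit irrigation; CWR assumes
demand fully met. Green/blue separation is a daily min/max partition, not a
soil-moisture accounting. Grey WF covers nitrate only. The two-path overlap
of the real satellite's revisit pattern (which yields ~32 scenes in 13
months rather than ~25) is not modelled; the cadence is a single 16-day
cycle. Scene stacks are gap-free; cloud masking is out of scope.
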