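# Methods

## Pigment-type spectra

Each population is characterized by a chlorophyll-specific absorption
spectrum on the photosynthetically active range, 400–700 nm at 5-nm band
centers (61 bands, treated as point samples; band integration is not
modeled). Spectra are parametric surrogates: sums of Gaussian pigment bands
(chlorophyll-a at 440 and 675 nm, phycocyanin at 620 nm, PUB at 495 nm, PEB
at 545 nm; default σ = 15 nm) over a small flat baseline. The PUB and PEB
amplitudes are solved in closed form so that the 495:545 absorption ratio
equals the requested PUB:PEB exactly (to rounding), under the constraint
that their summed amplitude is fixed (default 0.08 m² (mg chl)⁻¹, with
chlorophyll bands 0.030/0.020, phycocyanin 0.010, baseline 0.002 — magnitudes
typical of chlorophyll-specific absorption). PUB:PEB is operationalized
throughout as this 495:545 band ratio: it is the only version of the
chromophore ratio computable from a spectrum, and every quantitative anchor
in the package keys on it.

Defaults: BS 1.4, GS 0.4, CA endpoints 0.67 (green-acclimated) and 1.4
(blue-acclimated). The six CA state spectra are linear interpolations of the
endpoint spectra with weights (i−1)/5; state ratios are then strictly
monotone from 0.67 to 1.4 (the intermediate ratios are not equally spaced,
because a ratio of linear interpolants is not linear).

## Water-column model

A vertical column (default 20 layers × 10 m over 0–200 m) carries one
dissolved nutrient and eight biomass pools sharing one physiological
parameter set; only spectra differ.

**Optics.** Downwelling spectral irradiance decays by Beer–Lambert
absorption; the total coefficient sums pure seawater (a constant
literature-style table whose only load-bearing feature here is
a_w(545) > a_w(495), which makes clear water bluer with depth), an
exponential CDOM+detritus term (a(440) = 0.01 m⁻¹, slope 0.014 nm⁻¹), and
the chlorophyll-weighted sum of all pools' spectra (chl:C = 0.02 mg mg⁻¹).
Scattering is neglected: the B/G diagnostic rests on differential
absorption, and an absorption-only field keeps irradiance monotone in depth
band by band.

**Growth.** µ = µ_max · N/(N+k) · (1 − exp(−α·Φ/µ_max)) with Φ the
spectrally integrated absorbed quanta per unit carbon. Defaults:
µ_max = 1 d⁻¹, k = 0.05 mmol m⁻³, loss 0.1 d⁻¹ (half remineralized locally,
half exported), nutrient quota 0.0126 mmol N (mg C)⁻¹, bottom-layer supply
0.02 mmol m⁻³ d⁻¹, diffusive inter-layer mixing 0.5 d⁻¹. α = 15 is set so
that surface irradiance is moderately light-limiting (limitation factor
≈ 0.5 at the default surface PAR of 150 µmol photons m⁻² s⁻¹): in a fully
light-saturated column the pools' spectra would be irrelevant and no
light-color competition could occur, while a strongly light-starved column
would collapse biomass; moderate limitation is the regime in which spectral
fitness differences are expressed.

**Chromatic acclimation.** CA biomass hops between adjacent states toward
the target state, the argmax over states of absorbed quanta normalized by
each spectrum's band-integrated absorption (a spectral-shape match; ties
break toward the greener state). Because absorbed quanta are linear in the
PUB/PEB amplitude split, the instantaneous optimum is always an endpoint
state; intermediate states are occupied in transit and under vertically or
seasonally mixed light. The per-hop rate is q/τ with
q = gamma.ppf(0.95, 5) ≈ 9.154, calibrated so that a fully green population
places 95% of its biomass in the terminal blue state after exactly τ — the
acclimation duration, piecewise-linear in PAR through the culture anchors
(20 µmol → 6 d, 75 µmol → 3 d), clamped outside. The exchange conserves CA
biomass to machine precision.

**Time stepping.** Fixed-step explicit Euler, dt = 0.05 d, on a 360-day
calendar of twelve 30-day months (clean month boundaries for the monthly
means). Nutrient uptake in a layer is rescaled within a step if it would
overdraw the layer, so the per-step nitrogen balance
Δ(N + biomass-N) = supply − export holds to rounding. Non-finite states
abort with the offending pool named; negative values (possible only through
extreme parameter choices) are clipped with a logged count.

## Forcing scenarios

Surface irradiance is a PAR-normalized blend of a blue-peaked and a
green-peaked basis. The seasonal cycle moves both total PAR (±30%) and the
green weight; the latter's amplitude is the *color* knob that sets the
seasonal variance of B/G. The default baseline places the column in a
transitional light regime (mean green weight 0.45, color amplitude 0.8):
the seasonal swing crosses the blue/green tipping point, so the acclimator
retunes during the year — the environment in which flexibility is
observed to pay. The future surrogate scales nutrient supply by 0.7
(stratification proxy) and the color amplitude by 0.25 (spectral
stabilization); each knob can be moved independently.

## Diagnostics conventions

- **B/G with depth:** per-layer ratio, thickness-weighted mean over 0–200 m
  (default); the ratio of depth-averaged irradiances is available as
  `mode="ratio_of_mean"`. Cells with non-positive green irradiance are
  masked with a logged count.
- **Decadal statistics:** the 120-month window [nominal−5, nominal+5);
  annual variance is the mean over the 10 window years of each year's
  population variance (ddof = 0) of its 12 monthly values.
- **Classification:** exact Fisher-Jenks (dynamic programming over
  suffixes, ties resolved toward the smallest first break); breaks are
  fitted on the baseline epoch and reused for the later epoch, so class
  transitions reflect field change rather than break drift (refitting per
  epoch is a caller choice). Breaks are class maxima; value ≤ break →
  lower class.
- **Area statistics:** cosine-of-latitude cell weights by default; every
  function takes explicit weights, so pixel counting is one argument away.
- **Acclimation index:** a state is present at (cell, depth, month) when it
  holds ≥ 5% of the local CA biomass (the threshold is an explicit, logged
  parameter; "presence" needs an operational cutoff and 5% marks a state
  that is dynamically occupied rather than numerically residual). The raw
  index sums present-state counts over depth and month; normalization is
  min-max against the baseline epoch and deliberately unclamped elsewhere.
- **Concordance:** cells with an exactly zero sign are excluded and
  counted. MCC uses area-weighted counts (to match "% of ocean area"
  semantics; unweighted mode provided); a zero marginal gives MCC = 0 with
  a flag. Spearman ρ is the classical unweighted statistic with midranks.

## Synthetic generators

Generators emit their ground truth beside the data, so pipeline recoveries
are exact-expectation checks rather than statistical ones when noise is off.
The B/G generator prescribes per-cell trend signs (default 76% positive)
and seasonal-variance changes (default 64% decreasing) via a sinusoidal
seasonal cycle whose amplitude is halved or increased by half; monthly noise
is lognormal on irradiance so fields stay positive. The class-transition
generator plants k well-separated levels with sub-gap jitter and a per-class
sentinel maximum, so Fisher-Jenks breaks fitted on the baseline epoch bound
both epochs exactly and prescribed transition fractions are recovered to
machine precision. What these fields do *not* emulate: spatial covariance,
realistic seasonal phase geography, or feedback between biomass and light —
so passing recoveries validate the pipeline's bookkeeping, not the realism
of any mapped pattern.

## Problem sizes and numerical choices

Column experiments in the tests use 20 layers, 61 bands, dt = 0.05 d and
runs of 3–5 years — long enough for slow competitive sorting to express a
strict ordering between paired scenarios, short enough to iterate freely on
a laptop. The Euler/matrix-exponential comparison of the acclimation chain
uses dt = 10⁻³ d (global Euler error is first-order in dt; at the default
dt = 0.05 the chain is accurate to a few percent, ample for 3–6-day
transitions resolved by 60–120 steps).

## Known limitations

- One spatial dimension: no circulation, advection or horizontal transport;
  "gridded" analyses at global scale are exercised on synthetic fields.
- Single nutrient, fixed stoichiometry and chl:C, no temperature dependence,
  no photoinhibition, linear loss closure in place of explicit grazers.
- Absorption-only optics (no scattering, no Raman or inelastic terms).
- The CA target-state rule (normalized absorbed-quanta argmax) is one
  defensible reading of "matching the ambient color"; matching PUB:PEB to
  the local B/G directly is an alternative that differs only under strongly
  structured spectra.
- The 360-day calendar shifts annual frequencies by ~1.4% relative to a
  real year; all internal statistics use the same calendar consistently.
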