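# Methods

This note documents the science in `firegpp`: the model chain, its
assumptions, the parameters that matter, what the synthetic forcing does
and does not emulate, and the numerical choices.

## Scope and design

The package reproduces, at the scale of independent site columns, the
attribution logic used to quantify fire-pollution impacts on GPP: a
radiation stage (aerosol/cloud optics → surface direct and diffuse PAR),
a vegetation stage (multi-layer sunlit/shaded canopy with coupled
photosynthesis–conductance and flux-based ozone damage), and an
experiment layer (factorial arms, cloud-scaling sweep, perturbation
suite). Global chemistry-transport, reanalysis forcing, spectral
multi-layer radiative transfer, prognostic phenology and
aerosol–meteorology feedbacks are deliberately out of scope; the
attribution arithmetic is per-column, so site columns exercise it fully.

## Radiation

Single broadband PAR treatment: the PAR band carries 0.45 of the
extraterrestrial shortwave flux (configurable). One homogeneous layer
over a black surface is solved per timestep with delta-Eddington
two-stream scattering: the forward-peak fraction f = g² is folded into
the unscattered beam, the Eddington closure gives the coupled up/down
stream ODEs, and the single-layer boundary-value problem is solved
analytically by eigen-decomposition (overflow-safe for opaque cloud).
The direct beam follows Beer's law on the delta-scaled optical depth.

Component optics are fixed, representative broadband values
(configurable): scattering aerosol ω = 0.95, g = 0.65; absorbing aerosol
ω = 0.30, g = 0.60; liquid cloud ω = 0.9995, g = 0.85; Rayleigh τ = 0.10
(vertical, PAR band). Column mixing weights single-scattering albedo by
τ and asymmetry by scattering optical depth. Cloud optical depth is
τ_c = 3·LWP/(2·ρ_w·r_e) with r_e = 10 µm. Cloudy and clear sub-columns
combine linearly in cloud fraction (independent-column approximation),
matching the use of daily cloud fraction in the experiments.

Accuracy: against an independent Monte Carlo photon-transport solver
(Henyey–Greenstein sampling), total downward transmission agrees within
10% for τ ≤ 3 (worst case ~9% at τ = 3, µ0 = 0.5); the Rayleigh-only
column agrees to three decimal places. The scheme reproduces the
qualitative cloud-scaling behaviour: mean diffuse PAR rises with cloud
scaling, peaks near a factor of 1.5 for a ~0.7-cloud-fraction column
(where the fraction saturates and further scaling only thickens the
cloud), then falls.

## Canopy and leaf physiology

The canopy is divided into 20 layers (trapezoid nodes over cumulative
LAI). The sunlit fraction is f_sl = exp(−σL) with σ = 0.5/cosα (spherical
leaf-angle distribution); at zenith ≥ 90° it is defined as 0. Sunlit
leaves absorb the direct beam on projected area (σ·I_dir per leaf area)
plus local diffuse; shaded leaves absorb local diffuse only, attenuated
with its own extinction coefficient 0.72, so deep-canopy light is weaker
and more diffuse. Leaf PAR absorptance is 0.85. The 20-layer integral is
within 1% of a 2000-layer quadrature (tested).

Leaf assimilation uses the Farquhar C3 model (Rubisco- and
light-limited rates, Bernacchi-style Arrhenius kinetics, peaked
temperature response for Vcmax and Jmax with Hd = 200 kJ mol⁻¹ and
ΔS = 0.65 kJ mol⁻¹ K⁻¹, Jmax25 = 1.67·Vcmax25, non-rectangular
hyperbola with θ = 0.7 and quantum yield 0.3 e⁻/photon) or the Collatz
C4 model (light-, Rubisco- and PEP-limited). Dark respiration is
0.015·Vcmax25 with its own Arrhenius response. Stomatal conductance is
Ball–Berry, g_s = m·max(A,0)·h_s/c_s + b, with a fixed leaf
boundary-layer conductance of 2 mol m⁻² s⁻¹ for the CO2 path. The
internal CO2 is solved by a damped fixed point (50 iterations,
tolerance 10⁻⁴ µmol m⁻² s⁻¹) with a 60-step bisection fallback on the
supply–demand residual, which is monotone in c_i.

None of these constants are constrained by the study this package
re-examines; they are standard literature values per PFT, shipped in
`src/firegpp/data/pft_params.csv` (Vcmax25 between 30 and 70
µmol m⁻² s⁻¹, m = 9 for C3 / 4 for C4, b = 0.01 / 0.04 mol m⁻² s⁻¹).
GPP is reported gross (leaf dark respiration added back) in
µmol CO2 m⁻² s⁻¹ internally and g C m⁻² day⁻¹ at the reporting layer
(12 g C per mol CO2). A soil-moisture stress multiplier exists but is
off by default. There is no within-canopy nitrogen/Vcmax gradient, which
biases absolute GPP high for dense canopies; all shipped diagnostics are
relative (percent) responses, which are much less sensitive to this.

## Ozone damage

The flux-based scheme: fractional damage F = −a·(F_O3 − T_O3) above the
flux threshold, zero below; stomatal flux F_O3 = [O3]/(r_b + k·r_s) with
k = 1.67 (O3:H2O stomatal diffusivity ratio, from the scheme's source
literature). [O3] in nmol m⁻³ comes from ppbv via the ideal gas law;
r_b = 132·(d/u)^0.5 s m⁻¹ with leaf dimension d = 0.05 m; r_s = 1/g_s
converted to s m⁻¹. Damage multiplies assimilation by (1 + F), the
Ball–Berry coupling updates g_s, and the (F, g_s) pair is iterated with
0.5 damping to a 10⁻⁴ fixed point (≤ 50 iterations); the solution matches
an exhaustive 10⁻⁵-grid scan (tested). Damage is applied per leaf class
per layer, because the flux equation uses leaf-level r_s. Thresholds are
T_O3 = 1.6 nmol m⁻² s⁻¹ for woody and 5 for herbaceous PFTs.

The per-PFT sensitivity pairs (a_low, a_high) bracket species tolerance.
Their absolute scale is a calibration artifact, as the scheme's authors
intend: `firegpp.calibrate.calibrate_damage_scale` scales all pairs
jointly until the mean-sensitivity percent-GPP-per-ppbv slope of the
offline ozone protocol for deciduous broadleaf forest equals 0.27
%/ppbv, the centre of the observed envelope for temperate deciduous
trees. The calibration protocol is the mean slope over three 90-day
midlatitude-summer realisations; the resulting scale (2.396 on the
seed values) is versioned in the parameter file. Reported damage uses
the low, high, or central (mean of both solutions) sensitivity; central
± half-range is the uncertainty convention throughout. A variant with
evergreen-broadleaf coefficients reduced by 33%
(`PFTParams.with_scaled_damage(0.67)`) supports the tropical-tolerance
sensitivity case.

## Synthetic forcing

The generator emulates the statistical structure of the real drivers
without any external data. Meteorology: archetype mean states
(tropical_wet, midlatitude_summer, boreal_summer, arid) with
sinusoidal diurnal cycles and lag-1 autoregressive (ρ = 0.7) daily
anomalies; TOA insolation from Spencer-series solar geometry
(S0 = 1361 W m⁻²); prescribed sinusoidal seasonal LAI per archetype.
Pollution: background ozone as an AR(1) daily series with an
afternoon-peaking diurnal cycle; fire ozone flat inside a day-of-year
fire window with 10-day ramps, normalised so the in-window mean equals
the requested enhancement (default 5 ppbv, the magnitude of boreal
fire-season enhancements); AODs lognormal-AR(1) by component, with fire
aerosols (scattering-dominated, ~1:6 absorbing:scattering, reflecting
BC:OC emission ratios) confined to the fire window and sized so fires
contribute roughly a third to a half of fire-season AOD. Cloud: daily
(or 3-hourly) truncated-Gaussian AR(1) fraction plus LWP tied to
fraction; archetype climatologies span thin arid cloud (mean fraction
0.15, LWP 25 g m⁻²) to dense tropical cloud (0.80, 180 g m⁻²).

What the generator does *not* emulate: spatial covariance between sites,
synoptic weather organisation, correlated ozone–aerosol–cloud episodes,
drought stress, and real fire-emission timing. Passing tests therefore
demonstrate that the *response logic* (slopes, optima, orderings,
attribution algebra) behaves correctly under realistic marginal
statistics, not that the model reproduces any particular observed site
year.

## Experiments and protocols

Eleven factorial arms share one forcing realisation (NA/AA/FA without
ozone; NOH/NOL/FOH/FOL without aerosols; AAOH/AAOL/FAOH/FAOL with both);
fire attribution differences FA-type minus AA-type arms, combining
low/high damage arms as central ± half-range. The cloud-scaling sweep
runs 20 factors from 0 to 10 (aerosols off), scaling fraction
(capped at 1) and LWP jointly, and reports the GPP-maximising factor;
flat sweeps are flagged degenerate and ties break to the smaller factor.
The perturbation suite modifies the fire-aerosol/cloud drivers (BC05:
fire absorbing ×0.5, scattering ×1.05; BC20: ×2/×0.9; FA2/FA3: all fire
AOD ×2/×3; C00/C05/C20: cloud ×0/×0.5/×2; C3H: 3-hourly cloud) and
reports the fire-aerosol GPP effect under each.

Measurement protocols: (1) ozone slope — prescribed uniform O3 levels
20–100 ppbv against an ozone-free baseline, OLS of percent change on
concentration, 95% CI from the t distribution; (2) diffuse slope —
records filtered to diffuse fraction > 0.8 (≥ 100 required), GPP
averaged in 50 W m⁻² diffuse-PAR bins (≥ 3 records per bin), OLS on bin
means against bin-mean PAR, normalised by the mean GPP of the filtered
records; (3) diffuse optimum — clear-sky scattering-AOD sweep 0–3 in 20
steps, reporting the midday (±1 h) diffuse fraction of the
daily-GPP-maximising member. Slope estimators are exact on noise-free
linear inputs and invariant to record order (tested); coarse sweeps
agree with 10×-finer sweeps within one grid step (tested).

Single-season diffuse slopes scatter across forcing realisations about
as widely as the observed across-site envelope, so the acceptance-level
diffuse-slope diagnostic reports the median over seven independent
synthetic site-seasons — the analog of the per-PFT median across flux
sites. Problem sizes used by the shipped diagnostics: 90-day hourly
series for the ozone protocol, seven 90-day half-hourly site-seasons for
the diffuse protocol, one clear-sky day (LAI 5) for the optimum sweep.

## Numerical conventions and degenerate inputs

Zenith ≥ 90° gives zero fluxes and sunlit fraction 0 (not an error);
vacuum optical columns have albedo 1 and asymmetry 0 by convention;
diffuse fraction is defined as 1 when total PAR is 0; zero-baseline
percent changes raise a protocol error; flat cloud sweeps are flagged,
not silently resolved. The removable λµ0 = 1 singularity of the
two-stream solution is nudged; optical depths are capped at 500
(opaque). Time is hours since run start, calendar-free. All generators
and experiments are bit-reproducible for a fixed seed.

## Known limitations

Absolute GPP runs high for closed canopies (no N gradient, no water
stress); the net sign of the combined fire effect at a single site
depends strongly on the cloud regime and the fire O3/AOD mix, and a
cloudy midlatitude column can show aerosol fertilization outweighing
ozone loss — region-integrated conclusions cannot be read off one
column. The damage scheme is instantaneous (no cumulative dose memory);
the radiation scheme has no spectral resolution or aerosol–cloud
microphysics; C3H merely resamples cloud noise at 3-hour resolution
rather than resolving real diurnal cloud cycles.
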