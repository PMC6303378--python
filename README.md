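# firegpp

Fire smoke changes terrestrial photosynthesis through two opposing
pathways. Surface ozone formed in fire plumes enters leaves through
stomata and damages the photosynthetic machinery, while smoke aerosols
scatter sunlight and raise the diffuse share of photosynthetically active
radiation (PAR), which penetrates deeper into canopies and can *increase*
gross primary productivity (GPP) — the diffuse fertilization effect (DFE).

`firegpp` is a site-scale Python implementation of the full attribution
chain for quantifying these effects, aimed at land-carbon and
atmospheric-chemistry researchers who want a desk-scale, fully seeded
testbed rather than a coupled global model. It contains:

* a **synthetic forcing generator** (meteorology, ozone, aerosol, cloud
  scenarios for tropical, midlatitude, boreal and arid archetypes),
* a **single-band delta-Eddington radiation scheme** turning aerosol and
  cloud optics into surface direct/diffuse PAR,
* a **multi-layer sunlit/shaded canopy** with coupled
  Farquhar–Ball-Berry leaf physiology,
* a **flux-based ozone damage scheme**,
* the **factorial experiment matrix**, cloud-scaling sweep and
  aerosol/cloud perturbation suite used to attribute GPP changes to fire
  pollution, and
* the **measurement protocols** (GPP–O3 slopes, diffuse-PAR binning
  slopes, diffuse-fraction optimum).

## The model core

Per canopy layer, assimilation mixes sunlit and shaded leaves,

    A = f_sl · A_sl + (1 − f_sl) · A_sh,      f_sl = exp(−σL),  σ = 0.5 / cos α,

with `L` the cumulative leaf area index and `α` the solar zenith angle.
Sunlit leaves receive the unattenuated direct beam on their projected
area plus local diffuse light; shaded leaves receive diffuse light only,
attenuated as `exp(−0.72 L)`. Leaf rates `A_sl`, `A_sh` come from a
Farquhar C3/C4 model coupled to Ball–Berry stomatal conductance
`g_s = m A h_s / c_s + b`, solved to a consistent (A, g_s, c_i) fixed
point.

Ozone damage follows the flux-based (Sitch-type) scheme,

    F = −a · (F_O3 − T_O3)  if F_O3 > T_O3,  else 0,
    F_O3 = [O3] / (r_b + k · r_s),           k = 1.67,

so damage requires both high ozone *and* open stomata; the damage factor
(1 + F) feeds back on `g_s` and the pair is iterated to a fixed point.
Per-PFT sensitivities `(a_low, a_high)` bracket species tolerance; all
headline numbers use the central value of the low/high results with half
the range as uncertainty.

## Worked example

Run the eleven-arm factorial for one 90-day midlatitude summer site with
a 5 ppbv fire-season ozone enhancement and fire aerosols:

```python
from firegpp import forcing as fo, pft, experiments as ex

forcing = fo.generate_site_forcing(n_days=90,
                                   climate_archetype="midlatitude_summer",
                                   seed=1)
scen = ex.ScenarioConfig(base_o3_mean=30.0, fire_o3_delta=5.0,
                         n_days=90, seed=1)
params = pft.get_pft("deciduous_broadleaf_forest")
results = ex.run_factorial(forcing, scen.build(), params)
for name in ("NA", "FA", "FOH", "FOL"):
    r = results[name]
    print(f"{name:5s} GPP = {r.gpp_total:8.1f} g C m-2  "
          f"({r.delta_vs_reference:+.2f}% vs NA)")
for key, (central, half) in ex.fire_attribution(results).items():
    print(f"fire {key:8s}: {central:+.2f} +/- {half:.2f} g C m-2")
```

which prints

```
NA    GPP =   1987.5 g C m-2  (+0.00% vs NA)
FA    GPP =   2085.9 g C m-2  (+4.95% vs NA)
FOH   GPP =   1844.8 g C m-2  (-7.18% vs NA)
FOL   GPP =   1941.8 g C m-2  (-2.30% vs NA)
fire o3      : -15.52 +/- 7.67 g C m-2
fire aerosol : +27.71 +/- 0.00 g C m-2
fire combined: +8.73 +/- 9.43 g C m-2
```

`NA` is the clean-air reference; `FA` adds all aerosols; `FOH`/`FOL` add
all ozone at high/low damage sensitivity. The attribution lines difference
matching fire and non-fire arms: at this fairly cloudy midlatitude site
the seasonal fire-aerosol fertilization (+27.7 g C m⁻²) outweighs the
fire-ozone loss (−15.5 ± 7.7 g C m⁻²), and the combined effect is
positive with an uncertainty range that spans zero. The balance flips
with cloudier skies, higher background ozone or more absorbing smoke —
exactly the sensitivities the perturbation suite (`ex.perturbation_suite`)
explores.

A thin CLI wraps the same library:

```sh
firegpp generate --seed 1 --archetype arid --out arid_site
firegpp run --config run.toml --arms all --out run_out
firegpp diagnose slope-o3 --seed 1 --out slope.csv
```

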