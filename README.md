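# nasocond

Simulation of air conditioning in the nasal passage: steady laminar
inspiratory airflow with coupled heat and water-vapor exchange at the
mucosal wall, on parameterized synthetic passage geometries, with the
per-cross-section metrics used to compare how well different passage
anatomies warm and humidify inhaled air.

The nasal passage must bring inhaled air close to the state of the lower
airway — about 34 °C and saturation, i.e. a water mass fraction of 3.34% —
by the nasopharynx.  How well it does so depends on passage shape: a tall
cavity fed by a vertical vestibule through a narrow valve (the human-like
configuration) versus a long, low cavity fed by a horizontal vestibule
(the nonhuman-primate-like configuration).  `nasocond` lets you build such
passages parametrically, apply the classic virtual modifications (removing
the valve constriction; tilting the vestibule horizontal), and measure the
conditioning consequences under controlled ambient conditions — warm-wet
(30 °C, 60% RH), cold-dry (5 °C, 10% RH), and hot-dry (40 °C, 5% RH).

## The model

* **Flow** — incompressible steady laminar Navier–Stokes,
  ρ(u·∇)u = −∇p + μ∇²u, ∇·u = 0, solved with a collocated finite-volume
  SIMPLE scheme on a structured body-fitted mesh.  The nostril is a free
  (zero-gauge total-pressure) inlet; a uniform outward velocity is set at
  the pharyngeal outlet, derived if desired from the resting allometric
  relations TV = 7.69·BW¹·⁰⁴, f = 0.84·BW⁻⁰·²⁶, FV = 2·f·TV/CA.
* **Transport** — passive convection–diffusion of temperature T and water
  mass fraction F on the frozen flow field (one-way coupling).
* **Wall exchange** — a tissue layer at T_Tis = 34 °C, F_Tis = 3.34%
  behind an epithelial film (0.2 mm epidermis in the vestibule, 0.5 mm
  mucosa elsewhere; K_ep = 0.6 W/m·K).  Per wall face, conduction
  Q_ep = K_ep(T_Tis − T_S)/δ_ep, two-film evaporation
  W_bl = ρD_bl(F_S − F)/δ_bl with the surface fraction
  F_S = (aF_Tis + bF)/(a + b), a = D_ep/δ_ep, b = D_bl/δ_bl, and latent
  cooling Q_latent = −L(T_S)·W_bl with the cubic latent-heat fit
  L(0 °C) = 2500.79 kJ/kg.  The surface temperature balances the discrete
  fluid-side conduction against Q_total = Q_ep + Q_latent.
* **Metrics** — per-station extrema of T and F from nares to nasopharynx;
  the nasopharyngeal triple (T, MF, RH34), where RH34 = 100·MF/3.34 scores
  humidification against saturation at 34 °C; arithmetic cohort averages.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and known limitations.

## Worked example

Run the human-like preset under the cold-dry condition from the shell:

```sh
nasocond solve --preset human_like --condition cold_dry --outdir run_out --as-json
```

which prints

```json
{
  "cold_dry": [
    29.257730800269407,
    2.7195361036858734,
    81.42323663730161
  ]
}
```

— at the nasopharyngeal level the coldest air is still only 29.3 °C and
the driest air carries 2.72% water mass fraction, 81.4% of the saturation
reference: cold, dry air is *not* fully conditioned by the short passage.
Re-running with a halved cavity (`cavity_length=25`) degrades the triple
to about (27.0 °C, 2.40%, 71.7%), whereas removing the valve or tilting
the vestibule horizontal moves the mass fraction by only ~0.1 percentage
points — cavity length is the strong conditioning lever, vestibule
topology a weak one.  `run_out/` contains the per-station profile
CSV, the wall-state table (surface temperatures, evaporative fluxes), the
flow and scalar fields in legacy-VTK format, the boundary as STL,
residual histories, and a YAML echo of the exact configuration for
replay.

The same pipeline is available as a library:

```python
from nasocond import (PASSAGE_PRESETS, build_passage, mesh_passage,
                      FluidProperties, WallProperties, AMBIENT_PRESETS,
                      couple_flow_and_scalars, extract_profile,
                      nasopharyngeal_summary)

geom = build_passage(PASSAGE_PRESETS["human_like"])
mesh = mesh_passage(geom, spacing=0.7)  # mm
flow, fields = couple_flow_and_scalars(
    mesh, FluidProperties(), WallProperties(),
    AMBIENT_PRESETS["cold_dry"], outlet_velocity=0.2)
print(nasopharyngeal_summary(extract_profile(fields, mesh, geom, "cold_dry")))
```

Virtual anatomy modifications chain off the built geometry:

```python
from nasocond import apply_no_valve, apply_horizontal
no_valve = apply_no_valve(geom)
horizontal = apply_horizontal(no_valve, no_valve.vestibule_inclination())
```

`nasocond cohort --n-subjects 5 --seed 1` runs a jittered synthetic cohort
and prints a per-subject table with an Average row.

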