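# Methods

`nasocond` simulates the air-conditioning function of the nasal passage:
steady laminar inspiratory airflow through a passage-like duct, with heat
and water-vapor exchange at a mucosal wall, and the per-cross-section
metrics used to score how closely inhaled air approaches the tissue state
(34 °C, 3.34% water mass fraction) by the nasopharyngeal level.

## Governing model

The air is incompressible with constant properties (ρ = 1.2 kg/m³,
μ = 1.8·10⁻⁵ Pa·s, Cp = 1006 J/(kg·K), K = 0.026 W/(m·K),
D = 2.6·10⁻⁵ m²/s — standard room-temperature air, all overridable per
run).  Momentum and continuity,

    ρ (u·∇)u = −∇p + μ ∇²u,        ∇·u = 0,

are closed by a free inlet at the nostril (zero-gauge total pressure), a
uniform outward normal velocity at the pharyngeal outlet, and no-slip
walls.  Temperature T (°C) and water mass fraction F (%, vapor mass over
total humid-air mass) obey passive convection–diffusion,

    ρ Cp (u·∇)T = K ∇²T,           (u·∇)F = D ∇²F.

Coupling is one-way: buoyancy and property variation with T and F are
neglected, so one converged flow field serves every ambient condition on a
given geometry.  This makes the "identical flow across conditions"
property exact rather than approximate.

The flow is steady and laminar by construction of the study conditions.
The resting outlet velocity follows the allometric estimates
TV = 7.69·BW^1.04 ml, f = 0.84·BW^−0.26 Hz and FV = 2·f·TV/CA; the
default preset velocity of 0.2 m/s puts the pharyngeal Reynolds number
near 210 — inside the resting-breathing laminar range of roughly 135–1264
and far below the 2300 transition — and keeps the valve jet steady, which
a steady solver requires.  The `respiration` module exposes Re, Strouhal,
and Womersley screening numbers; the laminar flag is Re < 2300 with the
boundary excluded.

## Wall exchange model

The wall is a tissue layer at fixed T_Tis = 34 °C and F_Tis = 3.34%
behind an epithelial film (thickness δ_ep = 0.2 mm on the epidermis-lined
vestibule, 0.5 mm on mucosa; conductivity K_ep = 0.6 W/(m·K), that of
water) and, for water, a stagnant boundary layer of δ_bl = 0.5 mm with
diffusivity D_bl = 3.0·10⁻⁵ m²/s (epithelial D_ep = 2.6·10⁻⁵ m²/s).
With all fluxes taken positive into the air:

* conduction  Q_ep = K_ep (T_Tis − T_S)/δ_ep;
* two-film water flux  W_bl = ρ D_bl (F_S − F)/δ_bl, where flux
  continuity between the epithelial and boundary-layer films fixes the
  surface fraction F_S = (a F_Tis + b F)/(a + b), a = D_ep/δ_ep,
  b = D_bl/δ_bl.  F_S always lies between F and F_Tis and equals F_Tis at
  equilibrium — the form with a minus sign on the b F term fails that
  limit, so the plus-sign form is used.  The printed film laws D·ΔF/δ
  carry velocity units for a dimensionless F; multiplying by the air
  density gives a mass flux in kg/(m²·s), the standard species-flux
  convention, with the density exposed as an explicit factor;
* latent heat  Q_latent = −L(T_S)·W_bl with the cubic
  L = 2500.79 − 6.14342·10⁻⁶ T³ + 1.58927·10⁻³ T² − 2.36418 T (kJ/kg, fit
  range 0–50 °C; outside it the polynomial is evaluated with a warning,
  since solver intermediates can transiently leave the range);
* total  Q_total = Q_ep + Q_latent.

Per wall face, the surface temperature solves the balance between the
discrete fluid-side conduction (the finite-volume near-wall flux,
including its non-orthogonal correction — no empirical transfer
correlation) and Q_total.  The balance is mildly nonlinear through
L(T_S); it is solved by vectorized bisection bracketed in [−20, 60] °C to
1·10⁻¹⁰ °C, which is robust where Newton steps need not be.  Water
exchange enters the transport solve as a Dirichlet condition F = F_S on
mucosa faces; vestibule (epidermis) faces exchange heat only, with
W_bl = Q_latent = 0 and the thinner 0.2 mm film.  The boundary-layer film
is a closure for the surface state, not a replacement for the resolved
near-wall gradient: the latent heat uses the film flux W_bl, while the
water actually delivered to the air is the discrete diffusive flux of the
Dirichlet condition — the two agree in the fine-mesh limit.

Equilibrium is exact: a domain at (34 °C, 3.34%) with that inlet state
stays there, with all wall fluxes at zero to solver tolerance.  With dry
air at 34 °C the surface cools below tissue temperature (evaporative
cooling), which the tests assert as a sign property.

## Psychrometrics

Saturation vapor pressure uses the Arden Buck (1981) correlation over
liquid water (0.61121·exp[(18.678 − T/234.5)·T/(257.14 + T)] kPa, valid
−20…100 °C).  The mass fraction of water is vapor mass over *total*
humid-air mass, MF = ε p_v/(ε p_v + P − p_v) with ε = M_w/M_a ≈ 0.622 and
default total pressure 101.325 kPa; this definition reproduces the four
reference conversions (34 °C/100% → 3.34, 5 °C/10% → 0.05, 40 °C/5% →
0.23, 30 °C/60% → 1.58) within ±0.01 percentage points.  Standard
correlations straddle 3.33/3.34 for the saturated 34 °C value; the
equilibrium ambient preset pins its mass fraction to the 3.34 reference so
the wall model's fixed point is exact.  RH34 = 100·MF/3.34 is the
conditioning score.

## Synthetic passage geometry

Real nasal anatomies are three-dimensional tomography-derived surfaces;
this package deliberately reduces the domain to a parameterized 2D channel
strip (planar unit depth, or axisymmetric for straight ducts) so the full
physics runs at desk scale.  The strip is described by a centerline
heading θ(s) and width w(s) over arclength: a vestibule duct (inclination
90° human-like, 0° chimpanzee-like; epidermis walls), a valve — a narrow
slit-like channel whose width tapers to `valve_gap` over the first half of
the valve segment and holds it to the basal plane — an expanding cavity
entry, a cavity whose centerline arches upward (the `cavity_arch`
parameter, 25° in the human-like preset; the valve empties near the cavity
floor and the bulk path arches over it), a bend, and a pharyngeal outlet
duct.  Segment transitions are cosine-blended, and construction rejects
parameter sets whose curvature would fold the inner wall (|κ|·w/2 ≥ 1).
The basal plane sits at the downstream end of the valve segment.  The
cavity-entry expansion length is its own parameter (default 15 mm) so that
shortening the cavity does not steepen the diffuser behind the valve.
Preset cavity openings are deliberately narrow (6 mm): in a real nasal
cavity the airway is a thin slit between septum and turbinates, and a
wide 2D channel would leave the core unconditioned and let the valve slit
dominate humidification, misrepresenting the relative weight of cavity
and vestibule.

The virtual variants mirror anatomy editing: `no_valve` replaces
vestibule and valve with a straight duct from the nostril to the basal
plane, its width tapering linearly (monotone, minimum at the basal plane
— the interior constriction is gone); a short cosine heading blend ahead
of the basal plane keeps the junction meshable.  `horizontal` tilts that
straight duct about the basal plane; at a tilt equal to the vestibule
inclination the lower surface comes parallel to the cavity floor.  Tilts
beyond the inclination (the duct would dip below the cavity floor) and
any self-intersecting result are rejected.  Downstream samples are reused
bit-identically by both variants.

Meshing maps an (s, η) grid through the strip: structured quadrilaterals,
nominal spacing in mm, at least four cells across the narrowest opening
(spacing < valve_gap/4 enforced).  Cell volumes, face area vectors,
owner–neighbour connectivity, patch labels (inlet, outlet, epidermis and
mucosa walls, axis) and the finite-volume geometric factors are
precomputed.  Axisymmetric meshes weight volumes and face areas by radius
and record the hoop area used by the radial pressure gradient.

What the generator does *not* emulate: turbinates and the associated
surface-to-volume enrichment, paranasal sinuses, septal asymmetry,
nostril-pair topology, mucosal thickness variation, and the nasal cycle.
Passing tests therefore validate the physics and the comparative
anatomy-effect logic on idealized passages, not subject-level predictions
for real anatomies.

## Discretization and solvers

Collocated finite volumes with SIMPLE pressure–velocity coupling and
Rhie–Chow face fluxes.  Momentum convection is deferred-correction
central differencing over an implicit first-order upwind base — at these
cell Peclet numbers the scheme is stable and gives the second-order
accuracy needed for grid-converged velocities (halving the spacing moves
matched-station speeds by ≲1.6% on the presets).  Scalar (T, F)
convection is pure first-order upwind: it guarantees the discrete
extremum principle, so converged fields are provably bounded by the inlet
and wall-surface values, and the station minima behave monotonically.
Diffusion uses the over-relaxed orthogonal decomposition with explicit
non-orthogonal corrections.

Under-relaxation: momentum 0.7, pressure 0.3, wall-state updates 0.5 (the
latent-heat nonlinearity is mild but benefits from damping); the
total-pressure inlet value is damped by 0.5 per iteration to stabilize
its feedback on the inlet mass flux.  Scaled residual criteria: continuity
1·10⁻⁴, velocity components 1·10⁻⁵, energy 1·10⁻⁷, water 1·10⁻⁴; the
scalar/wall outer loop additionally requires face-state changes below
1·10⁻⁸.  Linear systems are solved with sparse LU; inside the
under-relaxed outer iteration the factorization is lagged (refreshed
every 20 iterations, used with one iterative-refinement step and an
accuracy fallback), and the scalar-transport matrices, constant once the
flow is frozen, are factored once per solve.  Refined-mesh solves can be
initialized by bilinear prolongation from a coarser solution; the
converged state is initialization-independent, which a test asserts.

The flow solver raises a convergence error carrying the full residual
history rather than returning an unconverged field; `pressure_drop` and
the transport solver refuse unconverged inputs.

## Metrics and tables

Conditioning profiles sample 12 equally spaced cross-section stations
from nares to outlet (configurable); per station the extremum of T and F
over cells whose centers fall within half a nominal spacing of the
station.  The nasopharyngeal summary takes the last station: lowest T for
warm-wet and cold-dry, highest T for hot-dry (approach to 34 °C from
above), lowest MF, and RH34 from that MF.  Cohort averages are arithmetic
means of unrounded per-subject values in exact decimal arithmetic, with
RH34 of the average recomputed from the unrounded mean MF.  Presentation
rounding (one decimal for T and RH34, two for MF) is decimal
round-half-even applied only at formatting.  Published cohort tables of
this kind average unrounded upstream values, so a table recomputed from
rounded per-subject entries can disagree in tie cells; the test suite
asserts recomputed values and documents the affected cells.

Streamlines seed uniformly over the nostril plane with a count
proportional to the inlet area (so bundle size reflects relative airflow
volume) and integrate with adaptive Runge–Kutta until the line leaves the
domain.  The bundle's mean path supports two diagnostics: the initial
(vestibular) heading, and the number of sign alternations of the signed
curvature with net turns below 8° ignored and the outlet-adjacent 5% of
the path trimmed (bundle averaging wiggles there).  The human-like
passage yields two alternations — backward over the valve, arching up
into the cavity, down to the pharynx — while the horizontal variant
enters flat and shows at most one.

## Study conditions and problem sizes

The default experiment matrix crosses geometry presets and variants with
three ambient conditions: warm-wet (30 °C, 60% RH, 1.58% MF), cold-dry
(5 °C, 10% RH, 0.05%), hot-dry (40 °C, 5% RH, 0.23%).  The test suite
and worked examples run the presets at 0.7 mm nominal spacing (about
2·10³ cells, with refinement to 0.35 mm ≈ 7·10³ cells for the
mesh-independence property) — sizes chosen so the full property matrix is
exercised in minutes on a single CPU while keeping the valve constriction
resolved by well over four cells.

## Known limitations

* 2D planar transport underestimates the surface-to-volume ratio of a
  turbinate-bearing 3D cavity, so absolute conditioning performance is
  poorer than in real passages of the same length; only comparative
  statements across geometries are meaningful.
* The steady formulation requires a steadily laminar valve jet; at outlet
  velocities well above the resting defaults the 2D jet becomes unsteady
  and the solver reports non-convergence instead of a field.
* Constant fluid properties and one-way coupling neglect buoyancy and the
  T-dependence of diffusivities (the water model is deliberately
  temperature-independent apart from L(T_S)).
* Exhalation, breathing-cycle unsteadiness, and mucosal regulation are
  out of scope.
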