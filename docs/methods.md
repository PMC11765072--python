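# Methods

## Problem setting

Melt-extrusion 3D printing of oleogel inks deposits a molten, oil-continuous
gel at nozzle temperature T₀ onto a cooled platform at Tp.  Print success
hinges on two couplings between rheology and process: (i) the ink must stay
liquid inside the syringe (Tg < T₀) yet gel quickly once deposited, and
(ii) its viscosity at the nozzle shear rate must sit in a window that allows
controlled flow without dripping or clogging.  `oleoprint` quantifies both,
plus the post-deposition cooling that decides whether each layer solidifies
before carrying the next.

## Gelation temperature and gel classification

A cooling sweep tabulates G′(T) and G″(T).  Tg is defined as the modulus
crossover, tan δ = G″/G′ = 1.  The crossover is located on the signed
log-gap d(T) = log G′ − log G″: the sign changes of d between consecutive
rows bracket the crossings, and each crossing is interpolated linearly in
(T, d).  Log-space interpolation is used because moduli span many decades
and vary roughly exponentially with temperature near the transition; it is
exact when both moduli are exponential in T, which the unit tests exploit.
If several crossings exist (noisy data, non-monotone tan δ), the
highest-temperature one is reported as the liquid→gel transition of the
cooling ramp and all crossings are retained in the result.  No smoothing is
applied to the moduli before crossover detection.

Gel class uses tan δ read at the single sweep row nearest 5 °C (a
storage-relevant reference temperature; no averaging window): strong gel
below 0.1, weak gel in [0.1, 1), viscous liquid at or above 1.  The printed
interval convention leaves tan δ = 0.1 ambiguous; it is assigned to the
weak-gel class so that the strong-gel definition stays strict.

## Viscosity interpolation

Flow curves give µ(γ̇) at a handful of fixed temperatures.  Queries at
printing conditions interpolate log µ bilinearly in (T, log γ̇) between the
two bracketing curves.  The scheme is exact (bit-identical, via a
short-circuit on exact grid hits) at measured points and monotone between
adjacent grid points in each axis.  Extrapolation is off by default and
raises; an explicit flag enables linear extension of the edge segments in
the same log coordinates, with a logged warning.

## Nozzle shear rate

The wall shear rate during extrusion is estimated by the Newtonian
Hagen–Poiseuille relation with the volumetric flow rate expressed through
printed mass and print time: γ̇ = 4m/(π r³ t ρ).  Inputs carry bench units
(g, µm, s, g/cm³) and are converted to SI before evaluation, eliminating
silent unit errors.  The raw value is kept; rounding to integer happens
only in the presentation table.  No Rabinowitsch (shear-thinning)
correction is applied — the estimate is deliberately the simple capillary
bound used for ink screening.  Default melt density is 0.8793 g/cm³
(high-oleic sunflower oil at 70 °C).

## Thermal model

Each printed layer is a rectangular slab governed by ∂T/∂t = α∇²T with
α = k/(ρCp).  Defaults for the packaged scenario are the oil-dominated
values k = 0.16 W/(m·K), ρ = 880 kg/m³, Cp = 2400 J/(kg·K)
(α ≈ 7.6×10⁻⁸ m²/s).  Note the thermal density (880 kg/m³) and the
shear-rate density (879.3 kg/m³) are kept as two separate inputs: they
describe the material at different temperatures and enter unrelated
formulas.

Boundary conditions: the base plane z = 0 is Dirichlet (platform
temperature Tp for layer 1); the four side walls and the top face are Robin,
−k ∂T/∂n = h∞(T − T∞), with h∞ = 2 W/(m²·K) as a typical natural-convection
value and ambient T∞ = 22.1 °C.  The initial condition is uniform at the
nozzle-exit temperature T₀ = 79.7 °C.  Latent heat of gelator
crystallization is neglected; it is a few percent of the sensible heat
exchanged over a layer's cooling.

### Discretization

Forward-time centred-space (FTCS) on a node-centred grid,
Δᵢ = Lᵢ/(Nᵢ − 1), default 20×20×10 nodes and Δt = 0.01 s.  Robin faces use
second-order ghost nodes (T₋₁ = T₁ − 2Δ h∞/k (T₀ − T∞)); a first-order
quasi-steady surface balance is available behind `robin_order=1`.  Edge and
corner nodes apply the ghost condition independently per exposed face.
Where the Dirichlet base meets Robin walls, Dirichlet wins: the whole z = 0
plane is pinned.  The solver refuses to run when
r = αΔt(1/Δx² + 1/Δy² + 1/Δz²) > ½ unless explicitly overridden (the
packaged scenario has r ≈ 0.065).

### Layer stacking

A print of n layers (default 7) is n independent slab problems: layer j ≥ 2
starts uniform at T₀ with its base Dirichlet-pinned at the final mean
top-surface temperature of layer j − 1.  The handoff reuses the recorded
value bit-for-bit, which the tests assert.  The alternative — growing one
domain and re-meshing — is deliberately not implemented; the per-layer
scheme matches the protocol this package reproduces.

### Surface aggregation

T_upper is the area-weighted (trapezoid) mean of the top-face nodes;
T_side the area-weighted mean over the four lateral faces, excluding the
base-contact node row (z = 0 belongs to the pinned platform plane, not to a
free surface).  Mean aggregation is chosen because a single trace per
surface is what gets compared against Tg; a max-aggregation option exists
(`_Stepper.surface_means` is the single point of change) but the mean is
the default and the tested path.

### Energy audit

Each layer run accumulates the discrete boundary fluxes that the FTCS
stencil itself exchanges: conduction across the base plane,
kA(Tp − T₁)/Δz per base-adjacent node, and the ghost-face flux
kA(T_ghost − T_b)/Δ on every Robin face, which decomposes into a surface
convection term 2hA(T_b − T∞) minus an interior-gradient term.  With node
enthalpy ρCp·ΔxΔyΔz·T summed over the updated nodes, the balance closes to
round-off by construction (residuals ~10⁻¹⁵ in the test runs); the checks
require < 1 %.  The audit is defined for the ghost-node scheme; the
first-order Robin option does not carry an exactness guarantee.

### Analytic oracle

With side/top convection switched off the 3D problem collapses to the 1D
slab with Dirichlet base and insulated top, whose separation-of-variables
solution is

T(z,t) = Tp + (T₀ − Tp) Σₖ 4/((2k+1)π) · sin((2k+1)πz/2Lz) ·
exp(−α((2k+1)π/2Lz)² t).

`analytic_slab_solution` evaluates this series (default 100 terms; the
truncation error for t ≥ 1 s is < 10⁻⁶ °C at 50 terms) and serves as the
independent oracle: the verification tests require the solver's centerline
to match within 0.5 °C at Nz = 40 and to converge at second order (error
ratio ≈ 4 when Δz halves, with Δt scaled ∝ Δz² at fixed r = 0.2).  The
oracle comparison uses a 5 s horizon and a 5×5 lateral grid, sizes chosen so
the whole verification runs in seconds while the grid-halving ratio is
clean.

## Operational map and verdict

The printable zone is the closed rectangle Tg ∈ [50, 80] °C,
µ ∈ [0.01, 0.05] Pa·s.  Closed bounds are a deliberate choice — the ranges
are stated without a boundary convention, and closing them keeps a
formulation sitting exactly on a bound printable.  All supplied viscosity
entries must pass (conservative AND); an any-pass mode exists behind a flag
for exploratory screening.  Extrudability is separate from the zone: Tg ≥ T₀
means the ink gels in the syringe, with equality counted as gelling (the
safe reading when the crossover sits within measurement error of T₀).
Shape stability requires every layer's final T_upper and T_side below Tg;
it is reported as indeterminate when no thermal histories are supplied —
the map alone cannot decide it.

## Synthetic data generator

`generate_sweep` models log G′ as a logistic sigmoid between a liquid
plateau (0.5 Pa) and a solid plateau (3×10⁶ Pa) with a 2 °C transition
width, and tan δ as a logistic ramp in log space from a liquid value 2.5
down to a solid plateau below 1.  The tan δ = 1 crossover is pinned exactly
at the requested Tg by solving the logistic midpoint analytically, so the
generator's truth is independent of the analyzer's root-bracketing.
`generate_flow_curves` uses µ = µ∞ + K(T)γ̇ⁿ⁻¹ with Arrhenius-type
K(T) = K₀·exp(E/T_K).  Noise, when requested, is multiplicative lognormal
(unit median, specified coefficient of variation), appropriate for strictly
positive quantities spanning decades; all randomness flows through a
`numpy` Generator seeded from the params, so identical params give
byte-identical output.

What the generator emulates: sigmoidal modulus growth on cooling, a single
liquid→gel crossover, shear-thinning with temperature-dependent
consistency, and instrument-like multiplicative scatter.  What it does not:
the two-stage modulus rise from polymorphic crystal transitions, thixotropy
and shear history, frequency dependence, and measurement artifacts such as
slip.  Passing tests therefore demonstrate correct recovery of crossover
and power-law structure under realistic noise — not robustness to every
rheometer pathology.

The presets (`SWEEP_PRESETS`, `FLOW_PRESETS`) mimic a phytosterol ladder in
a monoglyceride oleogel — Tg rising with co-gelator content except for
low-ratio members, one near-Newtonian optimal member with µ ≈ 0.013–0.032
Pa·s across 90–60 °C, and strongly shear-thinning high-load members.  They
are synthetic mimics for demos and tests, not measurements.

## Problem sizes used by the test suite

The verification suite runs the packaged scenario in full — four speeds,
seven layers each, 20×20×10 nodes, Δt = 0.01 s (≈ 3.8×10⁵ explicit steps
in total, about a minute) — and the Monte-Carlo checks use 200 seeded sweep
replicates and 10⁵ map samples.  Oracle-comparison runs use the reduced
grids noted above; these sizes are the package's own verification choices.

## Known limitations

* The Hagen–Poiseuille estimate assumes Newtonian laminar tube flow; for
  strongly shear-thinning inks the true wall shear rate is higher.
* The thermal model ignores deposition dynamics (a moving hot filament),
  radiation, crystallization kinetics and latent heat; each layer appears
  instantaneously at T₀.
* Layer coupling is one-way (base handoff); the previous layers' fields are
  not co-evolved while a new layer cools.
* The operational-map bounds are formulation-family-specific calibrations,
  not universal constants; re-calibrate for chemically different inks.
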