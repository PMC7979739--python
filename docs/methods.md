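# Model description and numerical methods

`ferrad` simulates photochemical radical production, oxygen limitation and
volatile mass loss in viscous aqueous iron(III)-citrate / citric-acid
particles and films, together with the laboratory observables used to
constrain such models: X-ray microscopy iron-oxidation-state profiles,
single-particle radius traces, and flow-tube HO2 release.

## The condensed-phase mechanism

The packaged default network (`ferrad/data/mechanism.yaml`) is a minimal
closure of the iron-carboxylate photochemical cycle:

| step | reaction | default rate |
|------|----------|--------------|
| R1 | FeIIICit + hv -> Fe2+ + CO2 + CCR | j (per light source) |
| R2 | CCR + O2 -> RO2 | 1e6 M-1 s-1, diffusion-capped |
| R3 | RO2 -> HO2 + C2-5 carbonyl (volatile) | 0.05 s-1 |
| R4 | HO2 + HO2 -> H2O2 + O2 | k_SR(RH) parameterization |
| R5 | Fe2+ + HO2 -> Fe3+ + H2O2 | 1.2e7 M-1 s-1, diffusion-capped |
| R6 | Fe2+ + H2O2 -> Fe3+ + OH | 700 M-1 s-1, diffusion-capped |
| R7 | Fe2+ + O2 -> Fe3+ + HO2 | 1.3 M-1 s-1 |
| R8 | OH + citrate -> CCR + CO2 | 3e8 M-1 s-1, diffusion-capped |
| R9 | CCR + CCR -> dimer | off by default |
| R10 | OH + OH -> H2O2 | 5.5e9 M-1 s-1, diffusion-capped |
| R11 | OH + H2O2 -> HO2 | 2.7e7 M-1 s-1, diffusion-capped |
| R12 | Fe2+ + OH -> Fe3+ | 3e8 M-1 s-1, diffusion-capped |
| R13 | Fe2+ + RO2 -> Fe3+ + product | 100 M-1 s-1 |

plus first-order HO2 (5 s-1, globally calibrated) and H2O2 (1e-4 s-1)
losses and two fast complexation equilibria,

    Fe3+ + Cit <-> FeIIICit   (K1 = 1e2 M-1, effective)
    Fe2+ + Cit <-> FeIIHCit   (K2 = 1e3 M-1, effective)

LMCT photolysis and the immediate decarboxylation are lumped into R1; only
the iron(III)-citrate complex is photolyzable. Carbon and iron are balanced
in every reaction (the carbon ledger of a sealed box is conserved along a
trajectory); proton and oxygen bookkeeping of the lumped steps is not
attempted, and acid-base speciation is collapsed into effective species at
the simulated pH.

Three design features matter most for where radicals persist:

* **Diffusion caps.** Bimolecular constants marked `diffusion_limited` are
  harmonically combined with the Smoluchowski encounter rate computed from
  the current species diffusivities, so radical-radical and radical-iron
  chemistry shuts down as the matrix vitrifies.
* **Complexation protection.** The reoxidation channels R5-R7 and the
  scavenging channels R12-R13 act on the *free* aqua Fe2+ ion. Where ligand
  is abundant (low Mr) nearly all iron(II) is complexed and reoxidation is
  slow; where iron outnumbers ligand (high Mr) free Fe2+ scavenges HO2,
  H2O2, OH and RO2, which shortens the ROS lifetime, while the reoxidized
  Fe3+ largely fails to recomplex (K1 < K2) and is photochemically inert.
  Both K values are effective constants for the viscous matrix.
* **The k_SR(RH) law.** The RH-dependent HO2 self-reaction spans five
  decades between RH 16% and 60% and is the main humidity switch routing
  HO2 into the H2O2/Fenton reoxidation loop at moist conditions.

All rate constants live in the mechanism file. Constants flagged
`calibratable` were fixed by calibrating against the three laboratory
anchors (fractional radius/mass loss of levitated particles at RH 50% and
16%, dark-reoxidation profile behavior, film HO2 release) and may be refit
with `ferrad.calibration` within the declared bounds.

## Material properties

* Water mass fraction: cubic-in-activity fit anchored to citric-acid
  hygroscopicity, w(1) = 1, w(0) = 0.
* Water diffusivity: log10 Dw quadratic in water activity through
  (0, -15.5), (0.5, -12.0), (1.0, -8.64) m2/s at 293 K — a steep,
  near-glassy low-RH branch consistent with citric-acid viscosity data —
  with Arrhenius temperature scaling (Ea = 60 kJ/mol) and a factor-4
  reduction from Mr = 0.05 to 1.0 (log-linear in log Mr). Species
  diffusivities are D_x = Dw * f_Dx with per-species constants f_Dx
  (gases ~ 0.04-0.7 of water, organics and iron 1e-2 to 1e-4).
* Density: volume-additive mixing of the dry organic (1.5 g/cm3) and water.
* Effective Henry constants: dilute values scaled by 10 (calibratable in
  [1, 30]).

## Transport and integration

The condensed phase is divided into 20-26 concentric shells (films: slabs)
graded geometrically toward the gas interface (surface layer 0.1 nm for
sub-micron particles, 1 nm for the 8-um levitated droplet; adjacent-layer
ratio <= 1.6). Within each macro segment (60-600 s) the complexation
equilibria are first imposed exactly (vectorized bisection on the shared
ligand, conserving total iron and citrate to machine precision), then
chemistry, inter-layer Fickian diffusion, and surface Henry exchange are
integrated *together* as one stiff ODE system with the BDF method (vode)
and a banded Jacobian; cumulative gas-side transfers are carried as extra
states. Finally layer volumes are recomputed from the evolved composition
at fixed water content and density, which moves the outer boundary as CO2
and the C2-5 carbonyls escape. When surface layers collapse under heavy
local mass loss the grid is rebuilt and the field remapped conservatively.

Monolithic (rather than operator-split) coupling of chemistry and diffusion
is essential here: the reacto-diffusive O2 length reaches molecular scale,
and any splitting of the O2 sink from its resupply produces a penetration
depth that depends on the macro step instead of on sqrt(D/k).

Numerical choices: mass-action rates are evaluated on a smoothed positive
part of the state, 0.5*(c + sqrt(c^2 + 1e-30)) — negative excursions in
quadratic rate terms are explosively unstable, while a hard clip destroys
the smoothness the implicit solver needs; the transition lies far below the
absolute tolerance (default rtol 1e-5, atol 1e-8 mol/m3). A failed stiff
solve is retried on quartered sub-segments with clipped restarts. Iron
conservation is monitored every segment and a relative drift above 1e-3
aborts the run rather than returning an untrustworthy state.

Water is held at its equilibrium content for the ambient RH (the particles
are pre-equilibrated in all protocols and RH is constant within a phase),
entering through density, layer volume and Dw only. Gas-side transport
resistance is neglected (surface conductance 1e-4 m/s, configurable);
diffusivities are evaluated at the initial composition of a run.

## Observables

* Radial beta profiles: per-shell Fe(III)/(total Fe).
* Column-integrated ring profiles: the half-sphere is ray-traced on a
  35-nm pixel grid (3x3 subpixel rays, midpoint z-quadrature), columns are
  reduced to Fe(III) and total-Fe integrals, and pixels are averaged in
  rings indexed by distance from the particle perimeter — the same
  reduction applied to the microscope images.
* P_HO2: time derivative of the cumulative HO2 gas ledger per film area
  over the trailing 10% of the run; a relative drift above 5% raises an
  error reporting the drift, rather than returning a non-steady value.
* Radical burdens: volume-weighted [CCR] (the carbon-centered radical pool)
  and [ROS] (HO2 + H2O2 + OH + RO2), time-averaged over the trailing 30 min
  of a 1 h run, reported in mM and molecules per microgram.
* O2 penetration depth: first depth below the surface where [O2] falls
  under 1/e of its surface value (threshold configurable), with linear
  interpolation between layer centers; "never" is reported as the particle
  size.

## Synthetic data

The generators in `ferrad.synthetic_data` emulate the statistical structure
of the three instruments: two-energy optical-density images (Poisson photon
noise calibrated so ring profiles carry ~+-0.07 uncertainty; packaged
absorptivity pair for the 707.8/709.5 eV resonances; organic background
proportional to column thickness), radius traces with a bounded smooth
refractive-index envelope (+-0.5%) plus white noise, and NO-depletion
traces with 1:1 HO2:NO titration and 10% cycle-to-cycle reproducibility.
They reproduce the instruments' *noise structure*, not their optics: no
beamline energy calibration, no Mie sizing physics, no NOx side chemistry.
Passing round-trip and recovery tests therefore validates the analysis
pipeline, not the instruments themselves.

## Calibration

`fit_global` performs bounded least squares in log-parameter space
(scipy.optimize.least_squares, TRF) with seeded multi-start, weighting each
datum by its stated uncertainty. The packaged default observation table
mixes published anchors (radius/mass loss) with synthetic flow-tube rows.
A factor-5 perturbation band of the fitted HO2 loss is attached to every
fit, mirroring the sensitivity analysis customary for this quantity.

## Problem sizes and defaults

Default runs use 20-26 layers; the levitated-particle protocol integrates
5.5 h of irradiation (the reported "more than 5 h") on an 8-um droplet in
about a minute of wall time, ambient-scan points use 1 h simulations of a
0.5-um particle, and flow-tube runs use 1.5-3 h of illumination. Doubling
the layer count changes the headline observables by well under the
experimental uncertainties.

## Known limitations

* The mechanism is a lumped closure: second-generation peroxy radicals are
  represented by one RO2 pool, acid-base speciation is implicit, and the
  C2-5 volatile product is a single surrogate species (146 g/mol).
* Effective equilibrium constants and several effective rate constants
  (k6, k13, the complexation pair) absorb matrix effects that a molecular
  model would resolve; they are meaningful only jointly, as calibrated.
* Sub-nanometer surface layers stretch the continuum picture; they follow
  the source model's own usage, and the caveat applies equally there.
* Diffusivities are frozen at the initial composition of each run; strong
  local composition changes (e.g. a fully burned surface at high Mr under
  full sun) are not fed back into the transport coefficients.
* Half-sphere particles are transported as spheres (substrate contact as a
  no-flux mirror plane); the half-sphere geometry enters only through the
  column-integration observables.
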