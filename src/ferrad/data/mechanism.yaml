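# Default iron(III)-citrate photochemical mechanism.
#
# A minimal closure of the iron-carboxylate photo-cycle: ligand-to-metal
# charge transfer (LMCT) with immediate decarboxylation, O2 addition to the
# carbon-centered radical (CCR), HO2 elimination from the peroxy radical,
# iron(II) reoxidation by ROS/O2, Fenton chemistry, H-abstraction from
# citrate by OH, and fast complexation equilibria.
#
# Units: molar masses g/mol; bimolecular rate constants M^-1 s^-1;
# unimolecular/loss rates s^-1; equilibrium constants M^-1.
# Rate constants carrying "calibratable: true" were fixed by a global
# calibration against the three laboratory protocols (single-particle
# radius-loss traces, dark-reoxidation beta profiles, film HO2 release)
# and may be refit within the stated bounds.

species:
  - {name: CA,       molar_mass: 192.12, f_dx: 1.0e-3, volatile: false, category: organic,     n_fe: 0, n_c: 6}
  - {name: FeIIICit, molar_mass: 244.95, f_dx: 1.0e-3, volatile: false, category: iron,        n_fe: 1, n_c: 6}
  - {name: Fe3,      molar_mass: 55.85,  f_dx: 1.0e-2, volatile: false, category: iron,        n_fe: 1, n_c: 0}
  - {name: Fe2,      molar_mass: 55.85,  f_dx: 1.0e-2, volatile: false, category: iron,        n_fe: 1, n_c: 0}
  - {name: FeIIHCit, molar_mass: 245.95, f_dx: 1.0e-3, volatile: false, category: iron,        n_fe: 1, n_c: 6}
  - {name: CCR,      molar_mass: 147.1,  f_dx: 1.0e-3, volatile: false, category: radical,     n_fe: 0, n_c: 5}
  - {name: RO2,      molar_mass: 179.1,  f_dx: 1.0e-3, volatile: false, category: ros,         n_fe: 0, n_c: 5}
  - {name: HO2,      molar_mass: 33.01,  f_dx: 0.5,    volatile: true,  henry: 6.81,    category: ros,         n_fe: 0, n_c: 0}
  - {name: H2O2,     molar_mass: 34.01,  f_dx: 0.5,    volatile: true,  henry: 987.0,   category: ros,         n_fe: 0, n_c: 0}
  - {name: OH,       molar_mass: 17.01,  f_dx: 1.0,    volatile: false, category: ros,         n_fe: 0, n_c: 0}
  - {name: O2,       molar_mass: 32.0,   f_dx: 0.1,    volatile: true,  henry: 1.28e-5, category: gas-derived, n_fe: 0, n_c: 0}
  - {name: CO2,      molar_mass: 44.01,  f_dx: 0.4,    volatile: true,  henry: 3.36e-4, category: product,     n_fe: 0, n_c: 1}
  - {name: VOC,      molar_mass: 146.1,  f_dx: 0.025,    volatile: true,  henry: 1.0e-2,  category: product,     n_fe: 0, n_c: 5}
  - {name: DIMER,    molar_mass: 294.2,  f_dx: 1.0e-4, volatile: false, category: product,     n_fe: 0, n_c: 10}

reactions:
  # LMCT photolysis lumped with immediate decarboxylation
  - name: R1_lmct
    law: photolytic
    reactants: {FeIIICit: 1}
    products: {Fe2: 1, CO2: 1, CCR: 1}
  # O2 addition to the carbon-centered radical (diffusion limited in matrix)
  - name: R2_ccr_o2
    law: bimolecular
    reactants: {CCR: 1, O2: 1}
    products: {RO2: 1}
    rate_parameter: 1.0e+6
    diffusion_limited: true
    calibratable: true
  # HO2 elimination from the primary peroxy radical, leaving a volatile C2-5 product
  - name: R3_ro2_decomp
    law: unimolecular
    reactants: {RO2: 1}
    products: {HO2: 1, VOC: 1}
    rate_parameter: 0.05
    calibratable: true
  # HO2 self reaction; rate follows the RH-dependent parameterization by default
  - name: R4_ho2_self
    law: bimolecular
    reactants: {HO2: 2}
    products: {H2O2: 1, O2: 1}
    rate_parameter: 8.3e+5
    ksr_mode: rh_polynomial
  # iron(II) reoxidation by HO2 (free aqua ion; the citrate-bound pool is
  # protected, so complexation controls the effective rate)
  - name: R5_fe2_ho2
    law: bimolecular
    reactants: {Fe2: 1, HO2: 1}
    products: {Fe3: 1, H2O2: 1}
    rate_parameter: 1.2e+7
    diffusion_limited: true
    calibratable: true
  # Fenton reaction
  - name: R6_fenton
    law: bimolecular
    reactants: {Fe2: 1, H2O2: 1}
    products: {Fe3: 1, OH: 1}
    rate_parameter: 700.0
    diffusion_limited: true
    calibratable: true
  # slow direct reoxidation by O2
  - name: R7_fe2_o2
    law: bimolecular
    reactants: {Fe2: 1, O2: 1}
    products: {Fe3: 1, HO2: 1}
    rate_parameter: 13.0
    diffusion_limited: true
    calibratable: true
  # OH scavenging by excess free iron(II): shortens the ROS lifetime where
  # iron outnumbers the ligand
  - name: R12_fe2_oh
    law: bimolecular
    reactants: {Fe2: 1, OH: 1}
    products: {Fe3: 1}
    rate_parameter: 3.0e+8
    diffusion_limited: true
  # peroxy-radical reduction by excess free iron(II)
  - name: R13_fe2_ro2
    law: bimolecular
    reactants: {Fe2: 1, RO2: 1}
    products: {Fe3: 1, VOC: 1}
    rate_parameter: 100.0
    diffusion_limited: true
  # H abstraction from citrate by OH followed by decarboxylation
  - name: R8_oh_ca
    law: bimolecular
    reactants: {OH: 1, CA: 1}
    products: {CCR: 1, CO2: 1}
    rate_parameter: 3.0e+8
    diffusion_limited: true
    calibratable: true
  # OH self-recombination and reaction with peroxide (OH sinks)
  - name: R10_oh_self
    law: bimolecular
    reactants: {OH: 2}
    products: {H2O2: 1}
    rate_parameter: 5.5e+9
    diffusion_limited: true
  - name: R11_oh_h2o2
    law: bimolecular
    reactants: {OH: 1, H2O2: 1}
    products: {HO2: 1}
    rate_parameter: 2.7e+7
    diffusion_limited: true
  # CCR recombination (off by default; observed not to control the fast cycling)
  - name: R9_ccr_self
    law: bimolecular
    reactants: {CCR: 2}
    products: {DIMER: 1}
    rate_parameter: 1.0e+6
    diffusion_limited: true
    switch: ccr_self_reaction

equilibria:
  # fast complexation; total iron and total citrate conserved exactly
  - {complex: FeIIICit, metal: Fe3, ligand: CA, K: 3.0e+0}
  - {complex: FeIIHCit, metal: Fe2, ligand: CA, K: 1.0e+3}

switches:
  ccr_self_reaction: false
  # first-order condensed-phase HO2 sink (the globally fitted parameter)
  ho2_first_order_loss: 5.0
  # slow first-order H2O2 loss
  h2o2_first_order_loss: 1.0e-4

# photolysis-rate coefficients per light band: j = power_density * quantum_yield * sigma_eff
# sigma_eff is a lumped actinic conversion constant (mm^2 mW^-1 s^-1) fixed by
# the measured j anchors for each lamp
light_bands:
  uv_365:      {sigma_eff: 6.1111e-4, quantum_yield: 1.0,   reference_power: 3.6}
  vis_473:     {sigma_eff: 5.375e-2,  quantum_yield: 0.002, reference_power: 40.0}
  cwft_lamp:   {sigma_eff: 9.1e-3,    quantum_yield: 1.0,   reference_power: 1.0}
  full_sun:    {sigma_eff: 5.23e-2,   quantum_yield: 1.0,   reference_power: 1.0}

ksr_rh_polynomial: [-2.854e-5, 0.0024, 0.1087, -0.05018]   # log10 kSR = p3*RH^3 + p2*RH^2 + p1*RH + p0
ksr_dilute: 8.3e+5
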