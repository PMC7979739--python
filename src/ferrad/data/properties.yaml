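# Material-property parameterizations for aqueous citric-acid/iron-citrate
# particles. All coefficients are configuration, not code.

water_activity:
  # water mass fraction w(aw) = aw * (c1 + c2*aw + c3*aw^2); monotone on [0,1],
  # w(1)=1 (pure water), anchored to citric-acid hygroscopicity data
  coefficients: [0.3175, -0.5925, 1.275]

water_diffusivity:
  # log10 Dw [m2/s] quadratic in water activity at the 293.15 K reference:
  # log10 Dw = a0 + a1*aw + a2*aw^2 through (0, -15.5), (0.5, -12.0), (1, -8.64)
  log10_coefficients: [-15.5, 7.14, -0.28]
  reference_temperature_k: 293.15
  # Arrhenius-type activation energy for the temperature scaling, J/mol
  activation_energy: 60.0e+3
  # Dw decreases by this factor between mole ratio 0.05 and 1.0 (log-linear in
  # log Mr); sign of the effect is exposed here
  mr_factor: 4.0
  mr_range: [0.05, 1.0]

density:
  # dry organic matrix density, g/cm3; mixed with water volume-additively
  organic: 1.5
  water: 1.0

henry:
  # effective Henry constants exceed dilute aqueous values by about this factor
  default_scaling: 10.0

transport:
  # surface gas-exchange conductance, m/s (gas-side resistance neglected)
  surface_conductance: 1.0e-4
  # effective reaction radius for diffusion-limited rate caps, m
  reaction_radius: 5.0e-10
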