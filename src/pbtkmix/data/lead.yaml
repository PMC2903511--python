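# Lead toxicokinetic parameters.
#
# Structure follows the O'Flaherty description: diffusible blood lead with a
# deep red-cell-bound pool, flow-limited soft tissues, urinary excretion, and
# bone as the dominant long-term reservoir — trabecular bone as a single
# exchanging pool and mature cortical bone discretised into eight concentric
# cylindrical shells exchanging by radial diffusion, the innermost shell in
# contact with blood.  Values are repository defaults representative of that
# model family; the bone uptake/return constants are calibrated so that a
# chronic adult simulation places ~95% of the body burden in bone, the
# literature anchor for human lead kinetics.
chemical: lead
molecular_mass: {value: 207.2, units: g/mol, source: "atomic mass of Pb"}
absorption:
  f_abs: {value: 0.08, units: fraction, source: "adult GI absorption, representative"}
blood_binding:
  k_plasma_to_rbc: {value: 2.0, units: 1/h, source: "red-cell binding, fast"}
  k_rbc_to_plasma: {value: 0.01, units: 1/h, source: "red-cell release; bound:diffusible amount ratio 200"}
  rbc_pool_volume: {value: 2.4, units: L, source: "red-cell volume"}
partition_coefficients:  # tissue : diffusible-blood, dimensionless
  liver: 100.0
  kidney: 100.0
  muscle: 60.0
  viscera: 80.0
  brain_h: 50.0       # permeability-area product L/h for the diffusion-limited brain
  brain: 40.0
  skin: 60.0
  fat: 10.0
partition_source: "soft-tissue : diffusible blood ratios, representative"
excretion:
  urinary_clearance: {value: 1.9, units: L/h, source: "on diffusible blood concentration, representative"}
bone:
  trabecular_volume: {value: 1.0, units: L, source: "trabecular bone"}
  cortical_volume: {value: 2.8, units: L, source: "mature cortical bone"}
  n_shells: {value: 8, units: count, source: "radial discretisation of mature cortical bone"}
  inner_radius_fraction: {value: 0.5, units: dimensionless, source: "marrow-cavity radius / outer radius of the cortical cylinder"}
  clearance_to_trabecular: {value: 0.31, units: L/h, source: "calibrated to the ~95% bone burden share"}
  clearance_to_cortical: {value: 0.57, units: L/h, source: "calibrated to the ~95% bone burden share"}
  trabecular_return: {value: 5.3e-5, units: 1/h, source: "trabecular turnover, half-life ~1.5 y"}
  bone_blood_partition: {value: 5.0e4, units: dimensionless, source: "bone : diffusible blood; sets cortical capacity and return"}
  shell_conductance: {value: 1.0e-4, units: L/h, source: "radial diffusive conductance scale; decadal cortical residence"}
age_growth:  # optional simplified childhood scaling (piecewise linear vs age)
  body_mass_knots_y: [0, 10, 20, 30]
  body_mass_kg: [3.5, 32, 68, 70]
  bone_turnover_multiplier: [8.0, 3.0, 1.2, 1.0]
  source: "simplified hooks; full growth model out of scope"
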