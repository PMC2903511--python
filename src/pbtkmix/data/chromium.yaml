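# Chromium toxicokinetic parameters.
#
# Two tracked species: Cr(VI), which is rapidly reduced to Cr(III) in blood,
# and Cr(III), whose distribution skeleton follows the same author's lead
# model (soft tissues plus a slowly exchanging bone pool).  Values are
# repository defaults representative of that model family.
molecular_mass: {value: 52.0, units: g/mol, source: "atomic mass of Cr"}
species: [crVI, crIII]
gi:
  k_absorption_crVI: {value: 0.10, units: 1/h, source: "GI uptake of chromate, representative"}
  k_absorption_crIII: {value: 0.005, units: 1/h, source: "GI uptake of Cr(III), poor"}
  k_fecal: {value: 1.0, units: 1/h, source: "GI transit; net F ~9% (VI), ~0.5% (III)"}
blood_reduction:
  {value: 10.0, units: 1/h, source: "rapid reduction of Cr(VI) to Cr(III) in blood; half-life ~4 min"}
partition_coefficients:  # tissue:blood
  crVI: {liver: 1.0, kidney: 1.0}
  crIII: {liver: 5.0, kidney: 5.0, muscle: 1.0, viscera: 2.0}
bone:
  clearance_to_bone: {value: 0.05, units: L/h, source: "slow skeletal uptake on blood concentration"}
  bone_return: {value: 1.0e-4, units: 1/h, source: "skeletal release, slow"}
  bone_pool_volume: {value: 4.2, units: L, source: "bone volume"}
excretion:
  urinary_clearance_crVI: {value: 0.10, units: L/h, source: "representative"}
  urinary_clearance_crIII: {value: 0.30, units: L/h, source: "representative; urinary route dominates absorbed dose"}
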