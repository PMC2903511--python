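# Methylmercury toxicokinetic parameters.
#
# Structure follows the Clewell description: flow-limited soft tissues, a
# diffusion-limited brain (blood-brain barrier), excretion in urine, hair and
# feces (plus breast milk when lactation is configured), distributed
# demethylation to inorganic mercury, and an optional fetal subsystem with
# bidirectional placental transfer and a growing fetal volume.  Amounts are
# expressed as Hg.  Values are repository defaults representative of that
# model family.
molecular_mass: {value: 200.59, units: g/mol, source: "amounts expressed as Hg"}
species: [mehg, ihg]
absorption:
  f_abs: {value: 0.95, units: fraction, source: "near-complete GI absorption of MeHg"}
partition_coefficients:
  mehg: {liver: 5.0, kidney: 4.0, brain: 3.0, muscle: 2.0, skin: 2.0, fat: 0.15, viscera: 2.0}
  ihg: {liver: 5.0, kidney: 10.0, viscera: 2.0}
brain_permeability:
  {value: 20.0, units: L/h, source: "blood-brain barrier permeability-area product for MeHg"}
demethylation:
  tissues: [liver, kidney, viscera]
  rate: {value: 5.0e-5, units: 1/h, source: "conversion to inorganic Hg; placement configurable (occurs in many tissues)"}
excretion:
  mehg:
    fecal_from_liver: {value: 4.0e-3, units: 1/h, source: "biliary/fecal route, dominant; gives whole-body half-life ~55 d"}
    hair_clearance: {value: 0.003, units: L/h, source: "incorporation into growing hair, on blood concentration"}
    urinary_clearance: {value: 0.005, units: L/h, source: "minor urinary route"}
    milk_clearance: {value: 0.02, units: L/h, source: "breast milk, applied only when lactation is configured"}
  ihg:
    urinary_clearance: {value: 0.010, units: L/h, source: "renal elimination of inorganic Hg"}
    fecal_from_liver: {value: 2.0e-4, units: 1/h, source: "representative"}
pregnancy:
  fetal_volume_start: {value: 0.05, units: L, source: "early-gestation fetal distribution volume"}
  fetal_volume_term: {value: 3.0, units: L, source: "term fetal distribution volume"}
  gestation_days: {value: 280, units: day, source: "term"}
  placental_clearance: {value: 0.10, units: L/h, source: "maternal-to-fetal transfer, representative"}
  fetal_maternal_ratio: {value: 1.8, units: dimensionless, source: "cord:maternal blood ratio >1; fetal blood may exceed maternal"}
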