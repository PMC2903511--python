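# Cadmium biokinetic parameters.
#
# Structure follows the Kjellström–Nordberg compartmental description:
# slow first-order exchange between blood, liver, kidney and a lumped
# other-tissue pool, with metallothionein-mediated retention expressed as
# very slow return/elimination constants.  Values are repository defaults
# representative of that model family (the original parameter compilation is
# not redistributed here); each entry records its provenance.
chemical: cadmium
molecular_mass: {value: 112.41, units: g/mol, source: "atomic mass of Cd"}
absorption:
  f_abs_male:
    {value: 0.05, units: fraction, source: "Kjellström–Nordberg family; GI absorption in adult males"}
  f_abs_female:
    {value: 0.10, units: fraction, source: "Kjellström–Nordberg family; higher fractional absorption in females"}
other_tissue_volume:
  {value: 40.0, units: L, source: "lumped non-liver/kidney soft tissue, repository default"}
transfers:  # first-order rate constants, 1/day
  blood_to_liver:
    {value: 0.25, units: 1/day, source: "Kjellström–Nordberg family, representative"}
  blood_to_kidney:
    {value: 0.10, units: 1/day, source: "Kjellström–Nordberg family, representative"}
  blood_to_other:
    {value: 0.40, units: 1/day, source: "Kjellström–Nordberg family, representative"}
  blood_to_urine:
    {value: 0.010, units: 1/day, source: "direct plasma filtration term, representative"}
  blood_to_feces:
    {value: 0.050, units: 1/day, source: "biliary/GI secretion term, representative"}
  liver_to_blood:
    {value: 0.00025, units: 1/day, source: "hepatic release; half-life ~7.6 y, representative"}
  kidney_to_urine:
    {value: 0.00010, units: 1/day, source: "renal elimination; half-life ~19 y, representative"}
  kidney_to_blood:
    {value: 0.00005, units: 1/day, source: "renal release, representative"}
  other_to_blood:
    {value: 0.005, units: 1/day, source: "soft-tissue release, representative"}
kidney_cortex_ratio:
  {value: 1.25, units: dimensionless, source: "cortex:whole-kidney concentration ratio, repository default"}
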