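# Arsenic toxicokinetic parameters.
#
# Structure follows the El-Masri/Kenyon description: six tracked arsenicals
# (AsV, AsIII, MMAV, MMAIII, DMAV, DMAIII), hepatic methylation by AS3MT with
# noncompetitive inhibition of the AsIII->MMAV step by liver MMAIII and of the
# MMAIII->DMAV step by liver AsIII, first-order reductions V->III, minor
# oxidations III->V for every species, no demethylation, and urinary excretion
# as the only elimination route.  Values are repository defaults representative
# of that model family.
molecular_mass: {value: 74.92, units: g/mol, source: "doses and amounts expressed as As"}
species: [asV, asIII, mmaV, mmaIII, dmaV, dmaIII]
partition_coefficients:  # tissue:blood, dimensionless
  asV:    {liver: 2.0, kidney: 3.0, muscle: 1.0, skin: 2.0}
  asIII:  {liver: 6.0, kidney: 5.0, muscle: 1.5, skin: 4.0}
  mmaV:   {liver: 1.5, kidney: 2.5, muscle: 1.0, skin: 1.5}
  mmaIII: {liver: 4.0, kidney: 4.0, muscle: 1.2, skin: 2.5}
  dmaV:   {liver: 1.5, kidney: 2.0, muscle: 1.0, skin: 1.5}
  dmaIII: {liver: 3.0, kidney: 3.0, muscle: 1.0, skin: 2.0}
partition_source: "El-Masri/Kenyon family, representative tissue:blood ratios"
gi:
  k_absorption: {value: 0.5, units: 1/h, source: "soluble arsenicals are well absorbed (~94% net)"}
  k_fecal: {value: 0.03, units: 1/h, source: "unabsorbed fraction to feces"}
metabolism:  # hepatic
  reduction_asV_to_asIII:   {value: 0.30, units: 1/h, source: "step 1, first order, representative"}
  methylation_asIII_to_mmaV:
    {vmax: 4.5, km: 10.0, k_nc: 0.5, units: "umol/h, umol/L, umol/L",
     source: "step 2, AS3MT; noncompetitively inhibited by liver MMAIII"}
  methylation_asIII_to_dmaV:
    {vmax: 1.5, km: 10.0, units: "umol/h, umol/L",
     source: "step 3, representative"}
  reduction_mmaV_to_mmaIII: {value: 1.0, units: 1/h, source: "step 4, representative"}
  methylation_mmaIII_to_dmaV:
    {vmax: 50.0, km: 8.0, k_nc: 0.5, units: "umol/h, umol/L, umol/L",
     source: "step 5, AS3MT; noncompetitively inhibited by liver AsIII"}
  reduction_dmaV_to_dmaIII: {value: 0.05, units: 1/h, source: "step 6, representative"}
  oxidation_III_to_V:       {value: 0.01, units: 1/h, source: "minor back-oxidation, all species"}
urinary_clearance:  # L/h on blood concentration
  asV: 4.0
  asIII: 1.0
  mmaV: 1.0
  mmaIII: 1.5
  dmaV: 5.0
  dmaIII: 3.0
urinary_source: "renal clearances, representative; urinary excretion is the only elimination route"
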