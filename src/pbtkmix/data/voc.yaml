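# Benzene and toluene inhalation parameters.
#
# Classic flow-limited volatile-organic PBTK structure (gas exchange, liver,
# fat, rapidly and slowly perfused tissues) mapped onto the shared whole-body
# physiology, with saturable hepatic oxidation and mutual competitive
# inhibition (each chemical's inhibition constant taken equal to its own Km).
# Values are representative of the human benzene/toluene PBPK literature.
alveolar_ventilation: {value: 300.0, units: L/h, source: "resting-to-light-activity alveolar ventilation"}
benzene:
  molecular_mass: {value: 78.11, units: g/mol}
  blood_air_partition: {value: 8.19, units: dimensionless, source: "human blood:air"}
  partition_coefficients: {liver: 1.7, fat: 6.7, muscle: 0.8, skin: 0.8, viscera: 1.7, kidney: 1.7}
  vmax: {value: 530.0, units: umol/h, source: "VmaxC 2.11 mg/h/kg^0.7 scaled to 70 kg"}
  km: {value: 4.5, units: umol/L, source: "0.35 mg/L"}
toluene:
  molecular_mass: {value: 92.14, units: g/mol}
  blood_air_partition: {value: 15.6, units: dimensionless, source: "human blood:air"}
  partition_coefficients: {liver: 4.6, fat: 56.7, muscle: 1.5, skin: 1.5, viscera: 4.6, kidney: 4.6}
  vmax: {value: 730.0, units: umol/h, source: "VmaxC 3.44 mg/h/kg^0.7 scaled to 70 kg"}
  km: {value: 6.0, units: umol/L, source: "0.55 mg/L"}
inhibition:
  source: "mutual competitive inhibition at the hepatic oxidation step; I set equal to the inhibitor's Km"
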