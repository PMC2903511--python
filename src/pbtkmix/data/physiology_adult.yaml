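# Reference adult physiology (70 kg), repository defaults assembled from
# standard human physiology compilations.  Units: L, L/h, kg.
# Perfused tissue flows sum exactly to the cardiac output (312 L/h = 5.2 L/min).
cardiac_output: 312.0
body_mass: 70.0
compartments:
  - {name: blood,    volume: 5.5,                    tags: [blood]}
  - {name: liver,    volume: 1.8,  blood_flow: 78.0, tags: [liver, rapidly_perfused]}
  - {name: kidney,   volume: 0.31, blood_flow: 59.3, tags: [kidney, rapidly_perfused]}
  - {name: brain,    volume: 1.4,  blood_flow: 37.4, tags: [brain, rapidly_perfused],
     scheme: diffusion_limited, subvolumes: [0.25, 1.15]}
  - {name: viscera,  volume: 4.0,  blood_flow: 37.5, tags: [viscera, rapidly_perfused]}
  - {name: fat,      volume: 14.0, blood_flow: 15.6, tags: [fat, slowly_perfused]}
  - {name: muscle,   volume: 28.0, blood_flow: 53.0, tags: [muscle, slowly_perfused]}
  - {name: skin,     volume: 3.4,  blood_flow: 15.6, tags: [skin, slowly_perfused]}
  - {name: bone,     volume: 4.2,  blood_flow: 15.6, tags: [bone, slowly_perfused]}
  - {name: gi_lumen, volume: 1.2,  scheme: storage,  tags: [gi_lumen]}
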