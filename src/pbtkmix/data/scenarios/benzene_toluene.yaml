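# Co-inhalation of benzene and toluene with mutual competitive inhibition.
physiology: reference_adult
models:
  - name: voc
exposures:
  - chemical: benzene
    route: inhalation
    events:
      - {start_h: 0.0, magnitude: 10.0, units: ppm}
  - chemical: toluene
    route: inhalation
    events:
      - {start_h: 0.0, magnitude: 20.0, units: ppm}
simulation:
  t_end_h: 240.0
  report_step_h: 1.0
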