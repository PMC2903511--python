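# Base-case metals + volatile-organics co-exposure (no interactions):
# continuous dietary metal intakes with a +40% step at day 500, constant
# benzene/toluene inhalation.  The full case study with the cadmium
# birth-to-age-30 pre-run and the metal->metabolism interaction variants is
# orchestrated by pbtkmix.interactions.run_mixture_scenario.
physiology: reference_adult
models:
  - name: cadmium
  - name: methylmercury
  - name: lead
  - name: arsenic
  - name: voc
exposures:
  - chemical: cadmium
    route: oral_continuous
    events: [{start_h: 0.0, magnitude: 15.0, units: ug/day}]
    scale: [{time_h: 12000.0, factor: 1.4}]
  - chemical: mehg
    route: oral_continuous
    events: [{start_h: 0.0, magnitude: 40.0, units: ug/day}]
    scale: [{time_h: 12000.0, factor: 1.4}]
  - chemical: lead
    route: oral_continuous
    events: [{start_h: 0.0, magnitude: 70.0, units: ug/day}]
    scale: [{time_h: 12000.0, factor: 1.4}]
  - chemical: asIII
    route: oral_continuous
    events: [{start_h: 0.0, magnitude: 100.0, units: ug/day}]
    scale: [{time_h: 12000.0, factor: 1.4}]
  - chemical: toluene
    route: inhalation
    events: [{start_h: 0.0, magnitude: 20.0, units: ppm}]
  - chemical: benzene
    route: inhalation
    events: [{start_h: 0.0, magnitude: 10.0, units: ppm}]
simulation:
  t_end_h: 18000.0
  report_step_h: 24.0
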