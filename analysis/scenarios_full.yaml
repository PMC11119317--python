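# Full study grid: 2 line-development methods x 3 switch stages x 3 trait
# heritabilities x 3 MC-IC genetic correlations = 54 scenarios, each run for
# 100 replicates of 20 breeding cycles. This is a multi-hour run on one CPU;
# see analysis/01_run_scenarios.py for the scaled-down comparison set.
grid:
  methods: [DH, EPR]
  switch_stages: [PYT, AYT, EYT]
  h2: [0.3, 0.5, 0.9]
  R: [0.3, 0.5, 0.9]
cycles: 20
replicates: 100
seed: 1
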