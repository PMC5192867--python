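model: t4ss_pool
factors:
  - {name: doublingTime, min: 20, max: 60}
  - {name: p1P, min: 0, max: 1}
  - {name: p1Cost, min: 0, max: 0.3}
  - {name: p2Cost, min: 0, max: 0.3}
method:
  samples: 64
  ticks: 100
  replications: 2
seed: 1
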