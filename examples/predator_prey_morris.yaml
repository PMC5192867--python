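model: predator_prey
factors:
  - {name: initialnumberofwolves, min: 20, max: 80}
  - {name: initialnumberofsheep, min: 50, max: 200}
  - {name: wolfgainfromfood, min: 10, max: 40}
  - {name: wolfreproduce, min: 2, max: 10}
  - {name: sheepgainfromfood, min: 2, max: 8}
  - {name: sheepreproduce, min: 2, max: 8}
  - {name: grassregrowthtime, min: 10, max: 60}
method:
  levels: 5
  trajectories: 10
  ticks: 200
  replications: 2
seed: 1
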