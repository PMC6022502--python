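# SYNTHETIC stand-in for a 10-lineage dog/wolf demographic configuration.
#
# The published analysis this package re-implements modelled its 53 samples
# as coming from 10 lineages; the exact parameter table is not distributed
# with this repository, so the values below are a plausible synthetic
# configuration (round numbers in the ranges inferred for canid demography)
# that exercises the full multi-lineage code path. The default study model
# used by the tests and analysis scripts is the simpler two-population split
# in domestiscan.demography.two_population_model.
#
# Times are generations before present; sizes are diploid effective sizes.
# Samples named "dog" draw from the first lineage whose name contains
# "dog", and "wolf" likewise (village_dog_east and wolf_europe here).
lineages:
  - {name: village_dog_east, size: 30000}
  - {name: village_dog_west, size: 25000}
  - {name: ancient_dog, size: 12000}
  - {name: dog_ancestor, size: 8000}
  - {name: wolf_europe, size: 12000}
  - {name: wolf_asia, size: 18000}
  - {name: wolf_america, size: 9000}
  - {name: wolf_ancestor, size: 20000}
  - {name: golden_jackal, size: 40000}
  - {name: canid_root, size: 35000}
events:
  # recent wolf-into-dog admixture pulse
  - {kind: migration_pulse, time: 300, source: village_dog_east, dest: wolf_asia, proportion: 0.02}
  - {kind: split, time: 1200, derived: [village_dog_east, village_dog_west], ancestral: dog_ancestor}
  # the ancient-dog lineage joins the dog ancestor
  - {kind: migration_pulse, time: 2400, source: ancient_dog, dest: dog_ancestor, proportion: 1.0}
  # post-domestication bottleneck in the dog ancestor
  - {kind: size_change, time: 2500, population: dog_ancestor, size: 4000}
  - {kind: split, time: 3000, derived: [wolf_europe, wolf_asia], ancestral: wolf_ancestor}
  - {kind: migration_pulse, time: 3500, source: wolf_america, dest: wolf_ancestor, proportion: 1.0}
  - {kind: split, time: 7500, derived: [dog_ancestor, wolf_ancestor], ancestral: canid_root}
  - {kind: migration_pulse, time: 30000, source: golden_jackal, dest: canid_root, proportion: 1.0}
mutation_rate: 4.0e-9
generation_time: 3.0
recombination_rate: 1.0e-8
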