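# Default 16-variable prognostic schema for breast-cancer survivability
# cohorts (SEER-style coding): 11 discrete and 5 continuous variables.
# Discrete variables take integer codes 1..cardinality.  Continuous
# variables carry the cohort mean/sd used by the synthetic generator and
# an admissible range (null = unbounded).  Note: the printed moments of
# tumor_size and num_primaries are inconsistent with their nominal units
# (coded units in the source registry); the schema records the declared
# codes and moments as-is.
variables:
  - {name: race, kind: discrete, cardinality: 16}
  - {name: radiation, kind: discrete, cardinality: 6}
  - {name: primary_site, kind: discrete, cardinality: 9}
  - {name: histological_type, kind: discrete, cardinality: 30}
  - {name: behavior_code, kind: discrete, cardinality: 2}
  - {name: grade, kind: discrete, cardinality: 5}
  - {name: site_specific_surgery, kind: discrete, cardinality: 12}
  - {name: stage, kind: discrete, cardinality: 10}
  - {name: extension_of_tumor, kind: discrete, cardinality: 16}
  - {name: lymph_node_involvement, kind: discrete, cardinality: 7}
  - {name: marital_status, kind: discrete, cardinality: 4}
  - {name: age_at_diagnosis, kind: continuous, mean: 63.64, sd: 14.25, range: [0, null]}
  - {name: tumor_size, kind: continuous, mean: 116.78, sd: 286.64, range: [0, null]}
  - {name: num_positive_nodes, kind: continuous, mean: 27.29, sd: 42.26, range: [0, null]}
  - {name: num_nodes_examined, kind: continuous, mean: 13.61, sd: 17.49, range: [0, null]}
  - {name: num_primaries, kind: continuous, mean: 0.54, sd: 1.29, range: [0, 6]}
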