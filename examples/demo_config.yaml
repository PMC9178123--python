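# Demonstration pipeline config: a small synthetic herd end to end.
# Run with:  methaherd run-all --config examples/demo_config.yaml \
#                --out-dir runs/demo --seed 1
seed: 1

simulate:
  n_founders: 80
  n_generations: 1
  offspring_per_mating: 3
  n_cows: 100
  weeks_per_cow: 10
  truth: default        # reference Danish Holstein variance structure

traits:
  apply_filters: true

varcomp:
  traits: [mep, rfi1]
  pairs: [[ecm, mep]]

index:
  methane_trait: mep
  parameters: demonstration   # published SDs/correlations + labelled fill-ins
  scenarios: standard         # SC0 / SC1 / SC2A / SC2B

impact:
  compare: [SC0, SC2B]        # delta taken from the index responses
  assumptions:
    lactation_days: 305
    n_cows: 550000
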