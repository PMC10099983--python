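# Example configuration driving the CLI workflow:
#   nestipm simulate --config config.yaml
#   nestipm fit --config config.yaml
#   nestipm ltre --config config.yaml --design random
#   nestipm project --config config.yaml --horizon 10
data_dir: nestipm-out/dataset     # nests.csv, captures.csv, weather.csv
output_dir: nestipm-out
seed: 1
scenario: baseline                # for `simulate`
# years: [1980, 2019]             # optional explicit study range
mcmc:
  n_chains: 3
  n_iter: 20000
  n_burnin: 5000
  thin: 10
  seed: 1
priors: {}                        # e.g. {CS_A: [2.0, 10.0], om_max: 150}
ltre:
  designs: [random, fixed]
  period1: [0, 15]                # used by the period design
  period2: [20, 35]
projection:
  horizon: 10
  reps: 1000
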