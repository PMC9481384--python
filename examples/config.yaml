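# Example run configuration for the midsim CLI.
# Every section and key is optional; omitted keys use package defaults.

community:
  M: 30              # species count for `sample` / `simulate`
  m: 10              # substrate count
  S0_each: 1.0e4     # initial amount of every substrate, mg
  intervals:         # (low, high) overrides per kinetic parameter
    mu: [0.24, 1.36]     # specific growth rate, 1/h
    alpha: [0.05, 1.0]   # intraspecific competition
    beta: [0.16, 1.0]    # interspecific competition
    x0: [0.01, 0.1]      # inoculum per species, abundance units

disturbance:
  psd: [5, 5, 5, 5, 5]   # PSD level per channel (growth, intra, inter,
                         # production, consumption)
  redraw_interval: 24.0  # hours each draw is held (daily forcing)

simulation:
  dt: 0.05               # integration step, hours
  horizon: 2400.0        # 100 days
  sample_interval: 24.0  # record one state per day
  extinction_threshold: 1.0e-120

experiment:              # for the `experiment` subcommand
  M_range: [20, 50]
  m_range: [5, 15]
  weak_psd_range: [0.0, 2.0]
  strong_psd_range: [2.0, 10.0]
  replicates: 50
  paired: true

stats:                   # for `stats` / the simulate summary
  rel_threshold: 1.0e-3  # relative abundance defining "coexisting"
  window: 20             # final samples the coexistence count averages over
  max_lag: 10            # correlation lags, in sampling intervals
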