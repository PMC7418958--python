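# Equal-group study conditions: N = 40, half the agents status-sensitive
# (sigma_S = 0.1), half more open-minded (sigma_L = 1.5 sigma_S).
n_agents: 40
n_small: 20
sigma_small: 0.1
sigma_relation_rule: f1
noise_half_width: 0.2
gossip_count: 3
n_iterations: 500000
measure_every: 10000

# sweep settings (leviathan sweep-sigma / sweep-size / baseline)
sigma_small_grid: [0.03, 0.05, 0.07, 0.1, 0.12, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5, 1, 2, 3]
replicas: 50
base_seed: 0
scale_factor: 1.0   # e.g. 0.1 for a desk-scale pass
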