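# Synthetic trial configuration (all fields optional; defaults shown)
n_per_group: 32
mean_ln_k: -5.0
sd_ln_k: 2.5
mean_baseline_drinks: 5.5
phase_effects:
  EFT: {baseline: 1.0, monitoring1: 0.75, monitoring2: 0.55}
  CET: {baseline: 1.0, monitoring1: 0.85, monitoring2: 1.0}
demand_Q0_mean: 10.0
demand_alpha_mean: 0.003
noise_sd_choice: 20.0
noise_sd_demand: 0.1
missingness_log_odds: {baseline: -2.2, monitoring1: -1.8, monitoring2: -1.2}
brac_per_drink: 0.012
seed: 0
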