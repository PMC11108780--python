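# Annotated run configuration for `hierwin demo --config run_config.yaml`.
# Every key is optional except `seed`; defaults shown where omitted.

# Trial designs to generate and pool. Built-ins:
#   dapa_hf_like    720-day window, visits at 0/14/60/.../720 days (knot 14)
#   deliver_like    1,080-day window, visits at 0/30/120/360/720/1080 (knot 30)
designs: [dapa_hf_like, deliver_like]

# Tier hierarchy: main | model1 (drop >=40% decline) |
# model2 (also drop slope; ties possible) | model3 (drop mortality)
tier_model: main

# Stratification variables for pairing, variance and Cox models.
strata: [diabetes, trial]

# Participants per arm in each generated trial.
n_per_arm: 500

# Wins-over-time grid step (days) and horizon (must not exceed the
# shortest fixed window of the pooled designs).
grid_step: 10.0
horizon: 720.0

# Mandatory: controls every random draw; identical seed => identical bundle.
seed: 12345

# Output directory for the result bundle (CSV tables + result.json).
outdir: hierwin_run

# Optional overrides applied to every generated cohort's parameters, e.g.:
# config_overrides:
#   egfr_noise_sd: 7.0          # visit-level noise, ml/min/1.73m^2
#   death_hr_treated: 1.0       # null the mortality effect
#   missing_baseline_fraction: 0.01
config_overrides: {}
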