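"""Project the survey index beyond the fitted horizon and probe prior
sensitivity.

The one-step-ahead projection advances each posterior draw with fresh
process noise and observes it with fresh observation noise.  The
sensitivity runs refit the model with one prior changed at a time (presets
sen1-sen9) and report posterior shifts against the base case.
"""

from otaria import (
    FitData,
    MCMCConfig,
    generate_scenario,
    project_one_step,
    run_sensitivity,
    sample_posterior,
)

scenario = generate_scenario(seed=0)
data = FitData(scenario.removals, scenario.observations.restrict(2013))
cfg = MCMCConfig.scaled(seed=3)
base = sample_posterior(data, config=cfg)

proj = project_one_step(base, None, 2015, seed=3)
print("projected survey index (thousands):")
print(proj.round(2).to_string(index=False))

runs = run_sensitivity(data, base, ["sen3", "sen4"], config=cfg)
print("\nposterior-median shifts vs the base case:")
for run in runs:
    print(f"  {run.preset} (alters {run.altered_parameter} prior):")
    print(run.deltas.round(4).to_string())
# Biasing the K prior upward (sen3) moves the K posterior median by
# hundreds (of thousands of animals) while R_max shifts in the third
# decimal: the survey data pin the growth rate and detectability but say
# little about pre-exploitation abundance.
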