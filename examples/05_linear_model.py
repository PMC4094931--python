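"""Fit per-output linear models on the significant inputs of a network.

After reconstruction, each output's retained inputs define a parsimonious
linear model Y = X b + eps (X standardized, Y centered), trained on a 3:1
split and scored on the held-out quarter by RMSE and R^2.
"""

from minet import (
    PipelineConfig,
    analyze,
    default_planted_spec,
    fit_output_models,
    generate_planted,
)

data, _ = generate_planted(default_planted_spec(n_observations=300, seed=4))
res = analyze(data, PipelineConfig(seed=9, n_pairs=40, fit_models=False))
metrics = fit_output_models(data, res.network, test_fraction=0.25, seed=3)

print(f"network: {len(res.network.edges)} edges at I0 = {res.threshold:.4f}\n")
print(f"{'output':<6} {'#inputs':>7} {'R2_test':>8} {'RMSE_test':>10}")
for out, m in metrics.items():
    if "skipped" in m:
        print(f"{out:<6} skipped: {m['skipped']}")
    else:
        print(f"{out:<6} {len(m['inputs']):>7} {m['r2_test']:>8.3f} "
              f"{m['rmse_test']:>10.3f}")
print("\nOutputs driven by quadratic links fit poorly (low R^2): the linear")
print("model cannot express them even though the MI network finds them —")
print("the gap between detection and linear predictability is the point.")
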