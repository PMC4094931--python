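"""Reconstruct a planted signaling-style network end to end.

Generates the reference planted dataset (22 inputs, 7 outputs, 20 true
edges mixing linear, quadratic and saturating links), runs bandwidth
selection, MI-matrix computation, permutation-null threshold calibration
and edge filtering, then scores the result against the known truth.
"""

from minet import (
    PipelineConfig,
    analyze,
    default_planted_spec,
    evaluate_recovery,
    generate_planted,
    rank_edges,
)

spec = default_planted_spec(n_observations=300, seed=2)
data, truth = generate_planted(spec)
res = analyze(data, PipelineConfig(seed=5, n_pairs=40, fit_models=False))

precision, recall = evaluate_recovery(truth, res.network)
print(f"h = {res.bandwidth.h:.3f}, I0 = {res.threshold:.4f} at p = 0.005")
print(f"edges found: {len(res.network.edges)} (true edges: {truth.sum()})")
print(f"precision = {precision:.2f}, recall = {recall:.2f}")
print("\nstrongest five edges (MI in nats):")
for e in rank_edges(res.network)[:5]:
    print(f"  {e.source} -- {e.target}: {e.weight:.3f}")
print("\nP17 -- C6 is a purely quadratic dependence: its Pearson correlation")
print("is ~0, yet the MI estimator ranks it among the detected edges.")
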