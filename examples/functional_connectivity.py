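"""Infer directed functional connectivity from event-onset series.

A five-stage feed-forward chain (120-ms propagation, 10-ms jitter, 50
repetitions) is generated with known ground truth; the PSTH-lag analysis
with the dual t-test/KS gate should recover the chain and nothing reversed.
"""

from finitenet import funcon as fc
from finitenet import synthetic_calcium as syn

onsets, truth = syn.make_chain_population(
    n_stages=5, delay_ms=120.0, jitter_ms=10.0, n_repetitions=50, seed=1
)
series = fc.OnsetSeries(onsets=tuple(onsets), duration=truth.duration_s)
graph = fc.build_functional_graph(series)

print(f"true chain edges: {truth.edges}")
print("inferred edges (source -> target, mean lag, n lags):")
for e in sorted(graph.edges, key=lambda e: (e.source, e.target)):
    print(f"  {e.source} -> {e.target}  lag {e.mean_lag_ms:5.1f} ms  n={e.n_lags}")
print(f"top OUTPUT nodes: {fc.rank_nodes(graph, 'output', top_n=3)}")
print(f"top INPUT nodes:  {fc.rank_nodes(graph, 'input', top_n=3)}")

summary = fc.summarize_correlations(series)
for i in range(series.n_neurons):
    print(f"  neuron {i}: <CC_max> = {summary.cc_max[i]:.2f}, "
          f"<tau_max> = {summary.tau_max[i]*1000:+6.1f} ms")
# Early stages lead the population (positive mean lag); transitive edges
# such as 0 -> 2 are expected since stage 2 also reliably follows stage 0
# within the 500-ms window.
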