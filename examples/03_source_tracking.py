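"""Decompose a sink community into known sources plus an unknown source.

The sink is a 42/28/30 mixture of two Dirichlet-distinct sources and a
spike of taxa absent from both — the EM estimate should recover all three
proportions to within a few hundredths.
"""

from mycoassembly.source_tracking import em_source_track
from mycoassembly.synthetic import gen_source_sink

sources, sink, sink_counts, truth = gen_source_sink(
    n_sources=2, alphas=(0.6, 0.4), depth=50_000, seed=11,
    unknown_fraction=0.3,
)
est = em_source_track(sink_counts, sources, asv_ids=sink.asv_ids,
                      seed=0, n_restarts=5)

print("true proportions   : source_1=0.42, source_2=0.28, unknown=0.30")
print("estimated          : " + ", ".join(
    f"{n}={p:.3f}" for n, p in zip(est.source_names, est.proportions))
    + f", unknown={est.unknown:.3f}")
print(f"converged in {est.iterations} EM iterations "
      f"(log-likelihood {est.log_likelihood:.1f})")
print("\nThe unknown source absorbs sink reads on taxa no candidate source")
print("carries; its share estimates how much of the community is unexplained.")
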