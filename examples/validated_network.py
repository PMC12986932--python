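"""Build a statistically validated network and detect its modules.

Plants two co-occurrence modules (pairwise log OR = 2) in a synthetic
cohort, screens all 496 indicator pairs with Fisher's exact test under
Bonferroni control, and partitions the resulting network by minimising the
map equation.
"""

from medlifenet import build_svn, default_instrument, detect_communities, encode_cohort
from medlifenet.simulate import ModuleSpec, SimulationConfig, generate_structured

instrument = default_instrument()
ids = instrument.score_indicators
config = SimulationConfig(
    seed=3,
    module_spec=(ModuleSpec(ids[0:6], 2.0), ModuleSpec(ids[6:12], 2.0)),
    trait_effect=0.0,
)
cohort = generate_structured(config)
X = encode_cohort(instrument, cohort.records)

net = build_svn(X, alpha=0.05)
pos = sum(e.sign == "positive" for e in net.edges)
print(f"nodes tested: {len(net.nodes)}, pairwise tests: {net.m}")
print(f"validated edges: {len(net.edges)} ({pos} positive, "
      f"{len(net.edges) - pos} negative)")

partition = detect_communities(net, seed=3)
print(f"modules: {partition.n_modules}, codelength: {partition.codelength:.3f} bits")
for label, nodes in sorted(partition.modules().items()):
    if len(nodes) > 1:
        print(f"  module {label}: {sorted(nodes)}")
print()
print("Each retained edge has Bonferroni-adjusted p < 0.05; the two planted "
      "behaviour modules reappear as the two multi-node map-equation "
      "modules. Negative edges (e.g. between the one-hot levels of a "
      "tripartite item) mark behaviours that exclude each other.")
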