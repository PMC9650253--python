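"""Turn mined rules into an item network and export it for Gephi.

Every (antecedent item -> consequent item) pair becomes a directed
edge carrying lift/support/confidence; an ego view around a focus
item shows "rules centred on" that item, as in network figures.
"""

from pathlib import Path

from omnirule import PlantedRule, SynthConfig, generate_dataset
from omnirule.apriori import mine_rules
from omnirule.discretize import build_transactions, encode_within_sample
from omnirule.network import ego_subgraph, export_graph, rules_to_graph

Path("scratch").mkdir(exist_ok=True)

planted = PlantedRule(item="habitat=lake_or_pond", feature="ROI.7",
                      direction="High", prob=0.9)
ds = generate_dataset(SynthConfig(n_samples=200, planted_rules=(planted,), seed=7))
enc = encode_within_sample(ds.nmr, namespace="nmr")
tx = build_transactions([enc], metadata=ds.metadata.drop(columns=["strain"]))
rules = mine_rules(tx, max_len=2)

g = rules_to_graph(rules)
print(f"full network: {g.number_of_nodes()} items, {g.number_of_edges()} edges")

ego = ego_subgraph(g, ["habitat=lake_or_pond"], radius=1)
print(f"ego view of habitat=lake_or_pond: {ego.number_of_nodes()} items")
print("neighbours:", sorted(ego.successors("habitat=lake_or_pond"))[:5])

path = export_graph(ego, "scratch/habitat_ego.gexf", "gexf")
print("exported:", path)
# Open the GEXF in Gephi; edge thickness by lift reproduces the
# "association rules centred on X" style of figure.
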