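"""Per-layer descriptive statistics of a multiplex network.

Builds a small two-layer multiplex from an in-memory edge list and prints
the seven standard layer descriptors: node and edge counts, link density
(x 1e-3), mean degree, mean connected-component size, size of the greatest
connected component, and the coefficient of variation of component sizes
(0 means all components are equally large — e.g. a single spanning one).
"""

from emaplex import MultiplexNetwork, layer_stats_table

net = MultiplexNetwork.from_edges(
    {
        "meetings": [("ann", "bob"), ("bob", "cat"), ("ann", "cat"), ("dan", "eve")],
        "calls": [("ann", "bob"), ("cat", "dan"), ("dan", "eve"), ("eve", "fay")],
    },
    node_ids=["ann", "bob", "cat", "dan", "eve", "fay"],
)

table = layer_stats_table(net)
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print("Both layers are sparse (density well below 1); the meetings layer")
print("splits into a triangle plus a dyad and an isolate, hence its CoV of")
print("component sizes is positive, while higher CoV means more uneven")
print("component structure.")
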