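"""Build a tiny network by hand and census its building blocks.

Two groups A and B collaborate; A works lake L1 and B the downstream lake
L2. That is exactly one "lake chain collaboration" (block h), plus one
"supported lake group" (block f) in each orientation.
"""

import sesfit as sf

net = sf.SESNetwork.from_parts(
    actors=[sf.ActorNode("A", sf.ActorCategory.MOU), sf.ActorNode("B", sf.ActorCategory.SECOND_GEN)],
    ecos=[sf.EcoNode("L1", watershed="W1"), sf.EcoNode("L2", watershed="W1")],
    social_edges=[("A", "B")],
    eco_edges=[("L1", "L2")],
    membership_edges=[("A", "L1"), ("B", "L2")],
)
assert sf.validate(net) == []

catalog = sf.default_catalog()
cens = sf.census(net, catalog, keep_occurrences=True)
print("counts per block:", cens.counts)
print("block h occurrence:", cens.occurrences["h"][0].assignment_dict)
# counts: h=1 (the chain collaboration), f=2 (each group 'supports' the
# other on its own lake), everything else 0.
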