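"""Full fit analysis of the shipped stylized demo network.

The demo is a synthetic reconstruction of an urban lake-governance system:
23 groups (3 holding formal co-management agreements, "MOU"), 29 lakes in
three watershed chains. The pipeline runs the motif census, compares it to
1000 randomized networks (landscape frozen, ties and memberships
reshuffled), tallies who occupies which motif position, and evaluates the
three fit hypotheses.
"""

import sesfit as sf

net = sf.demo_network()
print(sf.summarize(net))

res = sf.run_analysis(net, R=1000, seed=1)
print()
print(res.nulls.to_frame().to_string(index=False))
# reading: block c (lake chain groups) is over-represented (++), blocks b
# and d (shared lakes without ties; unconnected-lake portfolios) are
# under-represented (--): the demo network displays good fit.

print()
print("MOU share of hub position e-1: %.2f" % sf.category_share(res.occupancy, "e", "e-1", "MOU"))
print("MOU share of support position g-2: %.2f" % sf.category_share(res.occupancy, "g", "g-2", "MOU"))
print()
print(res.report.to_markdown())
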