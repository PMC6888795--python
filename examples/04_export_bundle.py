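"""Write the demo network to the five-file CSV bundle and GraphML, read it
back, and save the occupancy dot-matrix plot."""

from pathlib import Path

import sesfit as sf

out = Path("demo_out")
net = sf.demo_network()
paths = sf.write_network(net, out)
sf.write_graphml(net, out / "demo.graphml")
print("wrote:", *[p.name for p in paths.values()], "demo.graphml")

again = sf.load_network(
    paths["actors"], paths["lakes"], paths["social_edges"], paths["eco_edges"], paths["membership"]
)
print("round trip identical:", again.equals(net))

catalog = sf.default_catalog()
cens = sf.census(net, catalog, keep_occurrences=True)
occ = sf.positional_occupancy(net, catalog, cens)
occ.to_csv(out / "occupancy.csv")
sf.plot_occupancy(occ, out / "occupancy.png")
print("wrote occupancy.csv and occupancy.png")
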