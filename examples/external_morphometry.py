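"""Morphometry of an externally supplied polyline network.

The metrics subsystem works on any 3D centerline graph, not only on
simulated vasculature: here a hand-built branching tree is measured, then
a simulated network is round-tripped through GraphML the way a third-party
reconstruction would be loaded.
"""

import tempfile
from pathlib import Path

import numpy as np

from angiosprout import baseline_config, network_metrics, run
from angiosprout.io import read_graphml, write_graphml
from angiosprout.metrics import graph_from_segments

# a small hand-built tree: a trunk that bifurcates into two arms
segs = [([100.0, 250, 250], [250.0, 250, 250]),
        ([250.0, 250, 250], [350.0, 330, 250]),
        ([250.0, 250, 250], [350.0, 170, 250])]
tree = graph_from_segments([s for s, _ in segs], [e for _, e in segs])
rep = network_metrics(tree, volume_mm3=0.125)
print(f"hand-built tree: {rep.n_bifurcations} bifurcation, "
      f"{rep.n_segments} segments, VLD {rep.vld:.2f} mm/mm^3")

# round-trip a simulated network through GraphML
res = run(baseline_config(seed=4, duration_days=10.0))
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "network.graphml"
    write_graphml(res.network, path)
    loaded = read_graphml(path)
rep = network_metrics(loaded, volume_mm3=0.125)
print(f"reloaded simulation: VLD {rep.vld:.1f} mm/mm^3, BD {rep.bd:.0f} "
      f"/mm^3, FD {rep.fd:.2f}")
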