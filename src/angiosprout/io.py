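"""Network serialization: GraphML, SWC-like text, and legacy VTK polydata.

GraphML carries one graph node per geometric network node (x/y/z attributes
in microns) and one edge per agent segment (length, capillary id); it round
trips through :func:`read_graphml` so the metrics subsystem can be applied
to third-party reconstructions.  The SWC-like export is one sample per node
(id, type code, x, y, z, radius, parent; parent -1 starts a capillary — the
network may contain loops, so this is SWC-like rather than strict SWC).  The
VTK export writes ASCII polydata lines for 3D viewers.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .metrics import SpatialGraph, graph_from_segments
from .network import PHALANX, STALK, TIP, VascularNetwork

_SWC_TYPE = {TIP: 5, STALK: 6, PHALANX: 7}


def _node_key(p: np.ndarray) -> str:
    return "{:.6f}_{:.6f}_{:.6f}".format(*p)


def to_networkx(network: VascularNetwork) -> nx.MultiGraph:
    G = nx.MultiGraph()
    for cid in sorted(network.capillaries):
        cap = network.capillaries[cid]
        for aid in cap.agent_ids:
            ag = network.agents[aid]
            for p in (ag.node1, ag.node2):
                k = _node_key(p)
                if k not in G:
                    G.add_node(k, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            G.add_edge(_node_key(ag.node1), _node_key(ag.node2),
                       length=ag.length, capillary=cid, agent=aid)
    return G


def write_graphml(network: VascularNetwork, path) -> None:
    nx.write_graphml(to_networkx(network), str(path))


def read_graphml(path) -> SpatialGraph:
    """Load a polyline vascular graph exported by :func:`write_graphml`
    (or any GraphML with x/y/z node attributes) as a junction-segment graph."""
    G = nx.read_graphml(str(path))
    coords = {n: np.array([d["x"], d["y"], d["z"]])
              for n, d in G.nodes(data=True)}
    starts, ends = [], []
    for u, v in G.edges():
        starts.append(coords[u])
        ends.append(coords[v])
    return graph_from_segments(starts, ends)


def write_swc(network: VascularNetwork, path) -> None:
    lines = ["# SWC-like vascular centerline export",
             "# id type x y z radius parent"]
    idx = 0
    for cid in sorted(network.capillaries):
        cap = network.capillaries[cid]
        parent = -1
        for j, aid in enumerate(cap.agent_ids):
            ag = network.agents[aid]
            code = _SWC_TYPE.get(ag.cell_type, 7)
            if j == 0:
                idx += 1
                lines.append(f"{idx} {code} {ag.node1[0]:.6f} {ag.node1[1]:.6f} "
                             f"{ag.node1[2]:.6f} {ag.radius:.3f} -1")
                parent = idx
            idx += 1
            lines.append(f"{idx} {code} {ag.node2[0]:.6f} {ag.node2[1]:.6f} "
                         f"{ag.node2[2]:.6f} {ag.radius:.3f} {parent}")
            parent = idx
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk(network: VascularNetwork, path) -> None:
    """Legacy-VTK ASCII polydata: one polyline per capillary."""
    points = []
    polylines = []
    for cid in sorted(network.capillaries):
        cap = network.capillaries[cid]
        if not cap.agent_ids:
            continue
        start = len(points)
        first = network.agents[cap.agent_ids[0]]
        points.append(first.node1)
        for aid in cap.agent_ids:
            points.append(network.agents[aid].node2)
        polylines.append(list(range(start, len(points))))
    out = ["# vtk DataFile Version 3.0", "angiosprout vascular network",
           "ASCII", "DATASET POLYDATA", f"POINTS {len(points)} float"]
    out += ["{:.6f} {:.6f} {:.6f}".format(*p) for p in points]
    size = sum(len(pl) + 1 for pl in polylines)
    out.append(f"LINES {len(polylines)} {size}")
    out += [" ".join(map(str, [len(pl)] + pl)) for pl in polylines]
    Path(path).write_text("\n".join(out) + "\n")
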