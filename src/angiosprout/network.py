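"""Vascular-network data model: agents, capillaries, endothelial units.

The vasculature lives in a continuous 500 x 500 x 500 um domain (configurable).
Nodes are plain length-3 ``numpy`` arrays of coordinates in microns.  An
endothelial agent is a short vessel element spanning a trailing node (node 1)
and a forward node (node 2); consecutive agents of a capillary share a node,
so each capillary is a continuous polyline.  Groups of consecutive agents form
endothelial-cell *units* — the granularity at which the once-per-cell
sprouting rule is enforced.

Proximity queries (anastomosis, sprout regression) go through a uniform-bin
spatial hash over agent segments; results are exact (candidate gathering by
bin, then an exact point-to-segment distance filter).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._geometry import point_segments_distance
from .errors import ConfigurationError, IllegalOperationError, OutOfDomainError

TIP = "tip"
STALK = "stalk"
PHALANX = "phalanx"

#: coordinate quantum used when deciding whether two nodes coincide
NODE_TOL = 1e-6


@dataclass
class EndothelialAgent:
    """A two-node vessel element.

    ``node1`` trails, ``node2`` leads.  Activation gates migration and
    proliferation; deactivated agents never move or divide.  ``divided`` marks
    the one-time tip division.
    """

    id: int
    node1: np.ndarray
    node2: np.ndarray
    cell_type: str
    capillary_id: int
    unit_id: int
    radius: float = 5.0
    active: bool = True
    cell_cycle_length: float = np.inf
    cell_cycle_elapsed: float = 0.0
    divided: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.node2 - self.node1))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from node1 to node2 (undefined for zero length)."""
        d = self.node2 - self.node1
        n = np.linalg.norm(d)
        if n == 0.0:
            raise ValueError(f"agent {self.id} has zero length")
        return d / n


@dataclass
class EndothelialUnit:
    """A group of consecutive agents representing one biological cell.

    ``has_sprouted`` enforces the once-per-cell sprouting rule;
    ``suppressed`` records Delta-Notch lateral inhibition from a neighbouring
    unit's sprout.
    """

    id: int
    capillary_id: int
    agent_ids: list = field(default_factory=list)
    length: float = 0.0
    has_sprouted: bool = False
    suppressed: bool = False

    @property
    def first_agent_id(self) -> Optional[int]:
        return self.agent_ids[0] if self.agent_ids else None


@dataclass
class Capillary:
    """An ordered chain of agents (trailing to leading) sharing nodes."""

    id: int
    agent_ids: list = field(default_factory=list)
    unit_ids: list = field(default_factory=list)
    mature: bool = False
    parent_id: Optional[int] = None
    origin: Optional[np.ndarray] = None
    tip_id: Optional[int] = None
    #: the single agent whose cell-cycle clock is currently running
    clock_agent_id: Optional[int] = None
    child_ids: set = field(default_factory=set)
    #: geometry snapshot frozen at maturation (for immutability checks)
    frozen: Optional[bytes] = None
    #: the endothelial unit this capillary sprouted from (None for initials)
    source_unit_id: Optional[int] = None
    #: simulation time (hours) the capillary was created at
    born: Optional[float] = None


@dataclass
class ValidationReport:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


class SpatialHash:
    """Uniform-bin index from grid cells to the agent segments crossing them.

    Each segment is registered in every bin overlapping its axis-aligned
    bounding box, so a bin-range query over a sphere's bounding box is a
    superset of all segments within the radius.
    """

    def __init__(self, bin_size: float = 10.0):
        self.bin_size = float(bin_size)
        self._cells: dict = {}
        self._ranges: dict = {}

    def _bin_range(self, lo: np.ndarray, hi: np.ndarray):
        b = self.bin_size
        i0 = np.floor(lo / b).astype(int)
        i1 = np.floor(hi / b).astype(int)
        return tuple(i0), tuple(i1)

    def insert(self, aid: int, a: np.ndarray, b: np.ndarray) -> None:
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        r = self._bin_range(lo, hi)
        self._ranges[aid] = r
        (x0, y0, z0), (x1, y1, z1) = r
        for cell in itertools.product(
            range(x0, x1 + 1), range(y0, y1 + 1), range(z0, z1 + 1)
        ):
            self._cells.setdefault(cell, set()).add(aid)

    def remove(self, aid: int) -> None:
        r = self._ranges.pop(aid, None)
        if r is None:
            return
        (x0, y0, z0), (x1, y1, z1) = r
        for cell in itertools.product(
            range(x0, x1 + 1), range(y0, y1 + 1), range(z0, z1 + 1)
        ):
            s = self._cells.get(cell)
            if s is not None:
                s.discard(aid)
                if not s:
                    del self._cells[cell]

    def update(self, aid: int, a: np.ndarray, b: np.ndarray) -> None:
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        r = self._bin_range(lo, hi)
        if self._ranges.get(aid) == r:
            return
        self.remove(aid)
        self.insert(aid, a, b)

    def candidates(self, point: np.ndarray, r: float) -> set:
        lo = point - r
        hi = point + r
        (x0, y0, z0), (x1, y1, z1) = self._bin_range(lo, hi)
        out: set = set()
        for cell in itertools.product(
            range(x0, x1 + 1), range(y0, y1 + 1), range(z0, z1 + 1)
        ):
            s = self._cells.get(cell)
            if s:
                out |= s
        return out


class VascularNetwork:
    """All capillaries and agents plus the spatial index over the domain."""

    def __init__(self, domain=(500.0, 500.0, 500.0), d_max: float = 50.0,
                 bin_size: float = 10.0):
        domain = np.asarray(domain, dtype=float)
        if domain.shape != (3,) or np.any(domain <= 0):
            raise ConfigurationError(f"invalid domain extents {domain!r}")
        self.domain = domain
        self.d_max = float(d_max)
        self.agents: dict = {}
        self.capillaries: dict = {}
        self.units: dict = {}
        self.index = SpatialHash(bin_size)
        self._next_agent = 0
        self._next_capillary = 0
        self._next_unit = 0
        # append-only store of segments belonging to mature ("functional")
        # capillaries, kept as arrays for fast vectorized regression queries
        self._mat_a: list = []
        self._mat_b: list = []
        self._mat_cap: list = []
        self._mat_cache = None

    # ------------------------------------------------------------------ #
    # construction primitives
    # ------------------------------------------------------------------ #
    def in_domain(self, p: np.ndarray, tol: float = 1e-9) -> bool:
        return bool(np.all(p >= -tol) and np.all(p <= self.domain + tol))

    def new_capillary(self, parent_id=None, origin=None) -> Capillary:
        cid = self._next_capillary
        self._next_capillary += 1
        cap = Capillary(id=cid, parent_id=parent_id,
                        origin=None if origin is None else np.array(origin, dtype=float))
        self.capillaries[cid] = cap
        if parent_id is not None:
            self.capillaries[parent_id].child_ids.add(cid)
        return cap

    def new_unit(self, capillary_id: int) -> EndothelialUnit:
        uid = self._next_unit
        self._next_unit += 1
        unit = EndothelialUnit(id=uid, capillary_id=capillary_id)
        self.units[uid] = unit
        self.capillaries[capillary_id].unit_ids.append(uid)
        return unit

    def new_agent(self, capillary_id: int, unit_id: Optional[int], n1, n2,
                  cell_type: str, index: Optional[int] = None,
                  **kw) -> EndothelialAgent:
        """Low-level agent creation; ``index`` positions it in the chain.

        ``unit_id=None`` leaves the agent unattached to a unit (tips join the
        front unit only when their span is banked by a division).
        """
        n1 = np.array(n1, dtype=float)
        n2 = np.array(n2, dtype=float)
        for p in (n1, n2):
            if not self.in_domain(p):
                raise OutOfDomainError(f"node {p} outside domain {self.domain}")
        aid = self._next_agent
        self._next_agent += 1
        ag = EndothelialAgent(id=aid, node1=n1, node2=n2, cell_type=cell_type,
                              capillary_id=capillary_id, unit_id=unit_id, **kw)
        self.agents[aid] = ag
        cap = self.capillaries[capillary_id]
        if index is None:
            cap.agent_ids.append(aid)
        else:
            cap.agent_ids.insert(index, aid)
        if unit_id is not None:
            unit = self.units[unit_id]
            unit.agent_ids.append(aid)
            unit.length += ag.length
        self.index.insert(aid, n1, n2)
        return ag

    def append_agent(self, capillary_id: int, forward_position, cell_type: str,
                     unit_id: Optional[int] = None) -> int:
        """Append an agent at the leading end of a capillary.

        The new agent's trailing node is the previous leader's forward node
        (or the capillary origin for an empty capillary).  Raises
        ``OutOfDomainError`` for an out-of-bounds position and
        ``IllegalOperationError`` on a mature capillary.
        """
        cap = self.capillaries[capillary_id]
        if cap.mature:
            raise IllegalOperationError(
                f"capillary {capillary_id} is mature; cannot append")
        forward_position = np.asarray(forward_position, dtype=float)
        if not self.in_domain(forward_position):
            raise OutOfDomainError(
                f"position {forward_position} outside domain {self.domain}")
        if cap.agent_ids:
            n1 = self.agents[cap.agent_ids[-1]].node2.copy()
        elif cap.origin is not None:
            n1 = cap.origin.copy()
        else:
            raise IllegalOperationError(
                f"capillary {capillary_id} has no agents and no origin")
        if unit_id is None:
            unit_id = (cap.unit_ids[-1] if cap.unit_ids
                       else self.new_unit(capillary_id).id)
        ag = self.new_agent(capillary_id, unit_id, n1, forward_position, cell_type)
        return ag.id

    def move_node2(self, aid: int, new_pos: np.ndarray) -> None:
        ag = self.agents[aid]
        ag.node2 = np.array(new_pos, dtype=float)
        self.index.update(aid, ag.node1, ag.node2)

    def split_agent(self, aid: int, t: float) -> int:
        """Split an agent at parameter ``t`` into two chained agents.

        Geometry is unchanged; the second half becomes a new agent inserted
        right after the first in the capillary (and unit) order.  Returns the
        new agent id.  Not allowed on mature capillaries.
        """
        ag = self.agents[aid]
        cap = self.capillaries[ag.capillary_id]
        if cap.mature:
            raise IllegalOperationError("cannot split an agent of a mature capillary")
        mid = ag.node1 + t * (ag.node2 - ag.node1)
        old_n2 = ag.node2.copy()
        ag.node2 = mid.copy()
        self.index.update(aid, ag.node1, ag.node2)
        idx = cap.agent_ids.index(aid)
        new = self.new_agent(ag.capillary_id, ag.unit_id, mid, old_n2,
                             ag.cell_type, index=idx + 1, active=ag.active,
                             radius=ag.radius, divided=True)
        # keep unit ordering consistent with chain order; total unit length
        # is unchanged by a split
        unit = self.units[ag.unit_id]
        unit.length -= new.length
        unit.agent_ids.remove(new.id)
        unit.agent_ids.insert(unit.agent_ids.index(aid) + 1, new.id)
        return new.id

    def remove_capillary(self, capillary_id: int) -> float:
        """Remove a capillary and all of its agents/units; returns the length removed."""
        cap = self.capillaries.pop(capillary_id)
        removed = 0.0
        for aid in cap.agent_ids:
            ag = self.agents.pop(aid)
            removed += ag.length
            self.index.remove(aid)
        for uid in cap.unit_ids:
            del self.units[uid]
        if cap.parent_id is not None and cap.parent_id in self.capillaries:
            self.capillaries[cap.parent_id].child_ids.discard(capillary_id)
        return removed

    # ------------------------------------------------------------------ #
    # maturation
    # ------------------------------------------------------------------ #
    def mature_capillary(self, capillary_id: int) -> None:
        """Mark a capillary mature: agents quiesce (phalanx) and freeze."""
        cap = self.capillaries[capillary_id]
        if cap.mature:
            return
        cap.mature = True
        cap.tip_id = None
        cap.clock_agent_id = None
        for aid in cap.agent_ids:
            ag = self.agents[aid]
            ag.active = False
            ag.cell_type = PHALANX
            self._mat_a.append(ag.node1.copy())
            self._mat_b.append(ag.node2.copy())
            self._mat_cap.append(capillary_id)
        self._mat_cache = None
        cap.frozen = self.capillary_snapshot(capillary_id)

    def capillary_snapshot(self, capillary_id: int) -> bytes:
        cap = self.capillaries[capillary_id]
        coords = np.concatenate(
            [np.concatenate([self.agents[a].node1, self.agents[a].node2])
             for a in cap.agent_ids]) if cap.agent_ids else np.empty(0)
        return coords.tobytes()

    def mature_segments(self):
        """(A, B, cap_ids) arrays of all mature-capillary segments."""
        if self._mat_cache is None:
            if self._mat_a:
                self._mat_cache = (np.array(self._mat_a), np.array(self._mat_b),
                                   np.array(self._mat_cap))
            else:
                z = np.empty((0, 3))
                self._mat_cache = (z, z, np.empty(0, dtype=int))
        return self._mat_cache

    # ------------------------------------------------------------------ #
    # queries
    # ------------------------------------------------------------------ #
    def segment_hits(self, point, r: float):
        """Exact proximity query: agents whose segment passes within ``r``.

        Returns a list of ``(agent_id, distance, t)`` sorted by agent id,
        where ``t`` parameterizes the closest point on the segment.
        """
        if r <= 0:
            raise ValueError("query radius must be positive")
        point = np.asarray(point, dtype=float)
        # for large radii a full vectorized scan beats walking many bins
        if r > 4 * self.index.bin_size:
            ids = sorted(self.agents)
        else:
            ids = sorted(self.index.candidates(point, r))
        if not ids:
            return []
        A = np.array([self.agents[i].node1 for i in ids])
        B = np.array([self.agents[i].node2 for i in ids])
        dist, t = point_segments_distance(point, A, B)
        keep = dist <= r
        return [(ids[k], float(dist[k]), float(t[k]))
                for k in np.nonzero(keep)[0]]

    def neighbors_within(self, point, r: float) -> list:
        """Ids of all agents whose segment lies within distance ``r`` of ``point``."""
        return [aid for aid, _d, _t in self.segment_hits(point, r)]

    # ------------------------------------------------------------------ #
    # aggregates and validation
    # ------------------------------------------------------------------ #
    def agent_length(self, aid: int) -> float:
        return self.agents[aid].length

    def total_length(self) -> float:
        if not self.agents:
            return 0.0
        ids = list(self.agents)
        A = np.array([self.agents[i].node1 for i in ids])
        B = np.array([self.agents[i].node2 for i in ids])
        return float(np.linalg.norm(B - A, axis=1).sum())

    def capillary_length(self, capillary_id: int) -> float:
        return sum(self.agents[a].length
                   for a in self.capillaries[capillary_id].agent_ids)

    def validate(self) -> ValidationReport:
        """Check every structural invariant; returns the list of violations."""
        v: list = []
        seen: dict = {}
        for cid, cap in sorted(self.capillaries.items()):
            prev = None
            n_tip = 0
            for aid in cap.agent_ids:
                ag = self.agents.get(aid)
                if ag is None:
                    v.append(f"capillary {cid}: missing agent {aid}")
                    continue
                if aid in seen:
                    v.append(f"agent {aid} belongs to capillaries {seen[aid]} and {cid}")
                seen[aid] = cid
                for p in (ag.node1, ag.node2):
                    if not self.in_domain(p):
                        v.append(f"agent {aid}: node {p} out of bounds")
                if ag.length > self.d_max + 1e-9:
                    v.append(f"agent {aid}: length {ag.length:.3f} exceeds "
                             f"d_max {self.d_max}")
                if prev is not None and np.linalg.norm(ag.node1 - prev) > NODE_TOL:
                    v.append(f"capillary {cid}: chain broken before agent {aid}")
                prev = ag.node2
                if ag.cell_type == TIP:
                    n_tip += 1
            if cap.mature:
                if n_tip:
                    v.append(f"mature capillary {cid} contains a tip agent")
                if cap.frozen is not None and \
                        self.capillary_snapshot(cid) != cap.frozen:
                    v.append(f"mature capillary {cid} geometry changed")
            elif cap.agent_ids and n_tip != 1:
                v.append(f"growing capillary {cid} has {n_tip} tip agents")
        orphans = set(self.agents) - set(seen)
        for aid in sorted(orphans):
            v.append(f"agent {aid} belongs to no capillary")
        # unit bookkeeping
        for uid, unit in sorted(self.units.items()):
            real = sum(self.agents[a].length for a in unit.agent_ids
                       if a in self.agents)
            if abs(real - unit.length) > 1e-6 * max(1.0, real):
                v.append(f"unit {uid}: cached length {unit.length:.6f} != {real:.6f}")
        return ValidationReport(v)


def create_initial_network(config) -> VascularNetwork:
    """Build the starting vasculature: two mature capillaries of ten agents
    each, running along opposite edges of the cubic domain.

    Real mature microvessels are tortuous, so each capillary follows a
    gentle helix around its edge line (radius ``initial_helix_amplitude``,
    ``initial_helix_turns`` turns; amplitude 0 recovers straight vessels).
    Their agents are quiescent phalanx cells that never migrate or
    proliferate, but each agent forms its own endothelial unit that remains
    eligible for the (forced) first sprout.
    """
    domain = np.asarray(config.domain, dtype=float)
    if domain.shape != (3,) or np.any(domain <= 0):
        raise ConfigurationError(f"domain: invalid extents {config.domain!r}")
    net = VascularNetwork(domain=domain, d_max=config.migration.d_max,
                          bin_size=config.bin_size)
    off = float(config.initial_offset)
    amp = float(config.initial_helix_amplitude)
    turns = float(config.initial_helix_turns)
    axis = int(config.initial_axis)
    others = [k for k in range(3) if k != axis]
    n_agents = 10
    for which in (0, 1):
        # helix centerline offset so the vessel envelope stays `off` from
        # the two nearest faces
        center = np.zeros(3)
        for k in others:
            center[k] = off + amp if which == 0 else domain[k] - off - amp
        t = np.linspace(0.0, 1.0, n_agents + 1)
        if which == 1:
            t = t[::-1]
        theta = 2.0 * np.pi * turns * t
        pts = np.tile(center, (n_agents + 1, 1))
        pts[:, axis] = t * domain[axis]
        sign = 1.0 if which == 0 else -1.0
        pts[:, others[0]] += sign * amp * np.sin(theta)
        pts[:, others[1]] += sign * amp * np.cos(theta)
        cap = net.new_capillary(origin=pts[0].copy())
        for i in range(n_agents):
            unit = net.new_unit(cap.id)
            net.new_agent(cap.id, unit.id, pts[i], pts[i + 1], PHALANX,
                          active=False, radius=config.agent_radius)
        net.mature_capillary(cap.id)
    return net
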