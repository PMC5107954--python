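"""Growth-event rules: proliferation, sprouting, anastomosis, regression.

The front of a growing sprout advances by cell division.  A newly sprouted
tip performs a single, one-time division once its cell cycle elapses (the
former tip becomes the leading stalk and a short new tip is seeded ahead);
thereafter the leading stalk divides on its own clock, each division
"banking" the span the tip has migrated over as a new stalk agent and
re-seeding the tip ahead along its current direction.  The dividing stalk
deactivates, so exactly one cell-cycle clock runs per growing capillary and
the front extension rate is ~ min(MR, d_max / cell-cycle length).

Banked agents accumulate into endothelial-cell units; once a unit's length
exceeds ``e_min`` the next banked agent opens a new unit.  The first agent of
an un-sprouted, un-suppressed unit may initiate a sprout (once per unit);
sprouting laterally inhibits the adjacent units (Delta-Notch).  Tips that
migrate into another capillary anastomose, maturing both capillaries; new
sprouts within the regression distance ``d_r`` of a foreign mature vessel
retract.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._geometry import point_segments_distance
from .config import GrowthParams
from .errors import IllegalOperationError
from .network import (NODE_TOL, PHALANX, STALK, TIP, Capillary,
                      EndothelialAgent, VascularNetwork)

#: contact points closer than this to a sprout's own origin are not
#: anastomosis hits (the newborn sprout is still touching its parent there)
ORIGIN_EXCLUSION_PAD = 5.0


def sample_cell_cycle(params: GrowthParams, rng: np.random.Generator) -> float:
    """Cell-cycle length: Normal(cycle_mean, cycle_sd) floored at cycle_floor."""
    if params.cycle_sd == 0.0:
        return params.cycle_mean
    draw = rng.normal(params.cycle_mean, params.cycle_sd)
    return max(params.cycle_floor, float(draw))


def assign_to_front_unit(network: VascularNetwork, cap: Capillary,
                         agent: EndothelialAgent, e_min: float) -> int:
    """Attach a newly banked agent to the capillary's front unit.

    A fresh unit is opened when the front unit's accumulated length already
    exceeds ``e_min`` (or when the capillary has none yet).
    """
    if cap.unit_ids and network.units[cap.unit_ids[-1]].length <= e_min:
        unit = network.units[cap.unit_ids[-1]]
    else:
        unit = network.new_unit(cap.id)
    unit.agent_ids.append(agent.id)
    unit.length += agent.length
    agent.unit_id = unit.id
    return unit.id


def _seed_position(network: VascularNetwork, tip: EndothelialAgent,
                   seed_len: float) -> Optional[np.ndarray]:
    if tip.length == 0.0:
        return None
    pos = tip.node2 + seed_len * tip.direction
    if not network.in_domain(pos):
        return None
    return pos


def _bank_span(network: VascularNetwork, cap: Capillary, n1: np.ndarray,
               n2: np.ndarray, index: int, params: GrowthParams,
               rng: np.random.Generator, radius: float) -> list:
    """Lay the span n1-n2 down as collinear stalk agents at chain ``index``.

    The span a division hands over is divided into cell-sized agents of at
    most ``stalk_agent_length`` um, each joining the capillary's endothelial
    units under the ``e_min`` rule.  The front-most agent receives a fresh
    cell-cycle draw and becomes the capillary's running clock.  Returns the
    new agent ids (trailing to leading).
    """
    span = np.linalg.norm(n2 - n1)
    k = max(1, int(np.ceil(span / params.stalk_agent_length)))
    cuts = np.linspace(0.0, 1.0, k + 1)
    pts = n1[None, :] + cuts[:, None] * (n2 - n1)[None, :]
    ids = []
    for j in range(k):
        ag = network.new_agent(cap.id, None, pts[j].copy(), pts[j + 1].copy(),
                               STALK, index=index + j, active=False,
                               divided=True, radius=radius)
        assign_to_front_unit(network, cap, ag, params.e_min)
        ids.append(ag.id)
    leader = network.agents[ids[-1]]
    leader.active = True
    leader.cell_cycle_length = sample_cell_cycle(params, rng)
    leader.cell_cycle_elapsed = 0.0
    cap.clock_agent_id = leader.id
    return ids


def tip_proliferate(tip_agent: EndothelialAgent, network: VascularNetwork,
                    params: GrowthParams,
                    rng: np.random.Generator) -> Optional[int]:
    """One-time tip division of a sprouted tip whose clock has elapsed.

    The former tip's span is handed over as the leading stalk material
    (fresh cycle draw on the front agent) and a short new tip agent is
    created ahead, oriented along the old tip's direction.  Returns the new
    tip's id, or ``None`` when the clock has not elapsed or the seed
    position would leave the domain (the event is then skipped this step).
    Raises ``IllegalOperationError`` if this tip already divided.
    """
    if tip_agent.cell_type != TIP:
        raise IllegalOperationError(f"agent {tip_agent.id} is not a tip")
    if tip_agent.divided:
        raise IllegalOperationError(
            f"tip {tip_agent.id} already performed its one-time division")
    if tip_agent.cell_cycle_elapsed < tip_agent.cell_cycle_length:
        return None
    cap = network.capillaries[tip_agent.capillary_id]
    seed = _seed_position(network, tip_agent, params.new_tip_length)
    if seed is None:
        return None
    n1 = tip_agent.node1.copy()
    n2 = tip_agent.node2.copy()
    span = np.linalg.norm(n2 - n1)
    k = max(1, int(np.ceil(span / params.stalk_agent_length)))
    cuts = np.linspace(0.0, 1.0, k + 1)
    pts = n1[None, :] + cuts[:, None] * (n2 - n1)[None, :]
    idx = cap.agent_ids.index(tip_agent.id)
    # trailing sub-spans become quiescent stalk agents behind the former tip
    for j in range(k - 1):
        ag = network.new_agent(cap.id, None, pts[j].copy(), pts[j + 1].copy(),
                               STALK, index=idx + j, active=False,
                               divided=True, radius=tip_agent.radius)
        assign_to_front_unit(network, cap, ag, params.e_min)
    # the former tip becomes the new leading stalk (front sub-span)
    tip_agent.cell_type = STALK
    tip_agent.divided = True
    tip_agent.node1 = pts[-2].copy()
    network.index.update(tip_agent.id, tip_agent.node1, tip_agent.node2)
    tip_agent.cell_cycle_length = sample_cell_cycle(params, rng)
    tip_agent.cell_cycle_elapsed = 0.0
    assign_to_front_unit(network, cap, tip_agent, params.e_min)
    cap.clock_agent_id = tip_agent.id
    new_tip = network.new_agent(cap.id, None, n2.copy(), seed, TIP,
                                divided=True, radius=tip_agent.radius)
    cap.tip_id = new_tip.id
    return new_tip.id


def stalk_proliferate(capillary: Capillary, network: VascularNetwork,
                      params: GrowthParams,
                      rng: np.random.Generator) -> Optional[int]:
    """Division of the leading stalk: bank the tip's span, re-seed the tip.

    The tip's current segment becomes new stalk material (the front agent
    taking over the cell-cycle clock); the dividing stalk deactivates; the
    tip is advanced to a short seed segment ahead along its direction.
    Skipped (``None``) when the clock has not elapsed or the new tip
    position would leave the domain.
    """
    if capillary.mature:
        return None
    stalk = network.agents.get(capillary.clock_agent_id)
    tip = network.agents.get(capillary.tip_id)
    if stalk is None or tip is None or stalk.cell_type != STALK:
        return None
    if not stalk.active:
        return None  # this stalk already divided and deactivated
    if stalk.cell_cycle_elapsed < stalk.cell_cycle_length:
        return None
    seed = _seed_position(network, tip, params.new_tip_length)
    if seed is None:
        return None
    stalk.divided = True
    stalk.active = False
    idx = capillary.agent_ids.index(tip.id)
    ids = _bank_span(network, capillary, tip.node1.copy(), tip.node2.copy(),
                     idx, params, rng, tip.radius)
    tip.node1 = tip.node2.copy()
    tip.node2 = np.array(seed)
    network.index.update(tip.id, tip.node1, tip.node2)
    return ids[-1]


def proliferation_tick(network: VascularNetwork, capillary: Capillary,
                       params: GrowthParams, rng: np.random.Generator,
                       dt: float) -> Optional[str]:
    """Advance the capillary's single running clock; divide when elapsed."""
    agent = network.agents.get(capillary.clock_agent_id)
    if agent is None or capillary.mature:
        return None
    agent.cell_cycle_elapsed += dt
    if agent.cell_cycle_elapsed < agent.cell_cycle_length:
        return None
    if agent.cell_type == TIP:
        if tip_proliferate(agent, network, params, rng) is not None:
            return "tip_div"
    else:
        if stalk_proliferate(capillary, network, params, rng) is not None:
            return "stalk_div"
    return None


def eligible_sprout_agents(network: VascularNetwork) -> list:
    """Ids of unit-leading agents whose unit may still initiate a sprout."""
    out = []
    for uid in sorted(network.units):
        unit = network.units[uid]
        if unit.has_sprouted or unit.suppressed:
            continue
        first = unit.first_agent_id
        if first is None:
            continue
        ag = network.agents.get(first)
        if ag is None or ag.cell_type == TIP:
            continue
        out.append(first)
    return out


def attempt_sprout(agent: EndothelialAgent, network: VascularNetwork,
                   params: GrowthParams, rng: np.random.Generator,
                   dt: float = 1.0, force: bool = False) -> Optional[int]:
    """Probabilistically initiate a new capillary off this agent's unit.

    The sprout's trailing node is the agent's forward node; its initial tip
    direction is uniform random.  Sprouts proposed within
    ``boundary_margin`` of a domain face are rejected.  On success the
    sprouting unit is marked (once-per-cell rule) and the adjacent units of
    the same capillary are laterally inhibited.  ``force=True`` bypasses the
    Bernoulli draw (used for the forced first sprouts and by the engine,
    which draws for all eligible units at once).
    """
    unit = network.units.get(agent.unit_id)
    if unit is None or unit.has_sprouted or unit.suppressed:
        return None
    if unit.first_agent_id != agent.id or agent.cell_type == TIP:
        return None
    if not force:
        if rng.random() >= min(1.0, params.p_sprout * dt):
            return None
    origin = agent.node2.copy()
    margin = params.boundary_margin
    if np.any(origin < margin) or np.any(origin > network.domain - margin):
        return None  # sprout would sit on the boundary
    try:
        axis = agent.direction
    except ValueError:
        axis = None
    max_cos = np.cos(params.min_sprout_angle)
    seed = None
    for _ in range(100):
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n == 0.0:
            continue
        u = v / n
        # emerge transversally: reject directions hugging the vessel axis
        if axis is not None and abs(float(u @ axis)) > max_cos:
            continue
        cand = origin + params.new_tip_length * u
        if network.in_domain(cand):
            seed = cand
            break
    if seed is None:
        return None
    parent_cap = network.capillaries[agent.capillary_id]
    cap = network.new_capillary(parent_id=parent_cap.id, origin=origin)
    cap.source_unit_id = unit.id
    tip = network.new_agent(cap.id, None, origin, seed, TIP,
                            radius=agent.radius)
    tip.cell_cycle_length = sample_cell_cycle(params, rng)
    tip.cell_cycle_elapsed = 0.0
    cap.tip_id = tip.id
    cap.clock_agent_id = tip.id
    unit.has_sprouted = True
    # Delta-Notch lateral inhibition of the flanking units
    pos = parent_cap.unit_ids.index(unit.id)
    for j in (pos - 1, pos + 1):
        if 0 <= j < len(parent_cap.unit_ids):
            network.units[parent_cap.unit_ids[j]].suppressed = True
    return cap.id


def _connect_tip_to(network: VascularNetwork, tip: EndothelialAgent,
                    target: np.ndarray) -> bool:
    """Attach the tip's forward end to ``target`` (an existing node).

    Moves node 2 when the resulting agent stays within ``d_max``; otherwise
    appends a short connector agent so the hard length bound is never
    violated.  Returns False when no legal attachment exists.
    """
    if np.linalg.norm(target - tip.node1) <= network.d_max:
        network.move_node2(tip.id, target)
        return True
    if np.linalg.norm(target - tip.node2) <= network.d_max:
        network.new_agent(tip.capillary_id, tip.unit_id
                          if tip.unit_id is not None else
                          network.new_unit(tip.capillary_id).id,
                          tip.node2.copy(), target, STALK, active=False,
                          divided=True, radius=tip.radius)
        return True
    return False


def check_anastomosis(tip_agent: EndothelialAgent, network: VascularNetwork,
                      params: GrowthParams) -> str:
    """Fuse a just-moved tip with any foreign capillary within fusion range.

    Returns ``"tip_tip"`` when the nearest contact is another active tip (the
    tips join end-to-end), ``"tip_vessel"`` when it is a stalk/phalanx
    segment (fusion at the contact point), else ``"none"``.  Both capillaries
    involved become mature: their agents quiesce to phalanx and are frozen.
    """
    cap = network.capillaries.get(tip_agent.capillary_id)
    if cap is None or cap.mature or not tip_agent.active:
        return "none"
    hits = network.segment_hits(tip_agent.node2, params.fusion_radius)
    best = None
    excl = params.fusion_radius + ORIGIN_EXCLUSION_PAD
    for aid, dist, t in hits:
        other = network.agents[aid]
        if other.capillary_id == cap.id:
            continue
        contact = other.node1 + t * (other.node2 - other.node1)
        if cap.origin is not None:
            d_origin = np.linalg.norm(contact - cap.origin)
            if d_origin < excl:
                continue  # shared attachment node region
            if other.capillary_id == cap.parent_id and \
                    d_origin < params.origin_exclusion:
                continue  # sprout base is continuous with the parent vessel
        if best is None or dist < best[1]:
            best = (aid, dist, t)
    if best is None:
        return "none"
    aid, _dist, t = best
    other = network.agents[aid]
    other_cap = network.capillaries[other.capillary_id]
    if other.cell_type == TIP and other.active:
        target = other.node2.copy()
        if not _connect_tip_to(network, tip_agent, target):
            return "none"
        outcome = "tip_tip"
    else:
        contact = other.node1 + t * (other.node2 - other.node1)
        d1 = np.linalg.norm(contact - other.node1)
        d2 = np.linalg.norm(contact - other.node2)
        if other_cap.mature or other.cell_type == TIP or \
                min(d1, d2) < NODE_TOL:
            # snap to the nearest existing node: mature geometry is frozen
            target = (other.node1 if d1 <= d2 else other.node2).copy()
        else:
            new_id = network.split_agent(aid, t)
            target = network.agents[new_id].node1.copy()
        if not _connect_tip_to(network, tip_agent, target):
            return "none"
        outcome = "tip_vessel"
    tip_agent.active = False
    if other.cell_type == TIP:
        other.active = False
    network.mature_capillary(cap.id)
    network.mature_capillary(other_cap.id)
    return outcome


def regression_due(capillary: Capillary, network: VascularNetwork,
                   params: GrowthParams) -> bool:
    """True iff a foreign mature ("functional") vessel lies within d_r of the tip."""
    if capillary.mature or capillary.tip_id is None or params.d_r <= 0:
        return False
    tip = network.agents[capillary.tip_id]
    A, B, cap_ids = network.mature_segments()
    if len(A) == 0:
        return False
    mask = cap_ids != (capillary.parent_id if capillary.parent_id is not None
                       else -1)
    if not np.any(mask):
        return False
    dist, _t = point_segments_distance(tip.node2, A[mask], B[mask])
    return bool(dist.min() <= params.d_r)


def regress_sprout(capillary: Capillary, network: VascularNetwork) -> float:
    """Remove a regressing sprout; the parent unit's sprout flag is restored."""
    src = getattr(capillary, "source_unit_id", None)
    if src is not None and src in network.units:
        network.units[src].has_sprouted = False
    return network.remove_capillary(capillary.id)


def check_regression(new_sprout: Capillary, network: VascularNetwork,
                     params: GrowthParams) -> bool:
    """Apply the regression rule to a sprout; removes it when triggered.

    Returns whether the sprout regressed.
    """
    if not regression_due(new_sprout, network, params):
        return False
    regress_sprout(new_sprout, network)
    return True
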