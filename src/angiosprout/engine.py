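"""Simulation orchestration: event ordering, time, seeding, capture.

Each step (default dt = 1 h) executes, in order:

1. tip-cell migration (filopodia search + displacement) with an anastomosis
   check after every move;
2. proliferation — each growing capillary's single running cell-cycle clock
   advances, divisions fire when elapsed, and any advanced tip is re-checked
   for anastomosis;
3. sprouting — every eligible endothelial unit draws against ``p_sprout``,
   new sprouts are immediately tested for regression; then the ongoing
   regression hazard is applied to all young (immature, childless) sprouts.

During the very first step one forced sprout is created on each of the two
initial capillaries, which is how sprouting angiogenesis starts.

Randomness is split into four independent streams (initialisation,
migration, proliferation, sprouting) spawned from the master seed, so
perturbing one mechanism's parameters does not shift another's draws.  The
same (config, seed) pair reproduces every output byte.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import growth, metrics, migration
from .config import SimulationConfig
from .errors import AngiosproutError, ConfigurationError
from .network import NODE_TOL, VascularNetwork, create_initial_network


@dataclass
class SimulationState:
    config: SimulationConfig
    network: VascularNetwork
    rngs: dict
    t: float = 0.0
    step_count: int = 0
    events: list = field(default_factory=list)
    series: list = field(default_factory=list)


@dataclass
class SimulationResult:
    """Final network plus the morphometric time series and the event log."""

    config: SimulationConfig
    seed: int
    network: VascularNetwork
    series: pd.DataFrame
    events: pd.DataFrame
    final_metrics: "metrics.MetricsReport"


def _rng_streams(seed: int) -> dict:
    names = ("init", "migration", "proliferation", "sprouting")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.Generator(np.random.PCG64(c))
            for n, c in zip(names, children)}


def initialize(config: SimulationConfig) -> SimulationState:
    """Build the two-capillary initial network and the RNG streams.

    The forced first sprouts are created during the first :func:`step`.
    """
    config.validate()
    net = create_initial_network(config)
    return SimulationState(config=config, network=net,
                           rngs=_rng_streams(config.seed))


def _log(state: SimulationState, etype: str, cap_id, pos) -> None:
    state.events.append(
        {"t": state.t, "event": etype, "capillary_id": cap_id,
         "x": float(pos[0]), "y": float(pos[1]), "z": float(pos[2])})


def _forced_initial_sprouts(state: SimulationState) -> None:
    net = state.network
    rng = state.rngs["init"]
    gp = state.config.growth
    for cap_id in sorted(net.capillaries):
        cap = net.capillaries[cap_id]
        if cap.parent_id is not None:
            continue
        candidates = [u for u in cap.unit_ids
                      if not net.units[u].has_sprouted
                      and not net.units[u].suppressed]
        if not candidates:
            continue
        # random position along the capillary; retry (e.g. a unit whose
        # forward node sits on the domain boundary cannot sprout)
        new_id = None
        agent = None
        for uid in rng.permutation(candidates):
            agent = net.agents[net.units[int(uid)].first_agent_id]
            new_id = growth.attempt_sprout(agent, net, gp, rng, force=True)
            if new_id is not None:
                break
        if new_id is not None:
            net.capillaries[new_id].born = state.t
            _log(state, "sprout", new_id, net.capillaries[new_id].origin)
            if growth.check_regression(net.capillaries[new_id], net, gp):
                _log(state, "regression", new_id, agent.node2)


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one time step (in place)."""
    cfg = state.config
    net = state.network
    dt = cfg.dt
    gp = cfg.growth
    mp = cfg.migration

    if state.step_count == 0:
        _forced_initial_sprouts(state)

    # -- phase 1: tip migration + anastomosis -------------------------- #
    rng_m = state.rngs["migration"]
    for cap_id in sorted(net.capillaries):
        cap = net.capillaries.get(cap_id)
        if cap is None or cap.mature or cap.tip_id is None:
            continue
        tip = net.agents[cap.tip_id]
        if not tip.active or tip.length == 0.0:
            continue
        direction = migration.filopodia_search(tip, cfg.vegf, mp,
                                               net.domain, rng_m)
        moved = migration.migrate_tip(tip, direction, mp, dt, net)
        if moved > 0.0:
            outcome = growth.check_anastomosis(tip, net, gp)
            if outcome != "none":
                _log(state, f"anastomosis_{'tt' if outcome == 'tip_tip' else 'tv'}",
                     cap_id, tip.node2)

    # -- phase 2: proliferation + anastomosis -------------------------- #
    rng_p = state.rngs["proliferation"]
    for cap_id in sorted(net.capillaries):
        cap = net.capillaries.get(cap_id)
        if cap is None or cap.mature:
            continue
        fired = growth.proliferation_tick(net, cap, gp, rng_p, dt)
        if fired is not None:
            tip = net.agents.get(cap.tip_id)
            _log(state, fired, cap_id,
                 tip.node2 if tip is not None else np.zeros(3))
            if tip is not None and tip.active:
                outcome = growth.check_anastomosis(tip, net, gp)
                if outcome != "none":
                    _log(state,
                         f"anastomosis_{'tt' if outcome == 'tip_tip' else 'tv'}",
                         cap_id, tip.node2)

    # -- phase 3: sprouting + regression ------------------------------- #
    rng_s = state.rngs["sprouting"]
    eligible = growth.eligible_sprout_agents(net)
    if eligible:
        p = min(1.0, gp.p_sprout * dt)
        draws = rng_s.random(len(eligible))
        for aid, r in zip(eligible, draws):
            if r >= p:
                continue
            agent = net.agents.get(aid)
            if agent is None:
                continue
            new_id = growth.attempt_sprout(agent, net, gp, rng_s, force=True)
            if new_id is not None:
                net.capillaries[new_id].born = state.t
                _log(state, "sprout", new_id, net.capillaries[new_id].origin)
                if growth.check_regression(net.capillaries[new_id], net, gp):
                    _log(state, "regression", new_id, agent.node2)

    # ongoing hazard: newly formed sprouts (still a single agent and younger
    # than the regression window) retract when a functional vessel matures
    # within d_r of their tip
    for cap_id in sorted(net.capillaries) if gp.regression_window > 0 else ():
        cap = net.capillaries.get(cap_id)
        if cap is None or cap.mature or cap.parent_id is None or cap.child_ids:
            continue
        if len(cap.agent_ids) > 1:
            continue
        if cap.born is not None and state.t - cap.born > gp.regression_window:
            continue
        tip = net.agents.get(cap.tip_id)
        pos = tip.node2.copy() if tip is not None else np.zeros(3)
        if growth.check_regression(cap, net, gp):
            _log(state, "regression", cap_id, pos)

    state.t += dt
    state.step_count += 1
    return state


def quick_bifurcation_count(net: VascularNetwork) -> int:
    """Branch points counted from node multiplicity (degree >= 3)."""
    pts = []
    for ag in net.agents.values():
        if ag.length > 0.0:
            pts.append(ag.node1)
            pts.append(ag.node2)
    if not pts:
        return 0
    arr = np.round(np.asarray(pts) / NODE_TOL).astype(np.int64)
    _uniq, counts = np.unique(arr, axis=0, return_counts=True)
    return int(np.count_nonzero(counts >= 3))


def _record(state: SimulationState) -> None:
    net = state.network
    vol = state.config.volume_mm3
    total_mm = net.total_length() / 1000.0
    state.series.append({
        "t_hours": state.t,
        "n_agents": len(net.agents),
        "n_capillaries": len(net.capillaries),
        "total_length_mm": total_mm,
        "vld": total_mm / vol,
        "bd": quick_bifurcation_count(net) / vol,
    })


def run(config: SimulationConfig,
        validate_every: Optional[int] = None) -> SimulationResult:
    """Run a full simulation and return the result bundle.

    ``validate_every`` optionally re-checks every structural invariant each N
    steps and raises on the first violation (never silent corruption).
    """
    config = copy.deepcopy(config)
    state = initialize(config)
    record_every = max(1, int(round(config.metric_interval / config.dt)))
    _record(state)
    for k in range(config.n_steps):
        step(state)
        if (k + 1) % record_every == 0 or k + 1 == config.n_steps:
            _record(state)
        if validate_every and (k + 1) % validate_every == 0:
            report = state.network.validate()
            if not report.ok:
                raise AngiosproutError(
                    "invariant violation at t=%.1f h: %s"
                    % (state.t, "; ".join(report.violations[:5])))
    series = pd.DataFrame(state.series).drop_duplicates(subset="t_hours")
    events = pd.DataFrame(
        state.events,
        columns=["t", "event", "capillary_id", "x", "y", "z"])
    final = metrics.network_metrics(
        state.network, volume_mm3=config.volume_mm3,
        convention=config.segment_convention)
    return SimulationResult(config=config, seed=config.seed,
                            network=state.network, series=series,
                            events=events, final_metrics=final)
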