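import dataclasses

import numpy as np
import pytest

from angiosprout import SimulationConfig, baseline_config
from angiosprout.network import PHALANX, STALK, TIP, VascularNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    cfg = SimulationConfig(seed=0)
    cfg.validate()
    return cfg


def short_config(pr=0.025, mr=10.0, days=2.0, seed=0, **kw):
    return baseline_config(pr=pr, mr=mr, seed=seed, duration_days=days, **kw)


@pytest.fixture
def small_network():
    """A single straight 3-agent growing capillary with an active tip."""
    net = VascularNetwork(domain=(500.0, 500.0, 500.0), d_max=120.0)
    cap = net.new_capillary(origin=np.array([100.0, 250.0, 250.0]))
    unit = net.new_unit(cap.id)
    net.new_agent(cap.id, unit.id, [100.0, 250.0, 250.0],
                  [140.0, 250.0, 250.0], STALK, active=False)
    unit2 = net.new_unit(cap.id)
    net.new_agent(cap.id, unit2.id, [140.0, 250.0, 250.0],
                  [180.0, 250.0, 250.0], STALK, active=False)
    tip = net.new_agent(cap.id, None, [180.0, 250.0, 250.0],
                        [200.0, 250.0, 250.0], TIP)
    cap.tip_id = tip.id
    cap.clock_agent_id = tip.id
    return net


def random_segment_network(n_agents, rng, domain=500.0, seg_len=30.0):
    """Many independent short capillaries scattered in the cube."""
    net = VascularNetwork(domain=(domain,) * 3, d_max=seg_len * 2)
    for _ in range(n_agents):
        a = rng.uniform(seg_len, domain - seg_len, 3)
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        b = np.clip(a + seg_len * d, 0, domain)
        cap = net.new_capillary(origin=a)
        unit = net.new_unit(cap.id)
        net.new_agent(cap.id, unit.id, a, b, PHALANX, active=False)
    return net


def brute_force_neighbors(net, point, r):
    """Independent O(N) oracle: exact point-to-segment scan over all agents."""
    point = np.asarray(point, dtype=float)
    out = []
    for aid in sorted(net.agents):
        ag = net.agents[aid]
        ab = ag.node2 - ag.node1
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((point - ag.node1) @ ab / denom, 0, 1))
        q = ag.node1 + t * ab
        if np.linalg.norm(point - q) <= r:
            out.append(aid)
    return out
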