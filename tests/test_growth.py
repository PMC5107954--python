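import dataclasses

import numpy as np
import pytest

from angiosprout.config import GrowthParams
from angiosprout.errors import IllegalOperationError
from angiosprout.growth import (attempt_sprout, check_anastomosis,
                                check_regression, regression_due,
                                sample_cell_cycle, stalk_proliferate,
                                tip_proliferate)
from angiosprout.network import PHALANX, STALK, TIP, VascularNetwork


@pytest.fixture
def gp():
    return GrowthParams(cycle_mean=40.0, cycle_sd=4.0)


class TestCellCycle:
    def test_zero_sd_is_deterministic(self, rng):
        p = GrowthParams(cycle_mean=40.0, cycle_sd=0.0)
        assert all(sample_cell_cycle(p, rng) == 40.0 for _ in range(10))

    def test_mean_matches_inverse_proliferation_rate(self):
        # PR = 0.025/hr corresponds to division every 40 h
        rng = np.random.default_rng(0)
        p = GrowthParams(cycle_mean=1 / 0.025, cycle_sd=4.0)
        draws = [sample_cell_cycle(p, rng) for _ in range(10_000)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 40.0) < 3 * se

    def test_printed_cycle_lengths(self):
        # divisions every 68, 40 and 12 hours for the three studied rates
        for pr, hours in ((0.0147, 68.0), (0.025, 40.0), (0.083, 12.0)):
            assert 1.0 / pr == pytest.approx(hours, abs=0.1)

    def test_truncated_below_at_floor(self):
        rng = np.random.default_rng(3)
        p = GrowthParams(cycle_mean=2.0, cycle_sd=10.0, cycle_floor=1.0)
        assert min(sample_cell_cycle(p, rng) for _ in range(500)) >= 1.0


def _sprout_network(gp, tip_len=30.0, origin=(250.0, 250.0, 250.0)):
    """A lone single-agent sprout with a parent scaffold capillary."""
    net = VascularNetwork(domain=(500.0,) * 3, d_max=120.0)
    parent = net.new_capillary(origin=np.array([150.0, 250.0, 250.0]))
    unit = net.new_unit(parent.id)
    net.new_agent(parent.id, unit.id, [150.0, 250.0, 250.0],
                  list(origin), PHALANX, active=False)
    net.mature_capillary(parent.id)
    cap = net.new_capillary(parent_id=parent.id, origin=np.array(origin))
    tip = net.new_agent(cap.id, None, list(origin),
                        [origin[0], origin[1] + tip_len, origin[2]], TIP)
    tip.cell_cycle_length = 40.0
    cap.tip_id = tip.id
    cap.clock_agent_id = tip.id
    return net, cap, tip


class TestTipProliferation:
    def test_division_waits_for_clock(self, gp, rng):
        net, cap, tip = _sprout_network(gp)
        tip.cell_cycle_elapsed = 10.0
        assert tip_proliferate(tip, net, gp, rng) is None

    def test_division_creates_new_leading_tip(self, gp, rng):
        net, cap, tip = _sprout_network(gp)
        tip.cell_cycle_elapsed = 41.0
        before = len(cap.agent_ids)
        new_id = tip_proliferate(tip, net, gp, rng)
        assert new_id is not None
        assert len(cap.agent_ids) >= before + 1
        assert net.agents[cap.agent_ids[-1]].cell_type == TIP
        assert net.agents[cap.agent_ids[-2]].cell_type == STALK
        assert net.validate().ok

    def test_one_time_rule(self, gp, rng):
        net, cap, tip = _sprout_network(gp)
        tip.cell_cycle_elapsed = 41.0
        tip_proliferate(tip, net, gp, rng)
        with pytest.raises(IllegalOperationError):
            tip_proliferate(tip, net, gp, rng)  # former tip is now a stalk
        new_tip = net.agents[cap.tip_id]
        new_tip.cell_cycle_elapsed = 100.0
        with pytest.raises(IllegalOperationError):
            tip_proliferate(new_tip, net, gp, rng)  # lineage already divided


class TestStalkProliferation:
    def _divided_sprout(self, gp, rng, tip_len=30.0):
        net, cap, tip = _sprout_network(gp, tip_len=tip_len)
        tip.cell_cycle_elapsed = 41.0
        tip_proliferate(tip, net, gp, rng)
        return net, cap

    def test_front_advances_and_old_stalk_deactivates(self, gp, rng):
        net, cap = self._divided_sprout(gp, rng)
        stalk = net.agents[cap.clock_agent_id]
        tip = net.agents[cap.tip_id]
        # let the tip elongate, then let the stalk's clock elapse
        net.move_node2(tip.id, tip.node2 + [0.0, 50.0, 0.0])
        stalk.cell_cycle_elapsed = stalk.cell_cycle_length + 1.0
        new_id = stalk_proliferate(cap, net, gp, rng)
        assert new_id is not None
        assert not stalk.active
        assert net.agents[cap.clock_agent_id].active
        assert net.agents[cap.tip_id].length == pytest.approx(
            gp.new_tip_length)
        assert net.validate().ok

    def test_unit_growth_follows_e_min_rule(self, gp, rng):
        # banked material keeps joining the front unit until its length
        # exceeds e_min, then a fresh (sprout-eligible) unit opens
        net, cap = self._divided_sprout(gp, rng, tip_len=10.0)
        units_before = len(cap.unit_ids)
        front = net.units[cap.unit_ids[-1]]
        assert front.length <= gp.e_min  # 10 um of banked span so far
        tip = net.agents[cap.tip_id]
        net.move_node2(tip.id, tip.node2 + [0.0, 15.0, 0.0])
        stalk = net.agents[cap.clock_agent_id]
        stalk.cell_cycle_elapsed = 1e9
        stalk_proliferate(cap, net, gp, rng)
        assert len(cap.unit_ids) == units_before  # 10 < e_min: same unit
        tip = net.agents[cap.tip_id]
        net.move_node2(tip.id, tip.node2 + [0.0, 15.0, 0.0])
        stalk = net.agents[cap.clock_agent_id]
        stalk.cell_cycle_elapsed = 1e9
        stalk_proliferate(cap, net, gp, rng)
        assert len(cap.unit_ids) == units_before + 1  # 25 > e_min: new unit

    def test_skipped_when_new_tip_would_leave_domain(self, gp, rng):
        net, cap = self._divided_sprout(gp, rng)
        tip = net.agents[cap.tip_id]
        # point the tip straight at the domain face and park it there
        tip.node1 = np.array([250.0, 499.0, 250.0])
        tip.node2 = np.array([250.0, 500.0, 250.0])
        net.index.update(tip.id, tip.node1, tip.node2)
        stalk = net.agents[cap.clock_agent_id]
        stalk.cell_cycle_elapsed = 1e9
        n_agents = len(cap.agent_ids)
        assert stalk_proliferate(cap, net, gp, rng) is None
        assert len(cap.agent_ids) == n_agents


def _scaffold(gp, n_units=5, y=250.0, mature=True):
    """A straight scaffold capillary of n 40-um phalanx units along x."""
    net = VascularNetwork(domain=(500.0,) * 3, d_max=120.0)
    cap = net.new_capillary(origin=np.array([150.0, y, 250.0]))
    for i in range(n_units):
        unit = net.new_unit(cap.id)
        net.new_agent(cap.id, unit.id, [150.0 + 40.0 * i, y, 250.0],
                      [150.0 + 40.0 * (i + 1), y, 250.0], PHALANX,
                      active=False)
    if mature:
        net.mature_capillary(cap.id)
    return net, cap


class TestSprouting:
    def test_zero_probability_never_sprouts(self, gp, rng):
        net, cap = _scaffold(gp)
        p = dataclasses.replace(gp, p_sprout=0.0)
        agent = net.agents[net.units[cap.unit_ids[2]].first_agent_id]
        assert all(attempt_sprout(agent, net, p, rng) is None
                   for _ in range(1000))

    def test_certain_sprout_and_lateral_inhibition(self, gp, rng):
        net, cap = _scaffold(gp)
        p = dataclasses.replace(gp, p_sprout=1.0)
        unit = net.units[cap.unit_ids[2]]
        agent = net.agents[unit.first_agent_id]
        new_id = attempt_sprout(agent, net, p, rng)
        assert new_id is not None
        sprout = net.capillaries[new_id]
        assert np.array_equal(sprout.origin, agent.node2)
        assert net.agents[sprout.tip_id].cell_type == TIP
        assert net.agents[sprout.tip_id].active
        assert unit.has_sprouted
        assert net.units[cap.unit_ids[1]].suppressed
        assert net.units[cap.unit_ids[3]].suppressed

    def test_once_per_unit(self, gp, rng):
        net, cap = _scaffold(gp)
        p = dataclasses.replace(gp, p_sprout=1.0)
        agent = net.agents[net.units[cap.unit_ids[2]].first_agent_id]
        assert attempt_sprout(agent, net, p, rng) is not None
        assert attempt_sprout(agent, net, p, rng) is None

    def test_boundary_sprouts_rejected(self, gp, rng):
        net, cap = _scaffold(gp, y=2.0)  # within one agent radius of a face
        p = dataclasses.replace(gp, p_sprout=1.0)
        agent = net.agents[net.units[cap.unit_ids[2]].first_agent_id]
        assert attempt_sprout(agent, net, p, rng) is None

    def test_sprout_emerges_transversally(self, gp, rng):
        net, cap = _scaffold(gp)
        p = dataclasses.replace(gp, p_sprout=1.0)
        for uid in cap.unit_ids:
            agent = net.agents[net.units[uid].first_agent_id]
            new_id = attempt_sprout(agent, net, p, rng)
            if new_id is None:
                continue
            tip = net.agents[net.capillaries[new_id].tip_id]
            cos = abs(tip.direction @ np.array([1.0, 0.0, 0.0]))
            assert cos <= np.cos(p.min_sprout_angle) + 1e-9


class TestAnastomosis:
    def test_two_tips_fuse_head_on(self, gp):
        net = VascularNetwork(domain=(500.0,) * 3, d_max=120.0)
        tips = []
        for x0, x1 in ((200.0, 240.0), (284.0, 244.0)):
            cap = net.new_capillary(origin=np.array([x0, 250.0, 250.0]))
            t = net.new_agent(cap.id, None, [x0, 250.0, 250.0],
                              [x1, 250.0, 250.0], TIP)
            cap.tip_id = t.id
            tips.append(t)
        outcome = check_anastomosis(tips[0], net, gp)
        assert outcome == "tip_tip"
        assert np.array_equal(tips[0].node2, tips[1].node2)
        assert all(c.mature for c in net.capillaries.values())
        assert not tips[0].active and not tips[1].active
        assert net.validate().ok

    def test_tip_fuses_into_vessel_segment(self, gp):
        net, scaffold_cap = _scaffold(gp, mature=False)
        cap = net.new_capillary(origin=np.array([250.0, 300.0, 250.0]))
        tip = net.new_agent(cap.id, None, [250.0, 300.0, 250.0],
                            [251.0, 254.0, 250.0], TIP)
        cap.tip_id = tip.id
        outcome = check_anastomosis(tip, net, gp)
        assert outcome == "tip_vessel"
        # fusion node lies on the struck scaffold line y=250
        assert tip.node2[1] == pytest.approx(250.0)
        assert net.capillaries[cap.id].mature
        assert net.capillaries[scaffold_cap.id].mature
        assert net.validate().ok

    def test_isolated_tip_no_fusion(self, gp):
        net, _ = _scaffold(gp)
        cap = net.new_capillary(origin=np.array([250.0, 400.0, 250.0]))
        tip = net.new_agent(cap.id, None, [250.0, 400.0, 250.0],
                            [250.0, 380.0, 250.0], TIP)
        cap.tip_id = tip.id
        assert check_anastomosis(tip, net, gp) == "none"

    def test_newborn_sprout_does_not_fuse_with_parent(self, gp, rng):
        net, cap = _scaffold(gp)
        p = dataclasses.replace(gp, p_sprout=1.0)
        agent = net.agents[net.units[cap.unit_ids[2]].first_agent_id]
        new_id = attempt_sprout(agent, net, p, rng)
        tip = net.agents[net.capillaries[new_id].tip_id]
        assert check_anastomosis(tip, net, gp) == "none"


class TestRegression:
    def _sprout_with_foreign_vessel(self, gp, distance):
        """A newborn sprout whose tip sits `distance` from a foreign mature
        capillary (its own parent is always closer)."""
        net, parent = _scaffold(gp, y=250.0)
        other = net.new_capillary(origin=np.array([150.0, 250.0 + distance,
                                                   250.0]))
        unit = net.new_unit(other.id)
        net.new_agent(other.id, unit.id, [150.0, 250.0 + distance, 250.0],
                      [350.0, 250.0 + distance, 250.0], PHALANX, active=False)
        net.mature_capillary(other.id)
        sprout = net.new_capillary(parent_id=parent.id,
                                   origin=np.array([250.0, 250.0, 250.0]))
        tip = net.new_agent(sprout.id, None, [250.0, 250.0, 250.0],
                            [250.0, 250.1, 250.0], TIP)
        sprout.tip_id = tip.id
        return net, sprout

    def test_only_parent_in_range_is_ignored(self, gp):
        net, parent = _scaffold(gp)
        sprout = net.new_capillary(parent_id=parent.id,
                                   origin=np.array([250.0, 250.0, 250.0]))
        tip = net.new_agent(sprout.id, None, [250.0, 250.0, 250.0],
                            [250.0, 250.1, 250.0], TIP)
        sprout.tip_id = tip.id
        assert not regression_due(sprout, net, gp)

    def test_foreign_vessel_just_inside_triggers_removal(self, gp):
        net, sprout = self._sprout_with_foreign_vessel(gp, gp.d_r - 1.0)
        total = net.total_length()
        length = net.capillary_length(sprout.id)
        assert check_regression(sprout, net, gp)
        assert sprout.id not in net.capillaries
        assert all(a.capillary_id != sprout.id for a in net.agents.values())
        assert net.total_length() == pytest.approx(total - length, rel=1e-9)

    def test_foreign_vessel_just_outside_is_safe(self, gp):
        net, sprout = self._sprout_with_foreign_vessel(gp, gp.d_r + 1.0)
        assert not check_regression(sprout, net, gp)

    def test_sprout_flag_restored_after_retraction(self, gp, rng):
        net, parent = _scaffold(gp)
        other = net.new_capillary(origin=np.array([150.0, 300.0, 250.0]))
        unit = net.new_unit(other.id)
        net.new_agent(other.id, unit.id, [150.0, 300.0, 250.0],
                      [350.0, 300.0, 250.0], PHALANX, active=False)
        net.mature_capillary(other.id)
        p = dataclasses.replace(gp, p_sprout=1.0)
        agent = net.agents[net.units[cap_id_first := parent.unit_ids[2]]
                           .first_agent_id]
        new_id = attempt_sprout(agent, net, p, rng)
        assert net.units[cap_id_first].has_sprouted
        assert check_regression(net.capillaries[new_id], net, p)
        assert not net.units[cap_id_first].has_sprouted

    def test_zero_distance_disables_regression(self, gp):
        p = dataclasses.replace(gp, d_r=0.0)
        net, sprout = self._sprout_with_foreign_vessel(p, 10.0)
        assert not regression_due(sprout, net, p)

    def test_infinite_distance_kills_any_sprout_near_foreign_vessel(self, gp):
        p = dataclasses.replace(gp, d_r=1e9)
        net, sprout = self._sprout_with_foreign_vessel(p, 240.0)
        assert regression_due(sprout, net, p)
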