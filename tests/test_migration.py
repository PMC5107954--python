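import math

import numpy as np
import pytest

from angiosprout.config import MigrationParams
from angiosprout.errors import IllegalOperationError
from angiosprout.migration import (candidate_directions, direction_score,
                                   direction_scores, filopodia_search,
                                   migrate_tip, persistence_weight,
                                   select_direction)
from angiosprout.network import STALK, TIP, VascularNetwork
from angiosprout.vegf import VegfField


class TestCandidateDirections:
    def test_unit_norm(self, rng):
        c = candidate_directions(1, rng)
        assert np.linalg.norm(c[0]) == pytest.approx(1.0, abs=1e-12)

    def test_isotropy_of_large_sample(self, rng):
        c = candidate_directions(10_000, rng)
        assert np.linalg.norm(c.mean(axis=0)) < 0.05

    def test_seeded_determinism(self):
        a = candidate_directions(50, np.random.default_rng(7))
        b = candidate_directions(50, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_requires_at_least_one(self, rng):
        with pytest.raises(ValueError):
            candidate_directions(0, rng)


class TestPersistenceWeight:
    def test_maximal_at_zero(self):
        assert persistence_weight(0.0, math.pi / 6) == 1.0

    def test_closed_form_at_sigma(self):
        assert persistence_weight(0.5, 0.5) == pytest.approx(math.exp(-0.5))

    def test_reversal_suppressed(self):
        w = persistence_weight(math.pi, math.pi / 6)
        assert w == pytest.approx(math.exp(-18.0))

    def test_strictly_decreasing(self):
        thetas = np.linspace(0, math.pi, 30)
        ws = [persistence_weight(t, math.pi / 6) for t in thetas]
        assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_angle_folded_into_range(self):
        assert persistence_weight(-0.3, 0.5) == persistence_weight(0.3, 0.5)


class TestDirectionScore:
    def test_gamma_one_is_pure_persistence(self):
        p = MigrationParams(gamma=1.0)
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        for vegf in (0.0, 5.0, 100.0):
            assert direction_score(v, u, vegf, p, vegf_reference=100.0) == \
                pytest.approx(persistence_weight(math.pi / 2, p.sigma))

    def test_gamma_zero_uniform_vegf_equal_scores(self, rng):
        p = MigrationParams(gamma=0.0)
        u = np.array([1.0, 0.0, 0.0])
        cands = candidate_directions(10, rng)
        scores = direction_scores(cands, u, np.full(10, 20.0), p)
        assert np.allclose(scores, scores[0])

    def test_persistence_favours_current_heading(self):
        p = MigrationParams(gamma=0.5)
        u = np.array([1.0, 0.0, 0.0])
        ahead = direction_score(u, u, 20.0, p, vegf_reference=20.0)
        side = direction_score([0.0, 1.0, 0.0], u, 20.0, p, vegf_reference=20.0)
        assert ahead > side

    def test_all_zero_vegf_drops_chemotaxis(self, rng):
        p = MigrationParams(gamma=0.5)
        u = np.array([1.0, 0.0, 0.0])
        cands = candidate_directions(8, rng)
        scores = direction_scores(cands, u, np.zeros(8), p)
        pure = direction_scores(cands, u, np.zeros(8),
                                MigrationParams(gamma=1.0)) * 0.5
        assert np.allclose(scores, pure)


class TestSelectDirection:
    def test_single_candidate_always_chosen(self, rng):
        c = np.array([[0.0, 0.0, 1.0]])
        assert np.array_equal(select_direction(c, [3.0], rng), c[0])

    def test_equal_scores_split_evenly(self):
        rng = np.random.default_rng(5)
        c = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        n = 10_000
        hits = sum(select_direction(c, [1.0, 1.0], rng)[0] == 1.0
                   for _ in range(n))
        # binomial: p=0.5, 3 sigma band
        assert abs(hits - n / 2) < 3 * math.sqrt(n * 0.25)

    def test_scores_weight_selection(self):
        rng = np.random.default_rng(6)
        c = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        n = 10_000
        hits = sum(select_direction(c, [3.0, 1.0], rng)[0] == 1.0
                   for _ in range(n))
        assert abs(hits - 0.75 * n) < 3 * math.sqrt(n * 0.75 * 0.25)

    def test_all_zero_scores_falls_back_to_uniform(self):
        rng = np.random.default_rng(7)
        c = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        hits = sum(select_direction(c, [0.0, 0.0], rng)[0] == 1.0
                   for _ in range(2000))
        assert 800 < hits < 1200


def _lone_tip_network(length=10.0, d_max=120.0):
    net = VascularNetwork(domain=(500.0,) * 3, d_max=d_max)
    cap = net.new_capillary(origin=np.array([250.0, 250.0, 250.0]))
    tip = net.new_agent(cap.id, None, [250.0, 250.0, 250.0],
                        [250.0 + length, 250.0, 250.0], TIP)
    cap.tip_id = tip.id
    return net, tip


class TestMigrateTip:
    def test_saturated_agent_does_not_move(self):
        net, tip = _lone_tip_network(length=40.0, d_max=40.0)
        p = MigrationParams(d_base=10.0, d_max=40.0)
        assert migrate_tip(tip, [1.0, 0, 0], p, dt=1.0, network=net) == 0.0

    def test_fifty_percent_extension_cap(self):
        net, tip = _lone_tip_network(length=10.0, d_max=40.0)
        p = MigrationParams(d_base=10.0, d_max=40.0)
        assert migrate_tip(tip, [1.0, 0, 0], p, dt=1.0, network=net) == \
            pytest.approx(5.0)

    def test_base_rate_binds_when_smallest(self):
        net, tip = _lone_tip_network(length=30.0, d_max=40.0)
        p = MigrationParams(d_base=2.0, d_max=40.0)
        assert migrate_tip(tip, [1.0, 0, 0], p, dt=1.0, network=net) == \
            pytest.approx(2.0)

    def test_node1_never_moves(self):
        net, tip = _lone_tip_network()
        n1 = tip.node1.copy()
        migrate_tip(tip, [0.0, 1.0, 0.0], MigrationParams(), dt=1.0, network=net)
        assert np.array_equal(tip.node1, n1)

    def test_boundary_truncation(self):
        net, tip = _lone_tip_network(length=20.0)
        tip.node2 = np.array([495.0, 250.0, 250.0])
        tip.node1 = np.array([475.0, 250.0, 250.0])
        net.index.update(tip.id, tip.node1, tip.node2)
        moved = migrate_tip(tip, [1.0, 0, 0], MigrationParams(d_base=10.0),
                            dt=1.0, network=net)
        assert moved == pytest.approx(5.0)
        assert tip.node2[0] == pytest.approx(500.0)

    def test_non_tip_rejected(self):
        net, tip = _lone_tip_network()
        tip.cell_type = STALK
        with pytest.raises(IllegalOperationError):
            migrate_tip(tip, [1.0, 0, 0], MigrationParams(), dt=1.0, network=net)

    def test_deactivated_tip_rejected(self):
        net, tip = _lone_tip_network()
        tip.active = False
        with pytest.raises(IllegalOperationError):
            migrate_tip(tip, [1.0, 0, 0], MigrationParams(), dt=1.0, network=net)


def _walk(gamma, sigma, steps, seed, n_candidates=20):
    """A lone tip walking with fixed step length; returns its path."""
    rng = np.random.default_rng(seed)
    params = MigrationParams(gamma=gamma, sigma=sigma,
                             n_candidates=n_candidates)
    u = np.array([1.0, 0.0, 0.0])
    pos = np.zeros(3)
    path = [pos.copy()]
    for _ in range(steps):
        cands = candidate_directions(params.n_candidates, rng)
        scores = direction_scores(cands, u, np.full(len(cands), 20.0), params)
        u = select_direction(cands, scores, rng)
        pos = pos + u  # unit steps; straightness is scale-free
        path.append(pos.copy())
    return np.asarray(path)


def _straightness(path):
    steps = np.diff(path, axis=0)
    return np.linalg.norm(path[-1] - path[0]) / np.linalg.norm(steps, axis=1).sum()


class TestWalkStatistics:
    def test_straightness_increases_with_gamma(self):
        means = []
        for gamma in (0.2, 0.6, 1.0):
            vals = [_straightness(_walk(gamma, math.pi / 6, 60, seed))
                    for seed in range(60)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_turning_angle_decreases_with_sigma(self):
        def mean_turn(sigma, seed):
            path = _walk(1.0, sigma, 200, seed)
            steps = np.diff(path, axis=0)
            cos = np.einsum("ij,ij->i", steps[:-1], steps[1:])
            return np.mean(np.arccos(np.clip(cos, -1, 1)))

        wide = np.mean([mean_turn(math.pi / 2, s) for s in range(10)])
        narrow = np.mean([mean_turn(math.pi / 12, s) for s in range(10)])
        assert narrow < wide

    def test_isotropy_under_constant_vegf(self):
        ends = np.array([_walk(1.0, math.pi / 6, 100, seed, n_candidates=4)[-1]
                         for seed in range(300)])
        mean_disp = ends.mean(axis=0)
        se = ends.std(axis=0, ddof=1) / math.sqrt(len(ends))
        # initial heading +x biases the early steps; drop that axis and
        # require the transverse components to vanish statistically
        assert abs(mean_disp[1]) < 3 * se[1] + 1e-9
        assert abs(mean_disp[2]) < 3 * se[2] + 1e-9

    def test_length_never_exceeds_d_max(self, rng):
        net, tip = _lone_tip_network(length=1.0, d_max=40.0)
        params = MigrationParams(d_base=15.0, d_max=40.0, n_candidates=4)
        field = VegfField()
        for _ in range(200):
            d = filopodia_search(tip, field, params, net.domain, rng)
            migrate_tip(tip, d, params, dt=1.0, network=net)
            assert tip.length <= params.d_max + 1e-9
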