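"""Tip-cell migration: biased persistent random walk with filopodia search.

Each step a tip samples ``n_candidates`` directions uniformly on the sphere
(the filopodia search), scores each by

    score = gamma * exp(-theta**2 / (2 sigma**2)) + (1 - gamma) * C / C_max

where theta is the angle to the tip's current direction, C is the VEGF
concentration probed ``probe_length`` um ahead along the candidate and
C_max the maximum probe over the candidate set, then moves its forward node
along a direction drawn with probability proportional to the scores.  The
displacement is the base rate times the time step, capped at 50% of the
tip's current length and at the maximum agent length ``d_max``.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from ._geometry import angle_between
from .config import MigrationParams
from .errors import IllegalOperationError
from .network import TIP, EndothelialAgent, VascularNetwork
from .vegf import VegfField, vegf_samples


def candidate_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` unit vectors sampled area-uniformly on the sphere, shape (n, 3)."""
    if n < 1:
        raise ValueError("need at least one candidate direction")
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    # resample the (measure-zero) degenerate draws
    while np.any(norms == 0.0):
        bad = norms == 0.0
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
    return v / norms[:, None]


def persistence_weight(theta: float, sigma: float) -> float:
    """Gaussian angular persistence kernel exp(-theta^2 / (2 sigma^2)).

    Angles are unsigned; ``theta`` is folded into [0, pi].
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    theta = abs(float(theta))
    if theta > math.pi:
        theta = theta % (2.0 * math.pi)
        if theta > math.pi:
            theta = 2.0 * math.pi - theta
    return math.exp(-(theta ** 2) / (2.0 * sigma ** 2))


def direction_score(direction, current_direction, vegf_sample: float,
                    params: MigrationParams,
                    vegf_reference: Optional[float] = None) -> float:
    """Score of one candidate direction.

    ``vegf_reference`` is the maximum probe concentration over the current
    candidate set; when all probes are zero the chemotactic term vanishes and
    the walk is pure persistence.
    """
    theta = angle_between(np.asarray(direction, float),
                          np.asarray(current_direction, float))
    w = persistence_weight(theta, params.sigma)
    ref = vegf_sample if vegf_reference is None else vegf_reference
    chem = (vegf_sample / ref) if ref > 0 else 0.0
    return params.gamma * w + (1.0 - params.gamma) * chem


def direction_scores(candidates: np.ndarray, current_direction: np.ndarray,
                     vegf_values: np.ndarray,
                     params: MigrationParams) -> np.ndarray:
    """Vectorized ``direction_score`` over a candidate set."""
    u = np.asarray(current_direction, float)
    u = u / np.linalg.norm(u)
    cos = np.clip(candidates @ u, -1.0, 1.0)
    theta = np.arccos(cos)
    w = np.exp(-(theta ** 2) / (2.0 * params.sigma ** 2))
    vmax = float(np.max(vegf_values)) if len(vegf_values) else 0.0
    chem = vegf_values / vmax if vmax > 0 else np.zeros_like(w)
    return params.gamma * w + (1.0 - params.gamma) * chem


def select_direction(candidates: np.ndarray, scores: Sequence[float],
                     rng: np.random.Generator) -> np.ndarray:
    """Draw a candidate with probability proportional to its score.

    Falls back to a uniform draw when every score is zero.
    """
    candidates = np.asarray(candidates, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(candidates) == 0:
        raise ValueError("no candidate directions")
    if len(scores) != len(candidates):
        raise ValueError("scores and candidates differ in length")
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative")
    total = float(scores.sum())
    if total <= 0.0:
        k = int(rng.integers(len(candidates)))
    else:
        k = int(rng.choice(len(candidates), p=scores / total))
    return candidates[k]


def migration_step_length(params: MigrationParams, current_length: float,
                          dt: float) -> float:
    """min(d_base*dt, 50% of current length, headroom to d_max)."""
    return max(0.0, min(params.d_base * dt,
                        params.extension_cap_fraction * current_length,
                        params.d_max - current_length))


def migrate_tip(agent: EndothelialAgent, chosen_direction, params: MigrationParams,
                dt: float, network: Optional[VascularNetwork] = None) -> float:
    """Advance a tip's forward node along ``chosen_direction``.

    The step is truncated at the domain boundary when a network is given;
    node 1 never moves.  Returns the displacement actually applied.
    Raises ``IllegalOperationError`` for non-tip or deactivated agents, or
    when the capillary is mature.
    """
    if agent.cell_type != TIP or not agent.active:
        raise IllegalOperationError(
            f"agent {agent.id} is not an active tip")
    if network is not None and network.capillaries[agent.capillary_id].mature:
        raise IllegalOperationError(
            f"capillary {agent.capillary_id} is mature")
    u = np.asarray(chosen_direction, dtype=float)
    u = u / np.linalg.norm(u)
    step = migration_step_length(params, agent.length, dt)
    if step <= 0.0:
        return 0.0
    if network is not None:
        # largest s <= step keeping node2 + s*u inside the closed domain
        p = agent.node2
        for k in range(3):
            if u[k] > 0:
                step = min(step, (network.domain[k] - p[k]) / u[k])
            elif u[k] < 0:
                step = min(step, (0.0 - p[k]) / u[k])
        step = max(0.0, step)
        if step <= 0.0:
            return 0.0
        network.move_node2(agent.id, p + step * u)
    else:
        agent.node2 = agent.node2 + step * u
    return float(step)


def filopodia_search(agent: EndothelialAgent, field: VegfField,
                     params: MigrationParams, domain,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample candidate directions, score them, and pick one.

    Filopodia probing beyond the tumor space sense nothing: candidates whose
    probe position leaves the domain are masked out (unless every candidate
    does), which keeps tips from pinning themselves against a domain face.
    """
    cands = candidate_directions(params.n_candidates, rng)
    probes = agent.node2[None, :] + params.probe_length * cands
    vals = vegf_samples(field, probes, domain)
    scores = direction_scores(cands, agent.direction, vals, params)
    domain = np.asarray(domain, dtype=float)
    inside = np.all(probes >= 0.0, axis=1) & np.all(probes <= domain, axis=1)
    if np.any(inside):
        scores = np.where(inside, scores, 0.0)
    return select_direction(cands, scores, rng)
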