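# Model and methods

`angiosprout` is a hybrid agent-based model of sprouting angiogenesis in a
tumor-tissue cube, together with the standard morphometrics used to
characterize microvascular networks. This note documents the model rules,
every tunable that matters, the numerical choices, and what the simulated
networks do and do not share with real vasculature.

## The model

**Domain and environment.** Vessels grow in a continuous
500 × 500 × 500 µm cube ("tumor space"). The environment carries a VEGF
concentration field, by default a spatially constant 20 ng/ml; linear and
radial gradient families and a user-supplied voxel grid (trilinear
interpolation) are available. Coordinates are continuous; a uniform-bin
spatial hash (10 µm bins) provides exact proximity queries for fusion and
regression tests, avoiding lattice artifacts in tortuosity.

**Agents, capillaries, units.** An endothelial agent is a straight vessel
element between a trailing node and a forward node; consecutive agents of a
capillary share nodes, so a capillary is a continuous polyline. Each agent
carries a cell type (tip / stalk / phalanx), an activation flag, a radius
(5 µm, stored only), and a cell-cycle clock. Consecutive agents group into
endothelial-cell *units* — the granularity of the once-per-cell sprouting
rule. The simulation starts from two mature ten-agent capillaries lying
along opposite edges of the cube (envelope 5 µm from the faces; placement is configurable). Real
mature microvessels are tortuous — the comparison imaging literature
reports segment tortuosity of 1.1 and up for every vessel — so the
scaffold capillaries follow gentle helices around their edge lines
(radius 25 µm, 1.5 turns; amplitude 0 recovers straight vessels). Their
cells are quiescent phalanx cells, but each may still sprout once; during
the first iteration one forced sprout forms on each, which is how
angiogenesis begins.

**Tip migration.** Each step an active tip samples `n_candidates`
directions uniformly on the sphere (the filopodia search) and scores each
candidate as

    score = γ · exp(−θ² / 2σ²) + (1 − γ) · C/C_max

where θ is the unsigned angle to the tip's current axis, σ = π/6, C is the
VEGF concentration probed 20 µm ahead along the candidate and C_max the
maximum probe over the candidate set (zero outside the domain, so tips are
not drawn across the boundary; with all probes equal the walk is pure
persistence). One candidate is drawn with probability proportional to its
score and the forward node advances by

    d_mig = min(MR · Δt, 0.5 · L, d_max − L)

— the base migration rate capped by the printed 50 %-of-current-length rule
and by the maximum agent length d_max — truncated at the domain boundary.
The trailing node never moves.

**Proliferation.** Cell-cycle lengths are drawn from
Normal(1/PR, 0.1/PR), floored at 1 h. Exactly one clock runs per growing
capillary. A newly sprouted tip divides once when its clock elapses: the
span it has migrated over is handed back as stalk material and a short
fresh tip (0.1 µm seed) is created ahead along its axis. Thereafter the
leading stalk divides on its own clock with the same geometry: the tip's
current span is "banked" as collinear stalk agents of at most
`stalk_agent_length` µm (cell-sized pieces), the dividing stalk
deactivates, and the tip is re-seeded ahead. Banked agents join the front
unit until its length exceeds `e_min`, then open a new (sprout-eligible)
unit. A division is skipped while the new tip position would leave the
domain.

Two consequences are worth stating explicitly, because they carry the main
results. First, front extension is proliferation-limited at ordinary
migration rates: a tip can migrate at most one banked span per cell cycle,
so the front advances at ≈ min(MR, d_max/P_s). Second, the 0.1 µm seed
makes the 50 %-per-step extension rule a *startup barrier*: a tip needs
≈ 13 h to regrow to full migration speed, so at a 12-h cycle (PR = 0.083)
the banked spans stay ~10 µm — short, kinked elements that crowd, fuse and
trigger regression, reproducing the stunted, tortuous high-proliferation
phenotype, while 40–68 h cycles reach d_max-sized spans.

**Sprouting.** Every eligible unit-leading agent draws against `p_sprout`
per hour. A sprout's trailing node is the agent's forward node; its tip
emerges in a uniform-random direction re-drawn until it is at least π/6
away from the local vessel axis (a sprout grows into free space, not along
its vessel). Sprouts proposed within one agent radius of a domain face are
rejected. The sprouting unit is spent (once per cell) and its two flanking
units are laterally inhibited (Delta-Notch), rule-based only — no
molecular species are modeled.

**Anastomosis.** After every tip advance, agents of other capillaries
within `fusion_radius` of the tip's forward node are collision candidates;
contacts within 15 µm of the sprout's own origin, or on the parent within
`origin_exclusion` (50 µm) of the origin, are ignored (the sprout base is
continuous tissue with its parent). A hit on another active tip joins the
two tips end-to-end; a hit on a stalk/phalanx segment fuses at the contact
point — the struck agent is split there so the junction is a true
degree-3 node, or, if the struck capillary is mature (its geometry is
frozen), the tip snaps to the nearest existing node. Both capillaries
mature: their agents quiesce to phalanx and never move or divide again.

**Sprout regression.** A newly formed sprout whose tip lies within the
regression distance `d_r` of a *functional* vessel — a mature capillary
other than its own parent — retracts: its agents are removed and the
parent unit's sprout eligibility is restored. The test runs at creation
and is re-applied for `regression_window` hours (12 h) while the sprout is
still a single agent; an established sprout (one that has divided or
branched) is no longer at hazard, matching the rule's scope of *newly
formed* sprouts and avoiding the removal of sprouts that already carry
children. This rule is the phenomenological stand-in for oxygen delivery
from perfused vessels suppressing local VEGF; no oxygen transport or flow
is computed.

**Event order per step (Δt = 1 h).** (1) every active tip: filopodia
search, migration, anastomosis check; (2) every growing capillary: clock
advance, division on expiry, anastomosis check after any advance;
(3) sprouting draws for all eligible units, an immediate regression test
on each new sprout, then the regression re-check on young sprouts.
Capillaries and agents are visited in id order, and randomness is split
into four independent generator streams (initialisation / migration /
proliferation / sprouting) spawned from the master seed, so (config, seed)
reproduces every output byte and perturbing one mechanism's parameters
does not shift another's draws.

## Morphometry

The agent network reduces to a junction–segment graph: coincident nodes
(within 1e-6 µm) merge, zero-length elements drop, and maximal chains of
degree-2 nodes become polyline edges. Vertices of degree ≥ 3 are
bifurcations; degree-1 vertices are termini.

* **VLD** (mm/mm³): total centerline length / domain volume.
* **BD** (1/mm³): bifurcation count / volume (a degree-4 crossing counts
  once).
* **VSL** (mm): per-segment polyline length. Because sparse early networks
  have few true bifurcations, the default convention admits segments
  bounded by a bifurcation *or* a terminus; `bifurcation_only` restricts
  to bifurcation-to-bifurcation segments. Both are available and the
  convention is recorded with the result.
* **VST** (mm/mm): per-segment path length / Euclidean end-to-end distance
  (the morphological definition). Closed loops are excluded (undefined
  denominator).
* **FD**: box-counting dimension — polylines are rasterized at 2 µm,
  occupied boxes counted at sizes {4, 8, 16, 32, 64, 128} µm by default,
  and FD is the negated log–log regression slope (with R² reported).
  FD is protocol-dependent; the box sizes are part of the result.

## Parameters

| parameter | default | units | meaning / provenance |
|---|---|---|---|
| domain | 500³ | µm | tumor-space cube |
| VEGF | constant 20 | ng/ml | default environment |
| MR (`d_base`) | 10 | µm/hr | tip migration rate (swept 0.24–40) |
| PR → `cycle_mean` | 0.025 → 40 | 1/hr → h | proliferation rate; cycle = 1/PR (swept 0.015–0.083) |
| `cycle_sd` | 0.1/PR | h | cell-cycle spread |
| σ (`sigma`) | π/6 | rad | persistence kernel width |
| γ (`gamma`) | 1.0 | — | persistence weight (calibrated, see below) |
| `n_candidates` | 4 | — | filopodia directions per step |
| `probe_length` | 20 | µm | filopodium sensing distance |
| `d_max` | 120 | µm | maximum agent length (tip span per cycle) |
| extension cap | 0.5 | — | per-step growth ≤ 50 % of current length |
| `new_tip_length` | 0.1 | µm | fresh-tip seed (sets the startup barrier) |
| `stalk_agent_length` | 55 | µm | cell-sized pieces a banked span is cut into |
| `initial_helix_amplitude` / `turns` | 25 / 1.5 | µm / — | tortuosity of the initial scaffold vessels |
| `e_min` | 20 | µm | unit length threshold |
| `p_sprout` | 0.005 | 1/hr | per-unit sprout probability (calibrated) |
| `fusion_radius` | 5 | µm | tip contact distance for anastomosis |
| `d_r` | 100 | µm | regression distance (studied at 50–200) |
| `regression_window` | 12 | h | re-check window for newborn sprouts |
| `min_sprout_angle` | π/6 | rad | minimum sprout emergence angle |
| `origin_exclusion` | 50 | µm | parent-contact exclusion near the sprout base |
| `dt` | 1 | h | time step |
| duration | 20 (50/200) | days | study horizons |

Several of these (γ, p_sprout, d_max, n_candidates, fusion radius, seed
length, stalk agent length, the regression window) are not fixed by the
published description of the model family this implements; they were fixed
*once* by calibrating the two designated free knobs (γ, p_sprout) together
with the unprinted structural scales against the day-20 baseline condition
(PR = 0.025 1/hr, MR = 10 µm/hr, d_r = 100 µm) and then frozen for every
experiment, including the parameter sweeps and the regression-distance
study.

## Numerical choices and edge cases

* New tips are seeded with 0.1 µm length rather than exactly zero because
  the 50 %-per-step rule cannot elongate a zero-length agent; zero-length
  agents are legal transiently and dropped by the metrics.
* Domain bounds are closed. Migration steps truncate at the boundary, and
  filopodia mask candidates probing outside; divisions and sprouts whose
  new node would leave the domain are skipped that step.
* If a fusion target would stretch the tip beyond `d_max`, a short
  connector agent is appended instead of moving the tip node, so the hard
  length bound survives anastomosis.
* Mature capillaries are frozen byte-for-byte (a geometry snapshot is kept
  and re-checked by `validate`), which is why fusions with mature vessels
  snap to existing nodes instead of splitting frozen agents.
* Sub-step event order ties break by agent/capillary id; `p_sprout` is a
  per-hour hazard applied as `p_sprout · dt` per step.
* `neighbors_within` gathers candidates from the spatial hash (or falls
  back to a full vectorized scan for large radii) and then applies the
  exact point-to-segment distance test, so results equal brute force.

## What the generator does and does not emulate

The simulated networks reproduce the morphometric regimes of interest —
density maximized at intermediate proliferation, stunted tortuous growth
at high proliferation, regression-distance-controlled spacing, and a
long-run bifurcation-density plateau with ongoing sprout formation and
retraction. They do not include extracellular-matrix mechanics or MMPs,
VEGF isoforms, secretion/diffusion/consumption dynamics, blood flow,
oxygen transport (only its phenomenological proxy d_r), pericytes, lumen
or radius dynamics. Passing tests therefore support the *relative* effects
of proliferation and migration rates on network architecture, not
absolute agreement with any particular tumor's vasculature.

## Known limitations

* The within-cycle migration path of a tip is stored as its straight
  chord, so tortuosity lives at the scale of banked agents and junctions,
  not below it.
* Mean segment lengths run some 15–25 % below the published values at
  matched conditions, and sweep-mean bifurcation density is
  correspondingly low at the largest regression distance (200 µm), where
  the birth-blocking effect of mature vessels is stronger in this
  implementation than in the published aggregate numbers.
* The optimum proliferation rate for density is a broad plateau around
  0.02–0.025 1/hr; at migration rates of a few µm/hr the two are
  statistically indistinguishable.
* Very low migration rates leave tips pinned near their parent vessels;
  those networks are dominated by the initial scaffold.

## Experiment sizes

The packaged experiments use scaled problem sizes chosen for routine runs:
day-20 exemplar conditions average 10 replicate seeds; the
regression-distance study uses a reduced factorial grid
(PR ∈ {0.02, 0.025, 0.05, 0.083} × MR ∈ {0.24, 10}, 5 replicates) crossed
with d_r ∈ {50, 100, 200} µm; steady-state checks run 120 simulated days
(the bifurcation-density plateau is reached by ~80 days), five seeds at
baseline. All sizes are arguments, not constants.
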