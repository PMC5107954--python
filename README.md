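# angiosprout

Hybrid agent-based simulation of sprouting angiogenesis with 3D vascular
morphometry.

Sprouting angiogenesis — the recruitment of new blood vessels by a growing
tumor or ischemic tissue — is driven by three endothelial phenotypes: *tip*
cells that migrate up VEGF cues, *stalk* cells that proliferate and extend
the sprout behind the tip, and quiescent *phalanx* cells in established
vessels. `angiosprout` models endothelial cells as two-node vessel-element
agents in a continuous 500 µm tissue cube. Tips perform a biased persistent
random walk: each step a tip samples candidate filopodia directions
uniformly on the sphere, scores them as

```
score(d) = γ · exp(−θ²/2σ²) + (1 − γ) · C(d)/C_max,      σ = π/6
```

(θ the angle to the tip's current axis, C the VEGF concentration probed
20 µm ahead), draws a direction with probability ∝ score, and advances by
`min(MR·Δt, 0.5·L, d_max − L)` — the migration rate MR capped at 50 % of
current length L and at the maximum agent length. Stalk divisions, drawn
from a Normal(1/PR, 0.1/PR) cell cycle, bank the tip's migrated span as
cell-sized stalk agents and re-seed the tip, so front extension is
proliferation-limited at ≈ min(MR, d_max·PR). Endothelial units sprout at
most once (with Delta-Notch lateral inhibition of their neighbours), tips
that touch a foreign vessel anastomose — maturing both capillaries — and a
newborn sprout within the regression distance `d_r` of a foreign mature
("functional") vessel retracts.

Networks are summarized by the standard morphometrics: vascular length
density (VLD, mm/mm³), bifurcation density (BD, 1/mm³), vascular segment
length (VSL, mm) and tortuosity (VST = path length / end-to-end distance),
and the box-counting fractal dimension (FD). The central prediction this
reproduces: vascular density is maximized at an intermediate proliferation
rate (PR ≈ 0.025 1/hr), while very high proliferation yields stunted,
highly tortuous networks — proliferation, more than migration, controls
vascular coverage.

The model and morphometry details, all parameters with defaults and units,
and known limitations are in [docs/methods.md](docs/methods.md).

## A worked example

```python
from angiosprout import baseline_config, run

cfg = baseline_config(pr=0.025, mr=10.0, d_r=100.0, seed=1,
                      duration_days=20.0)
res = run(cfg)
print(res.final_metrics.to_dict())
```

Running `python examples/run_simulation.py` (the same computation, with
labels) prints:

```
final network: 516 agents in 60 capillaries
VLD 166.9 mm/mm^3   # total vessel length per tissue volume
BD  544 /mm^3      # branch points per tissue volume
VSL 0.175 mm   # mean segment length between junctions
VST 1.42      # mean tortuosity (path / straight-line)
FD  1.32            # box-counting fractal dimension
```

Twenty simulated days of growth from two mature seed capillaries filled the
cube with ≈ 21 mm of vessel (this seed runs dense; the 10-seed average is
VLD ≈ 110), branching every ≈ 0.18 mm, with mildly tortuous segments —
the balanced-growth regime. At PR = 0.083 1/hr the same experiment returns
VLD ≈ 17 and VST ≈ 2.3: fast-dividing sprouts crowd, fuse and regress
before colonizing the tissue (`examples/proliferation_vs_migration.py`).

Other entry points:

* `examples/regression_distance.py` — vessel spacing set by `d_r`;
* `examples/vegf_gradient.py` — growth under a VEGF gradient;
* `examples/external_morphometry.py` — morphometry of external polyline
  networks (GraphML);
* the `angiosprout` CLI — `simulate`, `sweep`, `report`, `metrics` — for
  shell use; every command is a thin wrapper over the functions above.

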