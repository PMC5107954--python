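"""Run one 20-day baseline simulation and summarize the vasculature.

Baseline conditions: constant VEGF 20 ng/ml in a 500-um cube, migration
rate MR = 10 um/hr, proliferation rate PR = 0.025 1/hr (40-h cell cycle),
regression distance d_r = 100 um.
"""

from angiosprout import baseline_config, run

cfg = baseline_config(pr=0.025, mr=10.0, d_r=100.0, seed=1,
                      duration_days=20.0)
res = run(cfg)

m = res.final_metrics
print(f"final network: {len(res.network.agents)} agents in "
      f"{len(res.network.capillaries)} capillaries")
print(f"VLD {m.vld:.1f} mm/mm^3   # total vessel length per tissue volume")
print(f"BD  {m.bd:.0f} /mm^3      # branch points per tissue volume")
print(f"VSL {m.vsl_mean:.3f} mm   # mean segment length between junctions")
print(f"VST {m.vst_mean:.2f}      # mean tortuosity (path / straight-line)")
print(f"FD  {m.fd:.2f}            # box-counting fractal dimension")
print("\nevent counts:")
print(res.events["event"].value_counts().to_string())
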