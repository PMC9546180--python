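"""Generate a synthetic two-group prescribing panel with known ground truth.

The generator draws monthly prescription rates from a segmented linear model
(level, pre-advisory slope, advisory level drop, post-advisory slope change)
with seasonal structure and AR(1) noise, and records the analytic mean
percentage change its parameters imply.
"""

from pathlib import Path

from itsar import PanelSchema, SimulationConfig, read_panel, simulate_panel

schema = PanelSchema(group=("group",))
configs = [
    SimulationConfig(group_id={"group": "males"},
                     beta=(226.6, -0.14, -18.3, -3.4)),
    SimulationConfig(group_id={"group": "females"},
                     beta=(145.3, -0.13, -9.9, -2.1)),
]

out = Path("scratch_panel.csv")
path, truths = simulate_panel(configs, out, seed=20110701, schema=schema)

for t in truths:
    print(f"{t['group']}: true mean % change = {t['true_pct_change']:.2f}% "
          f"(advisory {t['advisory_month']})")

series = read_panel(path, schema=schema)
s = series[0]
print(f"\n{s.label}: {len(s)} months {s.months[0]}..{s.months[-1]}, "
      f"rates {s.rates.min():.0f}-{s.rates.max():.0f} per 100 000")
print("Each group spans 24 pre-advisory months, the July 2011 transition "
      "month and 11 post months; the true effect is what the estimator "
      "should recover.")
out.unlink()
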