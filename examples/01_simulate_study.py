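"""Generate a synthetic low-biomass study and look at its ground truth.

The generator emulates a paired meconium / amniotic-fluid design with
empty-instrument field controls: contaminant taxa share one expected load
across specimens and controls, signal taxa occur only in specimens.
"""

from collections import Counter

from lowbiom import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=42))

print("feature table:", study.table.shape[0], "features x",
      study.table.shape[1], "samples")
print("feature classes:", dict(Counter(study.ground_truth.values())))

by_group = Counter(
    (m.sample_type, m.sample_class.value) for m in study.metadata.values()
)
for (stype, klass), n in sorted(by_group.items()):
    print(f"  {stype:9s} {klass:14s} n={n}")

sid = next(s for s, m in study.metadata.items() if m.pair_id == "pair01")
print(f"example sample {sid}: depth={study.table.depth(sid):,} reads, "
      f"qPCR={study.qpcr_copies[sid]:,.0f} copies")
print("Depths are set by library preparation, so a control can have more "
      "reads than a specimen despite carrying far less DNA.")
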