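"""Absolute 16S quantification: standard curve, inversion, exact test.

Cq values are converted to gene copies through a per-run standard dilution
series; specimen and field-control copy numbers are compared with an exact
two-tailed Mann-Whitney U test (full enumeration for small groups).
"""

import numpy as np

from lowbiom import SimulationConfig, fit_standard_curve, mann_whitney_u, quantify, simulate_study
from lowbiom.io_formats import SampleClass
from lowbiom.simulate import qpcr_frame

study = simulate_study(SimulationConfig(seed=42))
sheet = qpcr_frame(study)

standards = sheet[sheet["role"] == "standard"]
curve = fit_standard_curve(standards["copies"], standards["cq"])
print(f"standard curve: slope={curve.slope:.4f}, "
      f"efficiency={curve.efficiency:.3f}, r^2={curve.r_squared:.4f}")

copies = quantify(sheet)
for stype in ("meconium", "amnion"):
    spec = [v for s, v in copies.items()
            if study.metadata[s].sample_type == stype
            and study.metadata[s].sample_class is SampleClass.SPECIMEN]
    ctrl = [v for s, v in copies.items()
            if study.metadata[s].sample_type == stype
            and study.metadata[s].sample_class is SampleClass.FIELD_CONTROL]
    res = mann_whitney_u(spec, ctrl)
    print(f"{stype}: specimens {np.mean(spec):,.0f} copies (n={len(spec)}) vs "
          f"controls {np.mean(ctrl):,.0f} (n={len(ctrl)}), "
          f"U={res.u_statistic:.0f}, p={res.p_two_tailed:.4g} [{res.method.value}]")

print("A small p means specimens carry measurably more bacterial DNA than "
      "the sampling/reagent background.")
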