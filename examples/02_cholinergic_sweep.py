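"""Sweep a cholinergic weight and locate the alpha->theta transition.

Acetylcholine deficiency is emulated by lowering the M2-receptor weight
PNN->IN (C_idi) from its healthy value 18 toward 1: disinhibited thalamic
interneurons suppress the relay nucleus and the rhythm slows.  For each
value one realization is simulated and the dominant frequency, band powers
and amplitude are tabulated; the critical value is the largest C_idi whose
dominant frequency has dropped below the 8 Hz alpha/theta boundary.  A
coarse grid keeps this example fast; the full experiment uses step 0.5.
"""

from btcmodel import SimulationConfig, SweepSpec, default_config, model_from_config
from btcmodel.experiments import detect_transition, run_sweep

cfg = default_config()
model = model_from_config(cfg)
sim = SimulationConfig.from_mapping(cfg["simulation"])

spec = SweepSpec(parameter="C_idi", values=tuple(float(v) for v in range(18, 0, -2)))
table = run_sweep(model, spec, sim)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

report = detect_transition(table)
print()
if report.critical_value is None:
    print("No alpha->theta transition inside this grid.")
else:
    print(f"alpha->theta critical value of C_idi: {report.critical_value:g}")
    print("Below this weight the rhythm has slowed out of the alpha band -")
    print("the model's analogue of EEG slowing under cholinergic deficiency.")
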