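"""Run all four cholinergic-deficiency experiments and print the comparison sheet.

Sweeps the four pathway weights (PNN->TRC, PNN->IN, PNN->TRN, PY->PNN) over
their full grids, detects each alpha->theta transition and estimates
amplitude distributions at the published exemplar weights, then prints the
model's dominant frequencies and fitted amplitude means next to the
published values.  Takes a few minutes; lower `n_realizations` for a
quicker look.
"""

from btcmodel import run_all_experiments
from btcmodel.experiments import REFERENCE_CRITICAL_VALUE

bundle = run_all_experiments(n_realizations=100)

print("alpha->theta critical values")
for name, report in bundle.transitions.items():
    crit = "none" if report.critical_value is None else f"{report.critical_value:g}"
    print(f"  {name}: {crit}  (published ~{REFERENCE_CRITICAL_VALUE[name]:g})")

print()
print("exemplar comparison (model vs published)")
cols = ["param", "value", "dominant_freq_hz", "reference_freq_hz",
        "amp_mean_mv", "reference_amp_mean_mv"]
print(bundle.comparison[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print("Each row is one exemplar weight: the dominant frequency of a single")
print("120 s run and the normal-fit mean amplitude over the realization batch.")
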