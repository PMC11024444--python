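"""Extract the 19-metric panel from a plasma-like thermogram.

Evaluates the quiescent (stable-state) template — dominant Peak 1 near
63 degC, smaller Peak 2 near 70 degC, Peak 3 shoulder near 77 degC — and
prints every metric with its units.
"""

from tlbkit import Thermogram, compute_panel, default_templates

tpl = default_templates()["cCAD"]
tg = Thermogram("quiescent", tpl.mean_curve("Tfu"))
panel = compute_panel(tg)

units = {"Peak1": "cal/(degC.g)", "Peak2": "cal/(degC.g)", "Peak3": "cal/(degC.g)",
         "TPeak1": "degC", "TPeak2": "degC", "TPeak3": "degC",
         "V12": "cal/(degC.g)", "TV12": "degC", "Max": "cal/(degC.g)",
         "TMax": "degC", "TFM": "degC", "Width": "degC", "Area": "cal/g"}
for name, value in panel.to_dict().items():
    print(f"{name:8s} {value:10.4f}  {units.get(name, '-')}")
# Peak amplitudes are the window maxima (60-66, 67-73, 73-81 degC); the
# ratios describe the profile's shape independent of concentration; T_FM is
# the amplitude-weighted mean temperature — the single most discriminative
# metric between injury phenotypes at presentation.
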