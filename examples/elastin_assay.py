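"""Calibrate an elastin assay plate and quantify normalized tissue ratios.

Generates a plate with a 0-50 ug standards ladder plus skin-control and
capsule samples, fits the calibration line, converts absorbances to
elastin-per-tissue-mass ratios, and runs the skin QC gate.
"""

import numpy as np

import capsulemech as cm

cfgs = cm.default_configs()
metas = ([cm.SampleMeta("skin", 0, r, seed=17) for r in range(3)]
         + [cm.SampleMeta("Fb-P", a, 0, seed=17) for a in range(5)])
plate = cm.gen_assay_plate(cfgs, metas)

cal = cm.fit_standards(plate.standards)
print(f"calibration: A513 = {cal.slope:.4f} * ug + {cal.intercept:.4f} "
      f"(r^2 = {cal.r2:.4f})")

ratios = {}
for s in plate.samples:
    gid = s["meta"].group_id
    ratios.setdefault(gid, []).append(cm.quantify(s, cal))

skin = float(np.mean(ratios["skin"]))
fbp = float(np.mean(ratios["Fb-P"]))
print(f"skin control : {skin:.2f} ug/mg  "
      f"-> QC {'PASS' if cm.qc_skin(skin) else 'FAIL'} (expected ~3.5)")
print(f"Fb-P capsule : {fbp:.2f} ug/mg  (group mean configured at 3.15)")
print("\nThe skin control validates the calibration; capsule ratios above "
      "~3 ug/mg indicate substantial elastic fiber deposition.")
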