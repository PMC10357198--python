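"""Fit the layered capsule model's axial fiber content by parametric sweep.

Simulates the bare-device capsule (6-fold axial fibers in the inner 44% of
the thickness) as the 'observed' curve, then sweeps axial_fold 0..8 and
scores each candidate by r^2.
"""

from dataclasses import replace

import capsulemech as cm

truth = cm.CapsuleModelParams(axial_fold=6.0)
observed = cm.simulate_compression(truth)
print(f"observed curve: sigma(40%) = {observed.sigma[-1]:.1f} kPa "
      f"(matrix E_m={truth.E_m:g} kPa, r_v_tan={truth.r_v_tan:.0%}, "
      f"fold={truth.axial_fold:g})")

fit = cm.fit_sweep(observed, {"axial_fold": [float(f) for f in range(9)]},
                   fixed=replace(truth, axial_fold=0.0))
print("\n fold    r^2")
for row in fit.sweep_table.itertuples():
    marker = "  <- best" if row.axial_fold == fit.best_params.axial_fold else ""
    print(f"  {row.axial_fold:3.0f}  {row.r2:8.5f}{marker}")

print(f"\nselected axial fold = {fit.best_params.axial_fold:g} "
      f"(r^2 = {fit.r2:.1%})")
print("Stress at 40% strain grows monotonically with axial fiber content, "
      "so the sweep pins the fold that reproduces the observed stiffening.")
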