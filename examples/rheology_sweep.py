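"""Demodulate an oscillatory shear sweep into G', G'', delta and |G*|.

Generates one synthetic ECM-enveloped capsule sample at 5% strain across the
1-40 rad/s ladder and recovers its moduli from the raw waveforms.
"""

import capsulemech as cm

cfgs = cm.default_configs()
meta = cm.SampleMeta(group_id="Fb-PECM", animal_id=0, tech_rep=0, seed=17)
sweep = cm.gen_oscillation_sweep(cfgs["Fb-PECM"], meta, strain_level="low")

spectrum = cm.analyze_sweep(sweep)
print(spectrum.table.round(2).to_string(index=False))

summary = cm.sweep_summary(spectrum)
print(f"\nsweep-averaged G'' = {summary['G_loss_mean']:.1f} Pa "
      f"(group mean configured at 390 Pa)")
print(f"delta at 1/10/40 rad/s: "
      + ", ".join(f"{w:g}: {d:.1f} deg" for w, d in summary["delta_at"].items()))
print("\ndelta < 45 deg at every frequency: the capsule is solid-like "
      "(G' > G'') under small-strain shear.")
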