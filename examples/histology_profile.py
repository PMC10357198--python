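"""Quantify elastin IHC masks across section types for one animal.

Generates cross / in / mid / out section masks for a bare-device capsule
animal plus a dermis control, corrects for the negative-control background,
and expresses each section relative to dermal elastin.
"""

import capsulemech as cm

cfgs = cm.default_configs()
meta = cm.SampleMeta(group_id="Fb-P", animal_id=0, tech_rep=0, seed=17)

sections = [cm.gen_section_mask(cfgs["Fb-P"], sec, meta)
            for sec in cm.SECTION_TYPES]
dermis_ref = cfgs["Fb-P"].histo.dermis_frac

profile = cm.section_profile(sections, dermis_reference=dermis_ref)
profile["corrected_pct"] = 100 * profile["corrected_fraction"]
print(profile[["section", "corrected_pct", "relative_to_dermis_pct"]]
      .round(1).to_string(index=False))

print("\nElastin concentrates toward the implant-facing (inner) sections of "
      "the bare-device capsule, exceeding dermal levels there — the spatial "
      "pattern the axial-fiber term of the compression model encodes.")
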