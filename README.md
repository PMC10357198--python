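# capsulemech

Quantitative analysis of the fibrous capsules that form around subcutaneous
implants (pacemakers and other cardiovascular implantable electronic
devices), together with a layered fiber-reinforced hyperelastic model that
links capsule stiffness to the amount and orientation of its elastic fibers.

The package is aimed at soft-tissue biomechanics groups comparing capsule
properties between implant treatments — here, bare devices versus devices
wrapped in a decellularized small-intestine-submucosa ECM envelope — using
four measurement modalities plus a constitutive model:

* **Oscillatory shear rheology.** From waveforms γ(t) = γ₀ sin(ωt) and
  τ(t), least-squares demodulation recovers the storage and loss moduli
  G′(ω), G″(ω), the phase shift δ = atan2(G″, G′) (0° pure solid → 90° pure
  liquid) and the dynamic modulus |G\*| = √(G′² + G″²) = G′/cos δ, over a
  1–40 rad/s sweep at 5% (low) and 40% (high) strain.
* **Uniaxial compression.** Displacement/force records become engineering
  strain ε = u/h₀ and true stress σ = F(1−ε)/A₀; the tangent modulus dσ/dε
  uses the 5-point centered stencil
  (−σᵢ₊₂ + 8σᵢ₊₁ − 8σᵢ₋₁ + σᵢ₋₂)/12(εᵢ−εᵢ₋₁), and elastic moduli E = Δσ/Δε
  are reported as least-squares slopes over the 0–10% and 30–40% windows.
* **Elastin assay.** Absorbance at 513 nm is calibrated against a standards
  ladder and normalized to tissue mass (μg elastin / mg tissue), gated by a
  pig-skin positive control expected near 3.5 μg/mg.
* **Histology.** Binarized IHC masks are quantified as positive-pixel area
  fractions inside a polygonal tissue ROI, background-corrected by the
  slide's negative control, and expressed relative to a dermis reference
  across cross / inner / middle / outer sections.
* **Capsule model.** A stack of through-thickness layers in series, each an
  incompressible neo-Hookean matrix (σ = μ(λ² − λ⁻¹), μ = E_m/2(1+ν)) plus
  two linear-elastic fiber families with single-branch generalized-Maxwell
  viscoelasticity (energy factor f_e, relaxation time t_r): a tangential
  family everywhere (volume fraction r_v) and an axial family confined to
  the inner 44% of the thickness at `axial_fold` × r_v. Fitting is a
  parametric sweep scored by r². Six-fold axial fibers reproduce the stiff
  bare-device capsule; removing them reproduces the ECM-enveloped one.

Replicate statistics follow the study's hierarchy — technical replicates are
averaged per animal, then group mean ± SD and tests (Student's t, 1/2-factor
ANOVA with Tukey–Kramer; \*\*\* p<0.001, \*\* p<0.01, \* p<0.05) run over
animal means only.

Because the underlying animal study published summary statistics rather than
raw records, the package includes a first-class synthetic-cohort generator
(`capsulemech.synthetic`) whose defaults reproduce the printed group values
(e.g. G″ 541 vs 390 Pa, E 2042 vs 1043 kPa, elastin 3.15 vs 1.92 μg/mg);
every analysis stage is validated by inversion against it.

## Worked example

`python examples/full_study.py` generates both implant cohorts plus controls
at the study sample sizes (n=5 vs n=2 animals, 3 technical replicates),
pushes them through all four analysis stages, and prints:

```
                                      measure               Fb-P       Fb-PECM        p stars
     G'' [Pa], at low-gamma shear oscillation           541 ± 61      372 ± 12 0.014665     *
             E [kPa], at high-eps compression 2.09e+03 ± 3.7e+02 614 ± 1.4e+02 0.003438    **
   Released alpha-elastin from tissue [ug/mg]        3.75 ± 0.83    1.74 ± 0.1 0.023261     *
         Elastin in tissue section [%]: cross        13.4 ± 0.96    9.27 ± 1.7 0.007487    **
Elastin in tissue section [%]: mid-tangential         11.7 ± 1.1     5.6 ± 1.9 0.002232    **

skin assay QC ratio           : 3.53 ug/mg
cross-section vs dermis (Fb-P): 1.49x
mid-tangential vs dermis      : Fb-P 140% / Fb-PECM 67%
```

Each row is a group mean ± SD over animal means with the two-sample t-test
p-value: at this seed all five headline measures are significantly lower for
the ECM-enveloped group, the skin control passes QC, and capsule elastin
exceeds dermal levels only for the bare-device group. Other examples cover
one capability each: `rheology_sweep.py`, `compression_moduli.py`,
`capsule_model_fit.py` (the fold-6 recovery sweep), `elastin_assay.py`,
`histology_profile.py`.

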