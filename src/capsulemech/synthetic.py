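"""Seeded synthetic cohorts emulating the minipig implant-capsule study.

Every generator reproduces the configured population statistics (group means
and between-animal SDs) so that the analysis stages can be validated by
inversion: pushing a synthetic cohort through the real pipeline must recover
the configured values.  Between-animal variation is moment-matched lognormal
(strictly positive quantities); technical/measurement noise is Gaussian.
All randomness derives from a single root seed (``meta.seed``) by stable
hashing of (group, animal, replicate, purpose), so identical (config, seed)
pairs regenerate bit-identical cohorts.

Generated artefacts per sample:

* oscillation sweeps — gamma(t) = gamma0 sin(wt), tau(t) = gamma0 [G' sin +
  G'' cos] + noise over a log-spaced 1-40 rad/s ladder, with
  G''(w) = B w**b (near-flat weak power law) and G' = G''/tan(delta);
* compression curves — tangent modulus ramping from E_low to E_high through
  a cubic smoothstep between 10% and 30% strain (phenomenological), or
  delegated to the layered capsule model (model_based);
* assay plates — linear absorbance ladder plus samples at known
  elastin-to-mass ratios;
* section masks — fiber-like strokes stamped until the in-ROI positive
  fraction hits the configured target within +/-0.2 percentage points.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ._rand import lognormal_with_moments, rng_for
from .assay import AssayPlate
from .compression import CompressionCurve
from .config import GroupConfig, NoiseConfig, SampleMeta, SECTION_TYPES
from .histo import HistoSection
from .model import CapsuleModelParams, simulate_compression
from .rheometry import OscillationSweep, OscRecord

__all__ = [
    "NO_NOISE",
    "omega_ladder",
    "draw_animal_params",
    "cohort_metas",
    "gen_oscillation_sweep",
    "gen_compression_curve",
    "gen_assay_plate",
    "gen_section_mask",
    "phenomenological_stress",
]

#: Convenience all-zero noise configuration for inversion tests.
NO_NOISE = NoiseConfig(waveform_rel_sd=0.0, stress_rel_sd=0.0,
                       absorbance_sd=0.0, mask_jitter=0.0)

STRAIN_LEVELS = {"low": 0.05, "high": 0.40}


def omega_ladder(n: int = 8, lo: float = 1.0, hi: float = 40.0) -> np.ndarray:
    """Log-spaced angular-frequency ladder over [lo, hi] rad/s."""
    return np.geomspace(lo, hi, n)


def cohort_metas(cfg: GroupConfig, seed: int) -> list[SampleMeta]:
    """All (animal, technical replicate) sample identities for one group."""
    return [
        SampleMeta(group_id=cfg.group_id, animal_id=a, tech_rep=r, seed=seed)
        for a in range(cfg.n_bio)
        for r in range(cfg.n_tech)
    ]


def draw_animal_params(cfg: GroupConfig, animal_id: int, root_seed: int) -> dict:
    """Per-animal biological draws, shared across technical replicates.

    Each quantity uses its own hashed stream, so adding quantities never
    perturbs the others.  Lognormal draws are moment-matched to the
    configured (mean, SD).
    """
    out: dict = {}
    if cfg.rheo is not None:
        r = rng_for(root_seed, cfg.group_id, animal_id, "rheo_gpp")
        out["Gpp_sweep_mean"] = lognormal_with_moments(
            r, cfg.rheo.Gpp_low_mean, cfg.rheo.Gpp_low_sd_bio)
        r = rng_for(root_seed, cfg.group_id, animal_id, "rheo_delta_high")
        lo, hi = cfg.rheo.delta_high_deg_range
        out["delta_high_deg"] = float(r.uniform(lo, hi))
    if cfg.comp is not None:
        r = rng_for(root_seed, cfg.group_id, animal_id, "comp_ehigh")
        out["E_high"] = lognormal_with_moments(
            r, cfg.comp.E_high_mean, cfg.comp.E_high_sd_bio)
        r = rng_for(root_seed, cfg.group_id, animal_id, "thickness")
        out["thickness"] = lognormal_with_moments(
            r, cfg.comp.thickness_mean, cfg.comp.thickness_sd)
    if cfg.assay is not None:
        r = rng_for(root_seed, cfg.group_id, animal_id, "assay_ratio")
        out["assay_ratio"] = lognormal_with_moments(
            r, cfg.assay.true_ratio_mean, cfg.assay.sd_bio)
    if cfg.histo is not None:
        fracs = {}
        for sec, mean in cfg.histo.area_frac.items():
            r = rng_for(root_seed, cfg.group_id, animal_id, "histo", sec)
            sd = cfg.histo.area_frac_sd_bio.get(sec, 0.0)
            fracs[sec] = lognormal_with_moments(r, mean, sd) if mean > 0 else 0.0
        out["histo_frac"] = fracs
    return out


# ---------------------------------------------------------------------------
# oscillation sweeps

def gen_oscillation_sweep(
    cfg: GroupConfig,
    meta: SampleMeta,
    strain_level: str = "low",
    n_omega: int = 8,
    n_cycles: int = 5,
    samples_per_cycle: int = 64,
    noise: NoiseConfig | None = None,
) -> OscillationSweep:
    """One sample's strain/stress waveforms across the frequency ladder.

    The per-animal power-law prefactor B is set so the sweep-averaged G''
    equals the animal's drawn loss modulus; the phase shift is the low-strain
    configured delta (< 45 deg, solid-like) or a per-animal draw from the
    high-strain band (49-67 deg, fluid-like).
    """
    if cfg.rheo is None:
        raise ValueError(f"group {cfg.group_id!r} has no rheology configuration")
    if strain_level not in STRAIN_LEVELS:
        raise ValueError(f"strain_level must be 'low' or 'high', got {strain_level!r}")
    noise = cfg.noise if noise is None else noise
    gamma0 = STRAIN_LEVELS[strain_level]
    animal = draw_animal_params(cfg, meta.animal_id, meta.seed)

    ladder = omega_ladder(n_omega)
    b = cfg.rheo.power_exponent
    # sweep-averaged G'' equals the animal's draw regardless of b
    B = animal["Gpp_sweep_mean"] / float(np.mean(ladder**b))
    if strain_level == "low":
        delta_deg = cfg.rheo.delta_low_deg
    else:
        delta_deg = animal["delta_high_deg"]
    delta = np.radians(delta_deg)

    rng = rng_for(meta.seed, meta.group_id, meta.animal_id, meta.tech_rep,
                  "osc", strain_level)
    records = []
    for omega in ladder:
        Gpp = B * omega**b
        Gp = Gpp / np.tan(delta)
        n = n_cycles * samples_per_cycle
        t = np.arange(n) * (2 * np.pi / (omega * samples_per_cycle))
        wt = omega * t
        gamma = gamma0 * np.sin(wt)
        tau = gamma0 * (Gp * np.sin(wt) + Gpp * np.cos(wt))
        if noise.waveform_rel_sd > 0:
            amp = gamma0 * np.hypot(Gp, Gpp)
            tau = tau + rng.normal(0.0, noise.waveform_rel_sd * amp, size=n)
        records.append(OscRecord(omega=float(omega), t=t, gamma=gamma, tau=tau))
    return OscillationSweep(meta=meta, gamma0=gamma0, records=records)


# ---------------------------------------------------------------------------
# compression curves

def phenomenological_stress(eps: np.ndarray, E_low: float, E_high: float,
                            eps1: float, eps2: float) -> np.ndarray:
    """Closed-form integral of the smoothstep tangent modulus, kPa.

    d(sigma)/d(eps) = E_low + (E_high - E_low) S(x) with S = 3x^2 - 2x^3 and
    x = (eps - eps1)/(eps2 - eps1) clipped to [0, 1]; below eps1 the slope is
    exactly E_low, above eps2 exactly E_high.
    """
    eps = np.asarray(eps, dtype=float)
    w = eps2 - eps1
    x = np.clip((eps - eps1) / w, 0.0, 1.0)
    integral = w * (x**3 - 0.5 * x**4) + np.maximum(eps - eps2, 0.0)
    return E_low * eps + (E_high - E_low) * integral


def gen_compression_curve(
    cfg: GroupConfig,
    meta: SampleMeta,
    mode: str = "phenomenological",
    model_params: CapsuleModelParams | None = None,
    deps: float = 0.005,
    eps_max: float = 0.40,
    noise: NoiseConfig | None = None,
) -> CompressionCurve:
    """One technical replicate's true stress/strain compression record."""
    if cfg.comp is None:
        raise ValueError(f"group {cfg.group_id!r} has no compression configuration")
    if mode not in ("phenomenological", "model_based"):
        raise ValueError(f"unknown mode {mode!r}")
    noise = cfg.noise if noise is None else noise
    animal = draw_animal_params(cfg, meta.animal_id, meta.seed)
    h0 = animal["thickness"]

    if mode == "model_based":
        if model_params is None:
            raise ValueError("model_based mode requires model_params")
        sim = simulate_compression(model_params)
        eps, sigma = sim.eps, sim.sigma.copy()
        h0, d0, rate = sim.h0, sim.d0, sim.rate
    else:
        n = int(round(eps_max / deps)) + 1
        eps = np.arange(n) * deps
        sigma = phenomenological_stress(
            eps, cfg.comp.E_low, animal["E_high"], cfg.comp.eps1, cfg.comp.eps2)
        d0, rate = 8.0, 0.1

    if noise.stress_rel_sd > 0:
        rng = rng_for(meta.seed, meta.group_id, meta.animal_id, meta.tech_rep,
                      "comp")
        sigma = sigma * (1.0 + rng.normal(0.0, noise.stress_rel_sd, size=len(sigma)))
        sigma[0] = 0.0
    return CompressionCurve(eps=eps, sigma=sigma, h0=h0, d0=d0, rate=rate,
                            meta=meta)


# ---------------------------------------------------------------------------
# assay plates

def gen_assay_plate(
    cfgs: dict[str, GroupConfig],
    metas: list[SampleMeta],
    standard_masses: np.ndarray | None = None,
    slope: float = 0.02,
    blank: float = 0.05,
    noise: NoiseConfig | None = None,
) -> AssayPlate:
    """One plate: standards ladder plus one well per sample meta.

    Sample absorbance = slope * (true_ratio * mass) + blank + N(0, sd); the
    per-animal true ratio is the lognormal biological draw, the tissue wet
    mass varies per technical replicate (8-12 mg).
    """
    if standard_masses is None:
        standard_masses = np.linspace(0.0, 50.0, 6)
    standards = []
    for m in standard_masses:
        cfg0 = cfgs[metas[0].group_id] if metas else next(iter(cfgs.values()))
        sd = (cfg0.noise if noise is None else noise).absorbance_sd
        rng = rng_for(metas[0].seed if metas else 0, "standards", round(float(m), 6))
        a = slope * m + blank + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        standards.append({"mass_ug": float(m), "A513": float(a)})

    samples = []
    for meta in metas:
        cfg = cfgs[meta.group_id]
        nz = cfg.noise if noise is None else noise
        if cfg.assay is None:
            raise ValueError(f"group {cfg.group_id!r} has no assay configuration")
        animal = draw_animal_params(cfg, meta.animal_id, meta.seed)
        rng = rng_for(meta.seed, meta.group_id, meta.animal_id, meta.tech_rep,
                      "assay")
        mass_mg = float(rng.uniform(8.0, 12.0))
        true_ug = animal["assay_ratio"] * mass_mg
        a = slope * true_ug + blank
        if nz.absorbance_sd > 0:
            a += rng.normal(0.0, nz.absorbance_sd)
        samples.append({"meta": meta, "A513": float(a),
                        "tissue_mass_mg": mass_mg})
    return AssayPlate(standards=standards, samples=samples)


# ---------------------------------------------------------------------------
# section masks

def _default_roi(shape: tuple[int, int]) -> np.ndarray:
    """Octagonal ROI covering ~94% of the frame."""
    h, w = shape
    i = 2.0
    c = 0.15 * min(w, h)
    x1, y1 = w - 1.0, h - 1.0
    return np.array([
        [i + c, i], [x1 - i - c, i], [x1 - i, i + c], [x1 - i, y1 - i - c],
        [x1 - i - c, y1 - i], [i + c, y1 - i], [i, y1 - i - c], [i, i + c],
    ])


def _stamp_stroke(shape, rng, length, width):
    """Pixel coordinates of one randomly placed, randomly oriented stroke."""
    h, w = shape
    cx, cy = rng.uniform(0, w), rng.uniform(0, h)
    theta = rng.uniform(0, np.pi)
    ux, uy = np.cos(theta), np.sin(theta)
    a, b = length / 2.0, max(width / 2.0, 0.5)
    # bounding box, then exact rotated-rectangle membership of pixel centers
    r = np.hypot(a, b)
    x0, x1 = int(max(0, np.floor(cx - r))), int(min(w - 1, np.ceil(cx + r)))
    y0, y1 = int(max(0, np.floor(cy - r))), int(min(h - 1, np.ceil(cy + r)))
    if x1 < x0 or y1 < y0:
        return None
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    dx, dy = xs - cx, ys - cy
    along = np.abs(dx * ux + dy * uy)
    across = np.abs(-dx * uy + dy * ux)
    hit = (along <= a) & (across <= b)
    return ys[hit], xs[hit]


def _fill_to_fraction(shape, roi, target, rng, max_iter=200_000):
    """Stamp strokes until the in-ROI positive fraction is within 0.15pp of
    target; strokes that would overshoot are shrunk before stamping."""
    from .histo import roi_mask  # local import to avoid cycles at module load

    mask = np.zeros(shape, dtype=bool)
    inside = roi_mask(roi, shape)
    n_inside = int(inside.sum())
    if target <= 0:
        return np.zeros(shape, dtype=np.uint8)
    count = 0
    band = 0.0015
    length = 40.0
    for _ in range(max_iter):
        frac = count / n_inside
        if frac >= target - band:
            break
        L = length
        while True:
            stroke = _stamp_stroke(shape, rng, L, max(1.0, L / 10.0))
            if stroke is None:
                break
            yy, xx = stroke
            new = ~mask[yy, xx] & inside[yy, xx]
            gained = int(new.sum())
            if (count + gained) / n_inside <= target + band:
                mask[yy, xx] = True
                count += gained
                break
            L = L / 2.0
            if L < 5.0:
                break  # resample a fresh (tiny) stroke next round
    else:
        raise RuntimeError("mask fill did not converge")
    return (mask.astype(np.uint8)) * 255


def gen_section_mask(
    cfg: GroupConfig,
    section: str,
    meta: SampleMeta,
    size: tuple[int, int] = (256, 256),
    noise: NoiseConfig | None = None,
) -> HistoSection:
    """One slide: positive mask + negative-control mask + ROI polygon.

    Randomly oriented elongated strokes (aspect ~10) are stamped until the
    in-ROI positive fraction matches the animal's drawn area fraction plus
    the slide background, within +/-0.2 percentage points; the negative
    control targets the background alone.  The analysis-side subtraction of
    the negative control therefore recovers the configured fraction.
    """
    if cfg.histo is None:
        raise ValueError(f"group {cfg.group_id!r} has no histology configuration")
    if section not in SECTION_TYPES:
        raise ValueError(f"section must be one of {SECTION_TYPES}")
    if size[0] < 256 or size[1] < 256:
        raise ValueError("mask size must be at least 256x256")
    noise = cfg.noise if noise is None else noise

    animal = draw_animal_params(cfg, meta.animal_id, meta.seed)
    frac = animal["histo_frac"].get(section, 0.0)
    rng = rng_for(meta.seed, meta.group_id, meta.animal_id, meta.tech_rep,
                  "mask", section)
    if noise.mask_jitter > 0 and cfg.histo.background_frac > 0:
        background = lognormal_with_moments(
            rng, cfg.histo.background_frac, noise.mask_jitter)
    else:
        background = cfg.histo.background_frac
    target = frac + background
    if target > 0.9:
        raise ValueError(f"target fraction {target:.3f} > 0.9 is unreachable")

    roi = _default_roi(size)
    mask = _fill_to_fraction(size, roi, target, rng)
    neg = _fill_to_fraction(size, roi, background, rng)
    return HistoSection(meta=meta, section=section, mask=mask, neg_mask=neg,
                        roi=roi)
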