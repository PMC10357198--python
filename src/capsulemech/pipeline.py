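"""End-to-end study orchestration on synthetic cohorts.

``run_study`` generates a cohort at the configured study conditions, pushes
it through the real analysis stages (waveform demodulation, windowed
compression moduli, assay calibration and quantification, mask
quantification) and assembles the headline summary table with
Fb-P vs Fb-PECM p-values, mirroring how the measured study data were
processed.
"""

from __future__ import annotations

import pandas as pd

from . import assay as assay_mod
from . import compression as comp_mod
from . import histo as histo_mod
from . import rheometry as rheo_mod
from . import synthetic as syn
from .config import GroupConfig, default_configs
from .stats import GroupSummary, aggregate, build_report, t_test

__all__ = [
    "rheology_stage",
    "compression_stage",
    "assay_stage",
    "histology_stage",
    "run_study",
]


def _measurements_frame(rows):
    return pd.DataFrame(rows, columns=["group_id", "animal_id", "tech_rep", "value"])


def rheology_stage(cfgs: dict[str, GroupConfig], seed: int,
                   groups=("Fb-P", "Fb-PECM"),
                   strain_level: str = "low") -> dict[str, GroupSummary]:
    """Sweep-averaged G'' per group, recovered by demodulating waveforms."""
    out = {}
    for gid in groups:
        cfg = cfgs[gid]
        rows = []
        for meta in syn.cohort_metas(cfg, seed):
            sweep = syn.gen_oscillation_sweep(cfg, meta, strain_level)
            spectrum = rheo_mod.analyze_sweep(sweep)
            summary = rheo_mod.sweep_summary(spectrum)
            rows.append((meta.group_id, meta.animal_id, meta.tech_rep,
                         summary["G_loss_mean"]))
        out[gid] = aggregate(_measurements_frame(rows), measure_id="g_loss_low")
    return out


def compression_stage(cfgs: dict[str, GroupConfig], seed: int,
                      groups=("Fb-P", "Fb-PECM"),
                      window=(0.30, 0.40)) -> dict[str, GroupSummary]:
    """Windowed elastic modulus (kPa) per group from compression records."""
    out = {}
    for gid in groups:
        cfg = cfgs[gid]
        rows = []
        for meta in syn.cohort_metas(cfg, seed):
            curve = syn.gen_compression_curve(cfg, meta)
            E = comp_mod.window_modulus(curve, *window)
            rows.append((meta.group_id, meta.animal_id, meta.tech_rep, E))
        out[gid] = aggregate(_measurements_frame(rows), measure_id="E_high")
    return out


def assay_stage(cfgs: dict[str, GroupConfig], seed: int,
                groups=("Fb-P", "Fb-PECM", "Ad", "skin")) -> dict[str, GroupSummary]:
    """Calibrated, normalized elastin ratios (ug/mg) per group."""
    metas = []
    for gid in groups:
        metas.extend(syn.cohort_metas(cfgs[gid], seed))
    plate = syn.gen_assay_plate(cfgs, metas)
    cal = assay_mod.fit_standards(plate.standards)
    rows = []
    for s in plate.samples:
        m = s["meta"]
        rows.append((m.group_id, m.animal_id, m.tech_rep,
                     assay_mod.quantify(s, cal)))
    df = _measurements_frame(rows)
    return {gid: aggregate(df, measure_id="elastin_ratio", group_id=gid)
            for gid in groups}


def histology_stage(cfgs: dict[str, GroupConfig], seed: int,
                    groups=("Fb-P", "Fb-PECM"),
                    sections=("cross", "mid"),
                    dermis_group: str = "dermis",
                    n_sections_per_animal: int = 1) -> dict:
    """Corrected elastin area fractions per section type and group, plus the
    dermis reference and dermis-relative values.

    Returns {"fractions": {section: {group: GroupSummary}},
             "dermis": {section: mean fraction},
             "relative": {section: {group: ratio-to-dermis}}}.
    """
    def group_fracs(gid, section):
        cfg = cfgs[gid]
        rows = []
        for animal in range(cfg.n_bio):
            for rep in range(n_sections_per_animal):
                meta = syn.SampleMeta(group_id=gid, animal_id=animal,
                                      tech_rep=rep, seed=seed)
                sec = syn.gen_section_mask(cfg, section, meta)
                rows.append((gid, animal, rep, histo_mod.corrected_ratio(sec)))
        return _measurements_frame(rows)

    fractions: dict = {}
    dermis: dict = {}
    relative: dict = {}
    for section in sections:
        fractions[section] = {
            gid: aggregate(group_fracs(gid, section),
                           measure_id=f"histo_{section}")
            for gid in groups
        }
        dermis_summary = aggregate(group_fracs(dermis_group, section),
                                   measure_id=f"histo_{section}")
        dermis[section] = dermis_summary.group_mean
        relative[section] = {
            gid: fractions[section][gid].group_mean / dermis[section]
            for gid in groups
        }
    return {"fractions": fractions, "dermis": dermis, "relative": relative}


def run_study(seed: int, cfgs: dict[str, GroupConfig] | None = None,
              fit_block: dict | None = None):
    """Full synthetic study: all stages plus the summary table.

    Returns a dict with per-stage outputs, the assembled summary table
    (mean +/- SD per group with p-values and stars) and a flat metrics dict.
    """
    cfgs = default_configs() if cfgs is None else cfgs
    rheo = rheology_stage(cfgs, seed)
    comp = compression_stage(cfgs, seed)
    elastin = assay_stage(cfgs, seed)
    hist = histology_stage(cfgs, seed)

    summaries = {
        "g_loss_low": rheo,
        "E_high": comp,
        "elastin_ratio": {g: elastin[g] for g in ("Fb-P", "Fb-PECM")},
        "histo_cross": {
            g: _percentify(hist["fractions"]["cross"][g])
            for g in ("Fb-P", "Fb-PECM")
        },
        "histo_mid": {
            g: _percentify(hist["fractions"]["mid"][g])
            for g in ("Fb-P", "Fb-PECM")
        },
    }
    table, metrics = build_report(summaries, fit_block=fit_block)
    metrics["skin_qc.ratio"] = elastin["skin"].group_mean
    for section in hist["relative"]:
        for gid, val in hist["relative"][section].items():
            metrics[f"histo_{section}_rel_dermis.{gid}"] = val
    return {
        "rheology": rheo,
        "compression": comp,
        "assay": elastin,
        "histology": hist,
        "table": table,
        "metrics": metrics,
    }


def _percentify(summary: GroupSummary) -> GroupSummary:
    """Rescale a fraction-valued summary to percent for reporting."""
    return GroupSummary(
        group_id=summary.group_id,
        measure_id=summary.measure_id,
        animal_means=summary.animal_means * 100.0,
        group_mean=summary.group_mean * 100.0,
        group_sd=summary.group_sd * 100.0,
        n_bio=summary.n_bio,
    )
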