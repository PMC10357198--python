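"""Plain-text/PNG serialization of cohorts and analysis outputs.

Schemas:

* waveforms CSV — columns omega_rad_s, t_s, gamma, tau_Pa (one file per
  sample and strain level);
* compression CSV — eps, sigma_kPa (processed) or u_mm, F_N (raw);
* assay plate CSV — kind (standard|sample), group_id, animal_id, tech_rep,
  mass_ug, A513, tissue_mass_mg;
* masks — 8-bit PNG (0 negative / 255 positive) plus an ROI CSV vertex list
  (x_px, y_px);
* cohort manifest — YAML listing the files written per sample.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .assay import AssayPlate
from .compression import CompressionCurve
from .config import SampleMeta
from .histo import HistoSection
from .rheometry import OscillationSweep, OscRecord

__all__ = [
    "write_waveforms_csv", "read_waveforms_csv",
    "write_compression_csv", "read_compression_csv",
    "write_plate_csv", "read_plate_csv",
    "write_section", "read_section",
    "write_manifest", "read_manifest",
]


def write_waveforms_csv(sweep: OscillationSweep, path: str | Path) -> None:
    frames = []
    for rec in sweep.records:
        frames.append(pd.DataFrame({
            "omega_rad_s": rec.omega, "t_s": rec.t,
            "gamma": rec.gamma, "tau_Pa": rec.tau,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_waveforms_csv(path: str | Path, gamma0: float,
                       meta: SampleMeta | None = None) -> OscillationSweep:
    df = pd.read_csv(path)
    records = []
    for omega, g in df.groupby("omega_rad_s", sort=True):
        records.append(OscRecord(
            omega=float(omega),
            t=g["t_s"].to_numpy(),
            gamma=g["gamma"].to_numpy(),
            tau=g["tau_Pa"].to_numpy(),
        ))
    meta = meta or SampleMeta(group_id="unknown", animal_id=0)
    return OscillationSweep(meta=meta, gamma0=gamma0, records=records)


def write_compression_csv(curve: CompressionCurve, path: str | Path) -> None:
    pd.DataFrame({"eps": curve.eps, "sigma_kPa": curve.sigma}).to_csv(
        path, index=False)


def read_compression_csv(path: str | Path, h0: float, d0: float = 8.0,
                         rate: float = 0.1,
                         meta: SampleMeta | None = None) -> CompressionCurve:
    """Read either processed (eps, sigma_kPa) or raw (u_mm, F_N) records."""
    df = pd.read_csv(path)
    if {"eps", "sigma_kPa"}.issubset(df.columns):
        return CompressionCurve(eps=df["eps"].to_numpy(),
                                sigma=df["sigma_kPa"].to_numpy(),
                                h0=h0, d0=d0, rate=rate, meta=meta)
    if {"u_mm", "F_N"}.issubset(df.columns):
        from .compression import to_true_curve
        return to_true_curve(df["u_mm"].to_numpy(), df["F_N"].to_numpy(),
                             h0=h0, d0=d0, rate=rate, meta=meta)
    raise ValueError("compression CSV needs (eps, sigma_kPa) or (u_mm, F_N)")


def write_plate_csv(plate: AssayPlate, path: str | Path) -> None:
    rows = []
    for s in plate.standards:
        rows.append({"kind": "standard", "group_id": "", "animal_id": -1,
                     "tech_rep": -1, "mass_ug": s["mass_ug"],
                     "A513": s["A513"], "tissue_mass_mg": np.nan})
    for s in plate.samples:
        m = s["meta"]
        rows.append({"kind": "sample", "group_id": m.group_id,
                     "animal_id": m.animal_id, "tech_rep": m.tech_rep,
                     "mass_ug": np.nan, "A513": s["A513"],
                     "tissue_mass_mg": s["tissue_mass_mg"]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> AssayPlate:
    df = pd.read_csv(path)
    standards = [{"mass_ug": float(r.mass_ug), "A513": float(r.A513)}
                 for r in df[df["kind"] == "standard"].itertuples()]
    samples = []
    for r in df[df["kind"] == "sample"].itertuples():
        samples.append({
            "meta": SampleMeta(group_id=str(r.group_id),
                               animal_id=int(r.animal_id),
                               tech_rep=int(r.tech_rep)),
            "A513": float(r.A513),
            "tissue_mass_mg": float(r.tissue_mass_mg),
        })
    return AssayPlate(standards=standards, samples=samples)


def write_section(section: HistoSection, stem: str | Path) -> dict:
    """Write mask/neg-mask PNGs and the ROI CSV; returns the file map."""
    stem = Path(stem)
    files = {
        "mask": stem.with_suffix(".mask.png"),
        "neg_mask": stem.with_suffix(".neg.png"),
        "roi": stem.with_suffix(".roi.csv"),
    }
    iio.imwrite(files["mask"], section.mask)
    iio.imwrite(files["neg_mask"], section.neg_mask)
    pd.DataFrame(section.roi, columns=["x_px", "y_px"]).to_csv(
        files["roi"], index=False)
    return {k: str(v) for k, v in files.items()}


def read_section(stem: str | Path, section: str,
                 meta: SampleMeta | None = None) -> HistoSection:
    stem = Path(stem)
    mask = np.asarray(iio.imread(stem.with_suffix(".mask.png")))
    neg = np.asarray(iio.imread(stem.with_suffix(".neg.png")))
    roi = pd.read_csv(stem.with_suffix(".roi.csv"))[["x_px", "y_px"]].to_numpy()
    meta = meta or SampleMeta(group_id="unknown", animal_id=0)
    return HistoSection(meta=meta, section=section, mask=mask, neg_mask=neg,
                        roi=roi)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
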