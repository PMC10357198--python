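"""Oscillatory shear rheology: storage/loss moduli, phase shift, |G*|.

A parallel-plate rheometer imposes gamma(t) = gamma0 sin(w t) and records the
shear stress tau(t).  For a linear viscoelastic material

    tau(t) = gamma0 [ G'(w) sin(w t) + G''(w) cos(w t) ],

so the storage modulus G' (in-phase, elastic) and loss modulus G''
(quadrature, viscous) follow from a linear least-squares demodulation of the
stress waveform.  The phase shift delta = atan2(G'', G') runs from 0 deg
(pure solid) to 90 deg (pure liquid), and the dynamic modulus is
|G*| = sqrt(G'^2 + G''^2) = G'/cos(delta).

Sweeps cover an angular-frequency ladder (1-40 rad/s here) at fixed maximum
strain; instrument geometry (8 mm biopsy, 12 mm plate, 2 mm gap) is carried
as metadata only — stress is taken as already reduced to Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SampleMeta

__all__ = [
    "OscRecord",
    "OscillationSweep",
    "RheologySpectrum",
    "demodulate",
    "phase_and_dynamic",
    "analyze_sweep",
    "sweep_summary",
]


@dataclass(frozen=True)
class OscRecord:
    """One oscillation record at a single angular frequency."""

    omega: float  # rad/s
    t: np.ndarray  # s
    gamma: np.ndarray  # unitless strain
    tau: np.ndarray  # Pa

    def __post_init__(self):
        if not (len(self.t) == len(self.gamma) == len(self.tau)):
            raise ValueError("t, gamma, tau must have equal length")
        if self.omega <= 0:
            raise ValueError("omega must be positive")


@dataclass(frozen=True)
class OscillationSweep:
    """One sample's strain/stress waveforms across a frequency ladder."""

    meta: SampleMeta
    gamma0: float
    records: list[OscRecord] = field(default_factory=list)
    geometry: dict = field(default_factory=lambda: {
        "sample_d_mm": 8.0, "plate_d_mm": 12.0, "gap_mm": 2.0,
    })

    def __post_init__(self):
        omegas = [r.omega for r in self.records]
        if any(b <= a for a, b in zip(omegas, omegas[1:])):
            raise ValueError("record omegas must be strictly increasing")


@dataclass(frozen=True)
class RheologySpectrum:
    """Per-frequency moduli table for one sample.

    Columns: omega (rad/s), G_storage (Pa), G_loss (Pa), delta (degrees),
    G_dynamic (Pa), with G_dynamic^2 = G_storage^2 + G_loss^2.
    """

    meta: SampleMeta
    table: pd.DataFrame


def demodulate(record: OscRecord, gamma0: float) -> tuple[float, float]:
    """Extract (G_storage, G_loss) in Pa from one oscillation record.

    Least-squares fit of tau(t) to a * sin(wt) + b * cos(wt) + c; the
    constant c absorbs transducer drift/offset.  Exact on noiseless
    single-tone input; under Gaussian noise the modulus error shrinks as
    1/sqrt(N samples).

    Warns if the strain waveform is inconsistent with gamma0 * sin(wt) at the
    stated omega (relative residual > 1%), which flags a frequency mismatch.
    """
    t, tau, gamma = record.t, record.tau, record.gamma
    if len(t) < 8:
        raise ValueError("record too short to demodulate")
    span = t[-1] - t[0]
    if span * record.omega < 3 * 2 * np.pi * 0.999:
        raise ValueError("record must span at least 3 full cycles")
    if np.ptp(tau) == 0:
        raise ValueError("constant stress waveform: demodulation is rank-deficient")

    wt = record.omega * t
    design = np.column_stack([np.sin(wt), np.cos(wt), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, tau, rcond=None)
    a, b, _ = coef

    # Frequency sanity check against the strain channel.
    gamma_fit = gamma0 * np.sin(wt)
    denom = gamma0 if gamma0 > 0 else 1.0
    resid = np.sqrt(np.mean((gamma - gamma_fit) ** 2)) / denom
    if resid > 0.01:
        warnings.warn(
            f"strain waveform deviates from gamma0*sin(wt) at omega="
            f"{record.omega:g} rad/s (rel. residual {resid:.3g}); "
            "possible frequency mismatch",
            stacklevel=2,
        )

    return float(a / gamma0), float(b / gamma0)


def phase_and_dynamic(G_storage: float, G_loss: float) -> tuple[float, float]:
    """Phase shift delta (degrees) and dynamic modulus |G*| (Pa)."""
    if G_storage == 0.0 and G_loss == 0.0:
        raise ValueError("G' and G'' both zero: phase undefined")
    delta = np.degrees(np.arctan2(G_loss, G_storage))
    G_dynamic = float(np.hypot(G_storage, G_loss))
    return float(delta), G_dynamic


def analyze_sweep(sweep: OscillationSweep) -> RheologySpectrum:
    """Demodulate every record of a sweep into a moduli spectrum."""
    rows = []
    for rec in sweep.records:
        try:
            Gp, Gpp = demodulate(rec, sweep.gamma0)
            delta, Gdyn = phase_and_dynamic(Gp, Gpp)
        except ValueError as exc:
            raise ValueError(f"record at omega={rec.omega:g} rad/s: {exc}") from exc
        rows.append({
            "omega": rec.omega,
            "G_storage": Gp,
            "G_loss": Gpp,
            "delta": delta,
            "G_dynamic": Gdyn,
        })
    return RheologySpectrum(meta=sweep.meta, table=pd.DataFrame(rows))


def sweep_summary(
    spectrum: RheologySpectrum,
    band: tuple[float, float] = (1.0, 40.0),
    delta_at: tuple[float, ...] = (1.0, 10.0, 40.0),
) -> dict:
    """Band-averaged moduli plus delta read at chosen ladder frequencies.

    Means are arithmetic over the rows with band[0] <= omega <= band[1];
    ``delta_at`` frequencies are snapped to the nearest ladder point.
    """
    tab = spectrum.table
    sel = tab[(tab["omega"] >= band[0]) & (tab["omega"] <= band[1])]
    if len(sel) == 0:
        raise ValueError(f"no spectrum rows inside band {band}")
    delta_map = {}
    for w in delta_at:
        i = int((tab["omega"] - w).abs().idxmin())
        delta_map[w] = float(tab.loc[i, "delta"])
    return {
        "G_loss_mean": float(sel["G_loss"].mean()),
        "G_storage_mean": float(sel["G_storage"].mean()),
        "G_dynamic_mean": float(sel["G_dynamic"].mean()),
        "delta_at": delta_map,
        "n_omega": int(len(sel)),
    }
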