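"""Unconfined uniaxial compression: true stress/strain and elastic moduli.

Raw indenter records (displacement u, force F) are converted to engineering
compressive strain eps = u/h0 and true compressive stress

    sigma = F (1 - eps) / A0,       A0 = pi d0^2 / 4,

i.e. force over the current cross-section of an incompressible cylinder that
spreads laterally as it is squashed.  Both sigma and eps are positive in
compression.  Two modulus readouts are provided:

* ``instantaneous_modulus`` — the pointwise derivative d(sigma)/d(eps) using a
  5-point centered stencil (exact through quartics) on a uniform strain grid,
  with 2nd-order one-sided stencils at the ends;
* ``window_modulus`` — the least-squares slope over a strain window, reported
  at 0-10% (low) and 30-40% (high) strain in the study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SampleMeta

__all__ = [
    "CompressionCurve",
    "to_true_curve",
    "resample_uniform",
    "instantaneous_modulus",
    "window_modulus",
]


@dataclass(frozen=True)
class CompressionCurve:
    """Paired true-stress/strain record with specimen geometry.

    eps: engineering compressive strain (positive, strictly increasing from 0)
    sigma: true compressive stress in kPa (positive in compression)
    h0: specimen height, mm; d0: diameter, mm; rate: loading rate, mm/s.
    """

    eps: np.ndarray
    sigma: np.ndarray
    h0: float
    d0: float = 8.0
    rate: float = 0.1
    meta: SampleMeta | None = None

    def __post_init__(self):
        eps = np.asarray(self.eps, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "sigma", sigma)
        if len(eps) != len(sigma):
            raise ValueError("eps and sigma must have equal length")
        if len(eps) and abs(eps[0]) > 1e-12:
            raise ValueError("eps must start at 0")
        if np.any(np.diff(eps) <= 0):
            raise ValueError("eps must be strictly increasing")
        if len(eps) and eps[-1] > 0.7 + 1e-12:
            raise ValueError("eps exceeds 0.7: outside the supported range")
        if self.h0 <= 0 or self.d0 <= 0:
            raise ValueError("h0 and d0 must be positive")


def to_true_curve(
    u: np.ndarray,
    F: np.ndarray,
    h0: float,
    d0: float = 8.0,
    rate: float = 0.1,
    meta: SampleMeta | None = None,
) -> CompressionCurve:
    """Convert displacement (mm) / force (N) to a true stress/strain curve.

    sigma [kPa] = F [N] * (1 - eps) / A0 [m^2] / 1000, with A0 from the
    undeformed sample diameter d0 [mm].
    """
    u = np.asarray(u, dtype=float)
    F = np.asarray(F, dtype=float)
    if h0 <= 0 or d0 <= 0:
        raise ValueError("h0 and d0 must be positive")
    if np.any(u < 0) or np.any(np.diff(u) <= 0):
        raise ValueError("u must be non-negative and strictly increasing")
    if np.any(u >= h0):
        raise ValueError("displacement reaches specimen height: u must stay < h0")
    eps = u / h0
    A0_m2 = np.pi * (d0 * 1e-3) ** 2 / 4.0
    sigma_kPa = F * (1.0 - eps) / A0_m2 / 1e3
    return CompressionCurve(eps=eps, sigma=sigma_kPa, h0=h0, d0=d0, rate=rate, meta=meta)


def resample_uniform(curve: CompressionCurve, deps: float = 0.005) -> CompressionCurve:
    """Linear-interpolate a curve onto a uniform strain grid of spacing deps."""
    n = int(np.floor(curve.eps[-1] / deps + 1e-9)) + 1
    grid = np.arange(n) * deps
    sig = np.interp(grid, curve.eps, curve.sigma)
    return CompressionCurve(eps=grid, sigma=sig, h0=curve.h0, d0=curve.d0,
                            rate=curve.rate, meta=curve.meta)


def instantaneous_modulus(curve: CompressionCurve) -> np.ndarray:
    """Pointwise tangent modulus d(sigma)/d(eps) in kPa.

    Interior points use the 5-point centered stencil

        (-s[i+2] + 8 s[i+1] - 8 s[i-1] + s[i-2]) / (12 h),

    exact for polynomials through degree 4; the two points at each end use
    2nd-order one-sided 3-point stencils.  Requires a uniform strain grid
    (relative spacing tolerance 1e-6); resample non-uniform recordings first
    (see :func:`resample_uniform`).
    """
    eps, sig = curve.eps, curve.sigma
    if len(eps) < 5:
        raise ValueError("need at least 5 points for the 5-point stencil")
    h = np.diff(eps)
    h0 = h.mean()
    if np.max(np.abs(h - h0)) > 1e-6 * max(abs(h0), 1e-30):
        raise ValueError(
            "non-uniform strain spacing: resample onto a uniform grid "
            "(capsulemech.compression.resample_uniform) before differencing"
        )
    d = np.empty_like(sig)
    d[2:-2] = (-sig[4:] + 8 * sig[3:-1] - 8 * sig[1:-3] + sig[:-4]) / (12 * h0)
    # 2nd-order one-sided stencils at the two points of each end
    d[0] = (-3 * sig[0] + 4 * sig[1] - sig[2]) / (2 * h0)
    d[1] = (-3 * sig[1] + 4 * sig[2] - sig[3]) / (2 * h0)
    d[-2] = (3 * sig[-2] - 4 * sig[-3] + sig[-4]) / (2 * h0)
    d[-1] = (3 * sig[-1] - 4 * sig[-2] + sig[-3]) / (2 * h0)
    return d


def window_modulus(curve: CompressionCurve, eps_lo: float, eps_hi: float) -> float:
    """Least-squares slope of sigma on eps over eps_lo <= eps <= eps_hi, kPa."""
    if not (0 <= eps_lo < eps_hi):
        raise ValueError("require 0 <= eps_lo < eps_hi")
    m = (curve.eps >= eps_lo - 1e-12) & (curve.eps <= eps_hi + 1e-12)
    if m.sum() < 3:
        raise ValueError(
            f"window [{eps_lo}, {eps_hi}] contains {int(m.sum())} points; need >= 3"
        )
    slope = np.polyfit(curve.eps[m], curve.sigma[m], 1)[0]
    return float(slope)
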