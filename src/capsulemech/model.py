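"""Zoned fiber-reinforced capsule compression model (series-layer solver).

The fibrous capsule is modelled as a stack of through-thickness layers in
series, each made of

* a nearly-incompressible neo-Hookean matrix — uniaxial Cauchy stress
  ``sigma_m = mu (lambda^2 - 1/lambda)`` with ``mu = E_m / (2 (1 + nu))``,
  the pressure eliminated by traction-free lateral faces;
* two linear-elastic fiber families with single-branch generalized-Maxwell
  viscoelasticity (equilibrium spring fraction ``1 - f_e``, Maxwell branch
  fraction ``f_e`` with relaxation time ``t_r``):
  an axial family loaded on the axial engineering strain ``lambda - 1`` and a
  tangential (force-orthogonal) family loaded on the lateral stretch of the
  incompressible kinematics, ``lambda_t = lambda**-0.5``.

Axial fibers occupy only the inner portion of the thickness (default the
inner zone plus the inner third of the mid zone, i.e. the inner 44%), at a
volume fraction ``axial_fold`` times the tangential fraction ``r_v_tan`` —
the configuration that discriminates the stiff capsule formed on a bare
device (6-fold axial fibers) from the ECM-enveloped one (no axial fibers).

A rigid platen moving at constant speed compresses the stack quasi-
statically: at each time step the layer stretches are solved by Newton
iteration so that all layers carry the same axial stress (series
equilibrium) while their compressions sum to the imposed displacement.
Fitting to an observed curve is a parametric sweep scored by r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .compression import CompressionCurve

__all__ = [
    "CapsuleModelParams",
    "LayerState",
    "FitResult",
    "layer_stack",
    "matrix_stress",
    "fiber_family_stress",
    "layer_stress",
    "simulate_compression",
    "r_squared",
    "fit_sweep",
]


@dataclass(frozen=True)
class CapsuleModelParams:
    """Constitutive and protocol constants of the capsule compression model.

    Defaults are the fitted fibrous-capsule values: matrix E_m = 295 kPa,
    nu = 0.4999, fiber E_f = 400 kPa, Maxwell energy factor f_e = 2%,
    relaxation time t_r = 50 s, tangential volume fraction r_v_tan = 12%,
    axial fibers at ``axial_fold`` times r_v_tan in the inner 44% of the
    thickness (axial_fold = 6 for the bare-device capsule, 0 for the
    ECM-enveloped one).  Densities are carried for fidelity but unused in the
    quasi-static solve.  Units: kPa, mm, s.
    """

    E_m: float = 295.0       # kPa, matrix modulus
    nu: float = 0.4999       # Poisson's ratio (near-incompressible)
    rho_m: float = 1.05      # g/mL, unused quasi-statically
    E_f: float = 400.0       # kPa, fiber modulus
    rho_f: float = 1.2       # g/mL, unused
    f_e: float = 0.02        # Maxwell-branch stiffness fraction
    t_r: float = 50.0        # s, relaxation time
    r_v_tan: float = 0.12    # tangential fiber volume fraction
    axial_fold: float = 0.0  # axial fraction = axial_fold * r_v_tan
    zone_fracs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # in/mid/out
    axial_zone: float = 4 / 9  # thickness fraction (from inner face) with axial fibers
    h0: float = 3.3          # mm, specimen height
    d0: float = 8.0          # mm, specimen diameter
    rate: float = 0.1        # mm/s, platen speed
    eps_max: float = 0.40
    dt: float | None = None  # s; default min(t_r/10, loading_time/200)

    def __post_init__(self):
        if abs(sum(self.zone_fracs) - 1.0) > 1e-9:
            raise ValueError("zone_fracs must sum to 1")
        if not (0.0 < self.nu < 0.5):
            raise ValueError("nu must be in (0, 0.5)")
        if not (0.0 <= self.f_e <= 1.0):
            raise ValueError("f_e must be in [0, 1]")
        if self.t_r <= 0:
            raise ValueError("t_r must be positive")
        if not (0.0 <= self.axial_zone <= 1.0):
            raise ValueError("axial_zone must be in [0, 1]")
        if self.axial_fold < 0:
            raise ValueError("axial_fold must be >= 0")
        if not (0.0 <= self.r_v_tan <= 1.0):
            raise ValueError("r_v_tan must be in [0, 1]")

    @property
    def mu(self) -> float:
        """Matrix shear modulus, kPa."""
        return self.E_m / (2.0 * (1.0 + self.nu))


@dataclass
class LayerState:
    """One series layer: geometry, fiber content and viscous internal state."""

    phi: float        # thickness fraction
    r_v_ax: float     # axial fiber volume fraction
    r_v_tan: float    # tangential fiber volume fraction
    lam: float = 1.0  # axial stretch (1 = undeformed, <1 in compression)
    e_v_ax: float = 0.0     # Maxwell internal strain, axial family
    e_v_tan: float = 0.0    # Maxwell internal strain, tangential family
    e_ax_prev: float = 0.0  # fiber strain at the last converged step
    e_tan_prev: float = 0.0


@dataclass(frozen=True)
class FitResult:
    """Outcome of a parametric sweep fit."""

    best_params: CapsuleModelParams
    r2: float
    sweep_table: pd.DataFrame


def layer_stack(params: CapsuleModelParams) -> list[LayerState]:
    """Build the series layers from the in/mid/out zones and the axial zone.

    Zone boundaries are augmented with the axial-zone boundary when it does
    not already coincide with one, so axial fibers always fill exactly the
    inner ``axial_zone`` fraction of the thickness.  With the defaults
    (thirds + axial_zone 4/9) this yields four layers of thickness fractions
    1/3, 1/9, 2/9, 1/3, the first two carrying axial fibers.
    """
    bounds = np.concatenate([[0.0], np.cumsum(params.zone_fracs)])
    bounds[-1] = 1.0
    if not np.any(np.abs(bounds - params.axial_zone) < 1e-12):
        bounds = np.sort(np.append(bounds, params.axial_zone))
    layers = []
    r_ax = params.axial_fold * params.r_v_tan
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < 1e-12:
            continue
        in_axial = hi <= params.axial_zone + 1e-12
        layers.append(LayerState(
            phi=float(hi - lo),
            r_v_ax=r_ax if in_axial else 0.0,
            r_v_tan=params.r_v_tan,
        ))
    return layers


def matrix_stress(lam, E_m: float, nu: float):
    """Incompressible neo-Hookean uniaxial Cauchy stress, kPa.

    sigma = mu (lambda^2 - 1/lambda), mu = E_m / (2 (1+nu)); negative in
    compression (lambda < 1).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    mu = E_m / (2.0 * (1.0 + nu))
    out = mu * (lam**2 - 1.0 / lam)
    return float(out) if out.ndim == 0 else out


def fiber_family_stress(
    e_f: float,
    e_v: float,
    E_f: float,
    f_e: float,
    t_r: float,
    dt: float,
    e_f_prev: float = 0.0,
) -> tuple[float, float]:
    """One implicit-Euler step of a single-branch generalized-Maxwell fiber.

    The Maxwell branch (stiffness fraction f_e) carries the internal strain
    e_v, updated implicitly as

        e_v_next = (e_v + (e_f - e_f_prev)) / (1 + dt / t_r)

    and the total fiber stress is the equilibrium spring plus the branch:

        s_f = E_f [ (1 - f_e) e_f + f_e e_v_next ].

    On a step-and-hold history this gives s_f(0+) = E_f e_f and
    s_f(inf) = E_f (1 - f_e) e_f: the fractional stress relaxation is f_e.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    e_v_next = (e_v + (e_f - e_f_prev)) / (1.0 + dt / t_r)
    s_f = E_f * ((1.0 - f_e) * e_f + f_e * e_v_next)
    return float(s_f), float(e_v_next)


def layer_stress(lam: float, state: LayerState, params: CapsuleModelParams,
                 dt: float) -> float:
    """Total axial Cauchy stress of one layer at stretch ``lam``, kPa.

    sigma = sigma_matrix
          + lam * r_v_ax * s_f_ax(e_ax = lam - 1)
          + lam * (dlam_t/dlam) * r_v_tan * s_f_tan(e_tan = lam^-1/2 - 1),

    with dlam_t/dlam = -1/2 lam^-3/2 from the incompressible lateral
    kinematics (the tangential family resists lateral spread, converting its
    tension into axial compressive stress).  Compression-negative internally.
    """
    sig, _, _ = _stack_stress(
        np.array([lam]),
        np.array([state.r_v_ax]), np.array([state.r_v_tan]),
        np.array([state.e_v_ax]), np.array([state.e_v_tan]),
        np.array([state.e_ax_prev]), np.array([state.e_tan_prev]),
        params, dt,
    )
    return float(sig[0])


def _stack_stress(lam, r_ax, r_tan, e_v_ax, e_v_tan, e_ax_prev, e_tan_prev,
                  params, dt):
    """Vectorized per-layer stress, its lambda-derivative, and viscous updates.

    Returns (sigma, dsigma_dlam, (e_v_ax_next, e_v_tan_next, e_ax, e_tan)).
    """
    mu = params.mu
    E_f, f_e, t_r = params.E_f, params.f_e, params.t_r
    relax = 1.0 / (1.0 + dt / t_r)
    # effective tangent stiffness of a fiber family within this step
    k = E_f * ((1.0 - f_e) + f_e * relax)

    sig_m = mu * (lam**2 - 1.0 / lam)
    dsig_m = mu * (2.0 * lam + lam**-2)

    e_ax = lam - 1.0
    e_v_ax_next = (e_v_ax + (e_ax - e_ax_prev)) * relax
    s_ax = E_f * ((1.0 - f_e) * e_ax + f_e * e_v_ax_next)
    sig_ax = r_ax * lam * s_ax
    dsig_ax = r_ax * (s_ax + lam * k)

    lam_t = lam**-0.5
    e_tan = lam_t - 1.0
    e_v_tan_next = (e_v_tan + (e_tan - e_tan_prev)) * relax
    s_tan = E_f * ((1.0 - f_e) * e_tan + f_e * e_v_tan_next)
    # lam * dlam_t/dlam = -1/2 lam^-1/2
    sig_tan = -0.5 * lam_t * r_tan * s_tan
    dsig_tan = 0.25 * r_tan * lam**-1.5 * (s_tan + lam_t * k)

    sigma = sig_m + sig_ax + sig_tan
    dsigma = dsig_m + dsig_ax + dsig_tan
    return sigma, dsigma, (e_v_ax_next, e_v_tan_next, e_ax, e_tan)


def _solve_step(lam, s_guess, eps_target, phi, r_ax, r_tan,
                e_v_ax, e_v_tan, e_ax_prev, e_tan_prev, params, dt,
                max_iter=50, tol_eps=1e-12):
    """Series-equilibrium solve for one time step.

    Unknowns: the common stress s and per-layer stretches lam_j with
    sigma_j(lam_j) = s and sum phi_j (1 - lam_j) = eps_target.  Outer Newton
    on s; inner Newton on each lam_j (sigma_j is strictly increasing in
    lam_j, so the inversion is well-posed).
    """
    s = s_guess
    lam = lam.copy()
    for _ in range(max_iter):
        # invert each layer's stress at the current s
        for _ in range(60):
            sig, dsig, _ = _stack_stress(lam, r_ax, r_tan, e_v_ax, e_v_tan,
                                         e_ax_prev, e_tan_prev, params, dt)
            step = (sig - s) / dsig
            lam_new = np.clip(lam - step, 0.05, 1.5)
            if np.max(np.abs(lam_new - lam)) < 1e-14:
                lam = lam_new
                break
            lam = lam_new
        else:
            return None
        resid = float(np.sum(phi * (1.0 - lam)) - eps_target)
        if abs(resid) < tol_eps:
            sig, dsig, upd = _stack_stress(lam, r_ax, r_tan, e_v_ax, e_v_tan,
                                           e_ax_prev, e_tan_prev, params, dt)
            return s, lam, upd
        _, dsig, _ = _stack_stress(lam, r_ax, r_tan, e_v_ax, e_v_tan,
                                   e_ax_prev, e_tan_prev, params, dt)
        dresid_ds = -float(np.sum(phi / dsig))
        s = s - resid / dresid_ds
    return None


def simulate_compression(params: CapsuleModelParams) -> CompressionCurve:
    """Quasi-static platen compression of the layered capsule stack.

    The platen displacement grows at ``params.rate`` until the total strain
    reaches ``params.eps_max``; at every time step the layer stretches are
    solved for series equilibrium (equal stress, displacements summing to the
    imposed one).  Returns a compression-positive stress/strain curve in kPa.
    On Newton non-convergence the time step is halved and the simulation
    restarted (at most 3 times).
    """
    t_total = params.eps_max * params.h0 / params.rate
    dt = params.dt if params.dt is not None else min(params.t_r / 10.0, t_total / 200.0)
    if dt > params.t_r / 10.0 + 1e-12:
        raise ValueError("dt must be <= t_r / 10 for a stable viscous update")

    for _attempt in range(4):
        result = _run_simulation(params, t_total, dt)
        if result is not None:
            eps, sigma = result
            return CompressionCurve(eps=eps, sigma=sigma, h0=params.h0,
                                    d0=params.d0, rate=params.rate)
        dt /= 2.0
    raise RuntimeError("Newton iteration failed to converge even after halving dt 3x")


def _run_simulation(params, t_total, dt):
    layers = layer_stack(params)
    phi = np.array([l.phi for l in layers])
    r_ax = np.array([l.r_v_ax for l in layers])
    r_tan = np.array([l.r_v_tan for l in layers])
    n_layers = len(layers)
    lam = np.ones(n_layers)
    e_v_ax = np.zeros(n_layers)
    e_v_tan = np.zeros(n_layers)
    e_ax_prev = np.zeros(n_layers)
    e_tan_prev = np.zeros(n_layers)

    n_steps = max(2, int(np.ceil(t_total / dt)))
    dt_eff = t_total / n_steps
    deps = params.eps_max / n_steps

    eps_out = np.empty(n_steps + 1)
    sig_out = np.empty(n_steps + 1)
    eps_out[0] = 0.0
    sig_out[0] = 0.0
    s = 0.0
    for k in range(1, n_steps + 1):
        eps_t = k * deps
        sol = _solve_step(lam, s, eps_t, phi, r_ax, r_tan,
                          e_v_ax, e_v_tan, e_ax_prev, e_tan_prev,
                          params, dt_eff)
        if sol is None:
            return None
        s, lam, (e_v_ax, e_v_tan, e_ax_prev, e_tan_prev) = sol
        eps_out[k] = eps_t
        sig_out[k] = -s  # compression-positive reporting
    return eps_out, sig_out


def r_squared(observed: CompressionCurve, simulated: CompressionCurve) -> float:
    """Coefficient of determination of a simulated curve against observation.

    The simulated stress is linearly resampled onto the observed strain grid;
    r^2 = 1 - SS_res / SS_tot.  The strain spans must overlap (observed
    strains beyond the simulated span are not extrapolated).
    """
    obs_e, obs_s = observed.eps, observed.sigma
    if obs_e[-1] > simulated.eps[-1] + 1e-9 or obs_e[0] < simulated.eps[0] - 1e-9:
        raise ValueError("observed strain span exceeds the simulated span")
    ss_tot = float(np.sum((obs_s - obs_s.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed curve is constant: r^2 undefined")
    sim_on_obs = np.interp(obs_e, simulated.eps, simulated.sigma)
    ss_res = float(np.sum((obs_s - sim_on_obs) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_sweep(
    observed: CompressionCurve,
    grid: dict,
    fixed: CapsuleModelParams | None = None,
) -> FitResult:
    """Parametric-sweep fit: simulate every grid point, score r^2, argmax.

    ``grid`` maps any of {"E_m", "r_v_tan", "axial_fold"} to a list of
    values; unlisted parameters stay at ``fixed``.  Ties are broken toward
    smaller axial_fold, then smaller r_v_tan (the sweep is enumerated in that
    order and only a strictly larger r^2 replaces the incumbent).
    """
    if fixed is None:
        fixed = CapsuleModelParams(h0=observed.h0, d0=observed.d0, rate=observed.rate)
    allowed = {"E_m", "r_v_tan", "axial_fold"}
    unknown = set(grid) - allowed
    if unknown:
        raise ValueError(f"unsupported grid parameters: {sorted(unknown)}")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")

    folds = sorted(grid.get("axial_fold", [fixed.axial_fold]))
    rvs = sorted(grid.get("r_v_tan", [fixed.r_v_tan]))
    ems = sorted(grid.get("E_m", [fixed.E_m]))

    rows = []
    best = None
    n_failed = 0
    for fold, rv, em in product(folds, rvs, ems):
        p = replace(fixed, axial_fold=fold, r_v_tan=rv, E_m=em)
        try:
            sim = simulate_compression(p)
            r2 = r_squared(observed, sim)
        except (RuntimeError, ValueError):
            n_failed += 1
            rows.append({"axial_fold": fold, "r_v_tan": rv, "E_m": em,
                         "r2": np.nan})
            continue
        rows.append({"axial_fold": fold, "r_v_tan": rv, "E_m": em, "r2": r2})
        if best is None or r2 > best[0]:
            best = (r2, p)
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(f"all {n_failed} sweep simulations failed")
    return FitResult(best_params=best[1], r2=best[0], sweep_table=table)
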