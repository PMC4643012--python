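"""Reduced three-variable Martiel-Goldbeter cAMP relay model on a lattice,
with a developmental path in adenylate-cyclase activity (sigma) and
extracellular phosphodiesterase activity (k_e).

State per lattice element (each element represents a small synchronized group
of cells): the total fraction of active cAMP receptor rho_T in [0, 1], the
normalized intracellular cAMP beta, and the normalized extracellular cAMP
gamma (the only diffusing species):

    d rho_T/dt = -f1(gamma) rho_T + f2(gamma) (1 - rho_T)
    d beta /dt = q sigma Phi(rho_T, gamma, alpha) - (k_i + k_t) beta
    d gamma/dt = (k_t beta / h) - k_e gamma + D_gamma lap5(gamma)

with receptor modification rates

    f1 = (k1 + k2 g)/(1 + g),    f2 = (k1 L1 + k2 L2 c g)/(1 + c g)

and the receptor-coupled synthesis function

    Phi = alpha (lambda theta + eps Y^2) / (1 + alpha theta + eps Y^2 (1 + alpha)),
    Y = rho_T gamma / (1 + gamma).

The developmental path varies sigma and k_e sigmoidally in global time t,
each cell shifted by its own exponential time offset dt_ij (mean Delta, the
desynchronization parameter):

    sigma(t) = sigma_av + sigma_amp tanh[(t - t_sigma + dt_ij)/T_sigma]
    k_e(t)   = k_av    + k_amp    tanh[(t - t_k     + dt_ij)/T_k]

Along this path a single element passes through (non-excitable) steady state
-> excitable -> oscillatory -> excitable.  Cells far ahead on the path (large
offsets) reach the oscillatory window while the majority is still excitable;
these "effective pacemakers" seed target waves whose collision lines (the
Voronoi diagram of the pacemakers) organize where spiral tips later appear.

Kinetic constants are the standard literature values for the reduced model;
the path shape constants ship as documented reconstructed defaults (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fhn import CellPropertyMap
from .numerics import BoundaryCondition, NumericalBlowupError, SpaceTimeCube, laplacian_5pt

__all__ = [
    "GoldbeterParams",
    "GBPathParams",
    "receptor_rates",
    "synthesis_phi",
    "goldbeter_rhs",
    "gb_path",
    "gb_classify_regime",
    "gb_regime_path_sequence",
    "effective_pacemakers",
    "sample_offsets",
    "goldbeter_simulate",
]


@dataclass
class GoldbeterParams:
    k1: float = 0.036      # receptor desensitization rate (1/min)
    k2: float = 0.666      # receptor resensitization rate (1/min)
    L1: float = 10.0
    L2: float = 0.005
    c_r: float = 10.0      # the "c" affinity ratio inside f2
    q: float = 4000.0
    sigma: float = 0.6     # adenylate cyclase activity (1/min); overridden by path
    lambda_g: float = 0.01
    theta: float = 0.01
    eps_g: float = 1.0
    alpha: float = 3.0     # normalized ATP
    k_i: float = 1.7       # intracellular cAMP hydrolysis (1/min)
    k_t: float = 0.9       # cAMP transport out of the cell (1/min)
    h: float = 5.0         # dilution factor
    k_e: float = 5.4       # extracellular hydrolysis (1/min); overridden by path
    D_gamma: float = 0.4   # extracellular cAMP diffusion (sites^2/min)
    dt: float = 0.01       # Euler step (min)

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be positive")
        for name in ("k1", "k2", "L1", "L2", "c_r", "q", "k_i", "k_t", "k_e", "D_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GBPathParams:
    """Developmental path 3: sigmoidal rises of sigma and (later) k_e.

    sigma rises before k_e, so a cell passes through a window of high
    synthesis / low degradation -- the oscillatory regime -- before settling
    into the final excitable state.
    """

    sigma_av: float = 0.375
    sigma_amp: float = 0.275
    t_sigma: float = 60.0
    T_sigma: float = 25.0
    k_av: float = 9.25
    k_amp: float = 2.75
    t_k: float = 110.0
    T_k: float = 10.0
    Delta: float = 25.0

    def __post_init__(self) -> None:
        if self.T_sigma <= 0 or self.T_k <= 0:
            raise ValueError("path widths must be positive")
        if self.Delta <= 0:
            raise ValueError("Delta must be positive")


def receptor_rates(gamma_e, p: GoldbeterParams):
    """Receptor modification rates f1 (desensitization) and f2 (resensitization)."""
    g = np.asarray(gamma_e, dtype=float)
    if np.any(g < 0):
        raise ValueError("gamma must be >= 0")
    f1 = (p.k1 + p.k2 * g) / (1.0 + g)
    f2 = (p.k1 * p.L1 + p.k2 * p.L2 * p.c_r * g) / (1.0 + p.c_r * g)
    if f1.ndim == 0:
        return float(f1), float(f2)
    return f1, f2


def synthesis_phi(rho_T, gamma_e, p: GoldbeterParams):
    """Receptor-coupled adenylate cyclase activation Phi(rho_T, gamma, alpha)."""
    rho = np.asarray(rho_T, dtype=float)
    g = np.asarray(gamma_e, dtype=float)
    Y = rho * g / (1.0 + g)
    Y2 = p.eps_g * Y * Y
    out = p.alpha * (p.lambda_g * p.theta + Y2) / (1.0 + p.alpha * p.theta + Y2 * (1.0 + p.alpha))
    if out.ndim == 0:
        return float(out)
    return out


def goldbeter_rhs(rho_T, beta_i, gamma_e, sigma_field, ke_field, p: GoldbeterParams,
                  bc: BoundaryCondition = BoundaryCondition.NO_FLUX,
                  diffusion: bool = True):
    """Time derivatives of (rho_T, beta, gamma) with per-site sigma and k_e."""
    f1, f2 = receptor_rates(gamma_e, p)
    drho = -f1 * rho_T + f2 * (1.0 - rho_T)
    dbeta = p.q * sigma_field * synthesis_phi(rho_T, gamma_e, p) - (p.k_i + p.k_t) * beta_i
    dgamma = (p.k_t / p.h) * beta_i - ke_field * gamma_e
    if diffusion and p.D_gamma > 0 and np.ndim(gamma_e) == 2:
        dgamma = dgamma + p.D_gamma * laplacian_5pt(gamma_e, bc)
    return drho, dbeta, dgamma


def gb_path(t, dt_offset, pp: GBPathParams):
    """Path values (sigma, k_e) at global time t for offset(s) dt_offset."""
    s = pp.sigma_av + pp.sigma_amp * np.tanh((t - pp.t_sigma + np.asarray(dt_offset)) / pp.T_sigma)
    k = pp.k_av + pp.k_amp * np.tanh((t - pp.t_k + np.asarray(dt_offset)) / pp.T_k)
    return s, k


def _integrate_elements(sigma, ke, p: GoldbeterParams, T: float, dt: float,
                        state=None, record_gamma: bool = False):
    """Euler-integrate uncoupled elements (vectorized over parameter arrays)."""
    sigma = np.asarray(sigma, dtype=float)
    ke = np.asarray(ke, dtype=float)
    if state is None:
        rho = np.full(sigma.shape, p.L1 / (1.0 + p.L1))
        beta = np.zeros(sigma.shape)
        gamma = np.zeros(sigma.shape)
    else:
        rho, beta, gamma = (np.array(s, dtype=float) for s in state)
    n = int(round(T / dt))
    trace = np.empty((n,) + gamma.shape) if record_gamma else None
    for i in range(n):
        dr, db, dg = goldbeter_rhs(rho, beta, gamma, sigma, ke, p, diffusion=False)
        rho = np.clip(rho + dt * dr, 0.0, 1.0)
        beta = np.maximum(beta + dt * db, 0.0)
        gamma = np.maximum(gamma + dt * dg, 0.0)
        if record_gamma:
            trace[i] = gamma
    return (rho, beta, gamma), trace


def gb_classify_regime(sigma, k_e, p: GoldbeterParams, T_settle: float = 150.0,
                       T_probe: float = 60.0, dt: float | None = None):
    """Classify uncoupled elements at fixed (sigma, k_e) as steady / excitable
    / oscillatory.  Accepts scalars or equal-shaped arrays (vectorized).

    Oscillatory: sustained gamma oscillation of amplitude > 1e-3 after the
    transient.  Excitable: stable rest, but an additive gamma pulse of twice
    the rest value (held 1 min) triggers a beta excursion exceeding five times
    the pulse size.  Otherwise steady.
    """
    dt = dt or p.dt
    sig = np.atleast_1d(np.asarray(sigma, dtype=float))
    ke = np.broadcast_to(np.asarray(k_e, dtype=float), sig.shape).copy()
    state, _ = _integrate_elements(sig, ke, p, T_settle, dt)
    # amplitude over an observation window at the end
    _, trace = _integrate_elements(sig, ke, p, T_probe, dt, state=state, record_gamma=True)
    amp = trace.max(axis=0) - trace.min(axis=0)
    oscillatory = amp > 1e-3

    rho_r, beta_r, gamma_r = (np.array(s) for s in state)
    pulse = 2.0 * gamma_r
    beta_max = _beta_excursion(sig, ke, p, (rho_r, beta_r, gamma_r + pulse), T_probe, dt)
    excitable = ~oscillatory & (pulse > 0) & ((beta_max - beta_r) > 5.0 * pulse)

    labels = np.where(oscillatory, "oscillatory", np.where(excitable, "excitable", "steady"))
    if np.ndim(sigma) == 0 and np.ndim(k_e) == 0:
        return str(labels[0])
    return labels.reshape(np.shape(sigma) or np.shape(k_e))


def _beta_excursion(sig, ke, p, state, T, dt):
    rho, beta, gamma = (np.array(s, dtype=float) for s in state)
    n = int(round(T / dt))
    bmax = beta.copy()
    for i in range(n):
        dr, db, dg = goldbeter_rhs(rho, beta, gamma, sig, ke, p, diffusion=False)
        rho = np.clip(rho + dt * dr, 0.0, 1.0)
        beta = np.maximum(beta + dt * db, 0.0)
        gamma = np.maximum(gamma + dt * dg, 0.0)
        np.maximum(bmax, beta, out=bmax)
    return bmax


def gb_regime_path_sequence(pp: GBPathParams, p: GoldbeterParams,
                            t_grid: np.ndarray | None = None,
                            dt_offset: float = 0.0) -> list[str]:
    """Regime labels sampled along the developmental path (repeats removed)."""
    if t_grid is None:
        t0 = min(pp.t_sigma - 4 * pp.T_sigma, pp.t_k - 4 * pp.T_k) - dt_offset
        t1 = max(pp.t_sigma + 4 * pp.T_sigma, pp.t_k + 4 * pp.T_k) - dt_offset + 20.0
        t_grid = np.linspace(min(t0, 0.0), t1, 40)
    sig, ke = gb_path(np.asarray(t_grid), dt_offset, pp)
    labels = gb_classify_regime(sig, ke, p)
    seq: list[str] = []
    for lab in np.atleast_1d(labels):
        if not seq or seq[-1] != lab:
            seq.append(str(lab))
    return seq


def sample_offsets(shape: tuple[int, int], Delta: float, rng: np.random.Generator,
                   fixed_sites: list[tuple[int, int]] | None = None,
                   advantage: float = 0.0) -> CellPropertyMap:
    """Exponential time offsets (mean Delta); optional hand-placed pacemaker
    sites receive a bonus offset (time advantage) on top of their draw."""
    if Delta <= 0:
        raise ValueError("Delta must be positive")
    vals = rng.exponential(Delta, size=shape)
    if fixed_sites:
        for r, c in fixed_sites:
            vals[r, c] += advantage
    return CellPropertyMap(vals, kind="time_offset")


def effective_pacemakers(offsets: CellPropertyMap, pp: GBPathParams,
                         p: GoldbeterParams, q_frac: float = 0.05,
                         t_grid: np.ndarray | None = None,
                         regime_fn=None) -> np.ndarray:
    """Mask of effective pacemaker sites.

    A site qualifies if its time offset lies in the top ``q_frac`` quantile
    *and* the site is in the oscillatory regime at the first global time at
    which the excitable regime holds the majority of cells.  Ties at the
    quantile boundary are broken by larger offset, then row-major order.
    """
    if not (0.0 < q_frac <= 1.0):
        raise ValueError("q_frac must be in (0, 1]")
    dtv = offsets.values
    n_sites = dtv.size
    if np.ptp(dtv) == 0:
        import warnings

        warnings.warn("all time offsets equal; mask determined purely by tie-break")
    # regime as a function of path position u = t + dt (all cells share the path)
    if t_grid is None:
        t_grid = np.linspace(0.0, max(pp.t_k + 4 * pp.T_k, pp.t_sigma + 4 * pp.T_sigma) + 10.0, 120)
    u_grid = np.linspace(t_grid[0], t_grid[-1] + dtv.max(), 200)
    sig_u, ke_u = gb_path(u_grid, 0.0, pp)
    classify = regime_fn or (lambda s, k: gb_classify_regime(s, k, p))
    labels_u = np.atleast_1d(classify(sig_u, ke_u))

    def site_labels(t: float) -> np.ndarray:
        u = t + dtv.ravel()
        idx = np.searchsorted(u_grid, u).clip(0, len(u_grid) - 1)
        return labels_u[idx]

    t_star = None
    for t in t_grid:
        lab = site_labels(float(t))
        if np.sum(lab == "excitable") > n_sites / 2:
            t_star = float(t)
            break
    if t_star is None:
        t_star = float(t_grid[-1])
    lab = site_labels(t_star).reshape(dtv.shape)

    k = max(1, int(round(q_frac * n_sites)))
    # top-k by offset with deterministic tie-break: larger offset first, then
    # row-major order
    order = np.lexsort((np.arange(n_sites), -dtv.ravel()))
    top = np.zeros(n_sites, dtype=bool)
    top[order[:k]] = True
    mask = top.reshape(dtv.shape) & (lab == "oscillatory")
    return mask


def goldbeter_simulate(
    offsets: CellPropertyMap,
    pp: GBPathParams,
    p: GoldbeterParams,
    T: float,
    seed: int = 0,
    record_every: int = 50,
    bc: BoundaryCondition = BoundaryCondition.NO_FLUX,
) -> SpaceTimeCube:
    """Full lattice run recording the extracellular cAMP field gamma.

    Every cell starts from the common path-start state (receptor equilibrium
    at gamma = 0); all spatial structure emerges from the offsets.
    """
    dtv = offsets.values
    shape = dtv.shape
    rho = np.full(shape, p.L1 / (1.0 + p.L1))
    beta = np.zeros(shape)
    gamma = np.zeros(shape)
    dt = p.dt
    n_steps = int(round(T / dt))
    frames = [gamma.copy()]
    for step in range(1, n_steps + 1):
        t = step * dt
        sig, ke = gb_path(t, dtv, pp)
        dr, db, dg = goldbeter_rhs(rho, beta, gamma, sig, ke, p, bc=bc)
        rho = np.clip(rho + dt * dr, 0.0, 1.0)
        beta = np.maximum(beta + dt * db, 0.0)
        gamma = np.maximum(gamma + dt * dg, 0.0)
        if not np.all(np.isfinite(gamma)):
            raise NumericalBlowupError(step)
        if step % record_every == 0:
            frames.append(gamma.copy())
    cube = SpaceTimeCube(np.stack(frames), dt_record=dt * record_every)
    cube.meta.update(model="goldbeter", T=T, seed=seed, Delta=pp.Delta)
    return cube
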