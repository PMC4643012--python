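"""Hybrid cellular-automaton/ODE model of *Dictyostelium* cAMP signaling
("Levine model").

Each lattice cell is a discrete-state unit (ready, firing, absolute
refractory, relative refractory) coupled to two continuous fields: the
extracellular cAMP concentration

    dc/dt = -Gamma c + r_F s + D lap8(c)          (s = 1 while firing)

and a per-cell excitability that grows monotonically with cAMP exposure,

    dE/dt = eta + beta c,   E <= e_max.

A cell in the ready or relative-refractory state fires when the local cAMP
exceeds a refractory-phase-dependent threshold

    t(tau) = [c_max - A tau/(tau + T_ARP)] (1 - E),
    A = (T_RRP + T_ARP)(c_max - c_min)/T_RRP,

with tau the time spent in the relative refractory phase (tau = T_RRP for the
ready state, so the ready threshold is c_min (1-E)).  Designated pacemaker
cells additionally fire spontaneously with probability p_F per unit time.
``beta`` is the feedback factor: random firing histories amplify excitability
heterogeneity, which breaks wavefronts and nucleates spirals.

The kinetic constants not fixed by the model's published headline parameters
(beta, p_F, pacemaker fraction) ship as documented, reconstructed defaults
chosen so the automaton relays waves and sustains spirals; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .numerics import BoundaryCondition, NumericalBlowupError, SpaceTimeCube, laplacian_8pt

__all__ = [
    "READY", "FIRING", "ARP", "RRP",
    "LevineParams",
    "LevineState",
    "levine_threshold",
    "camp_field_step",
    "excitability_step",
    "levine_cell_update",
    "levine_simulate",
    "scattered_pacemakers",
    "clustered_pacemakers",
    "cross_pacemakers",
]

READY, FIRING, ARP, RRP = 0, 1, 2, 3


@dataclass
class LevineParams:
    Gamma: float = 2.0          # extracellular cAMP degradation rate
    r_F: float = 30.0           # cAMP production rate while firing
    D: float = 0.5              # cAMP diffusion coefficient (8-point stencil)
    eta: float = 0.0            # intrinsic excitability increase
    beta: float = 0.20          # feedback factor
    e_max: float = 0.5          # excitability cap
    c_max: float = 5.0          # activation threshold at tau = 0
    c_min: float = 3.0          # activation threshold in the ready state (E=0)
    T_ARP: float = 2.0          # absolute refractory period
    T_RRP: float = 8.0          # relative refractory period
    firing_duration: float = 1.0
    pm_gain: float = 3.0        # cAMP production multiplier for spontaneous firing
    p_F: float = 0.002          # pacemaker firing probability per unit time
    pm_quiescence: float = 0.0  # pacemakers fire only after being ready this long
    eps_pm: float = 0.0         # fraction of randomly emerging extra pacemakers
    dt: float = 0.1
    E0: float = 0.0             # starting excitability

    def __post_init__(self) -> None:
        if not (self.c_max > self.c_min >= 0):
            raise ValueError("need c_max > c_min >= 0")
        if self.T_ARP <= 0 or self.T_RRP <= 0:
            raise ValueError("refractory periods must be positive")
        if not (0.0 <= self.p_F <= 1.0):
            raise ValueError("p_F must be a probability")


@dataclass
class LevineState:
    """Vectorized cell states: phase code, time-in-phase, excitability."""

    phase: np.ndarray        # int codes READY/FIRING/ARP/RRP
    tau: np.ndarray          # time in current phase
    E: np.ndarray            # excitability per cell
    is_pacemaker: np.ndarray
    emit_gain: np.ndarray | None = None  # production multiplier of current episode

    def __post_init__(self) -> None:
        if self.emit_gain is None:
            self.emit_gain = np.ones_like(self.E, dtype=float)

    @property
    def s(self) -> np.ndarray:
        """Firing indicator (1 while in the firing state)."""
        return (self.phase == FIRING).astype(float)

    @property
    def source(self) -> np.ndarray:
        """Production indicator including the pacemaker emission gain."""
        return self.s * self.emit_gain


def levine_threshold(tau, E, p: LevineParams):
    """Activation threshold t(tau, E); tau in [0, T_RRP], E in [0, e_max]."""
    tau = np.asarray(tau, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(tau < 0) or np.any(tau > p.T_RRP):
        raise ValueError("tau must lie in [0, T_RRP]")
    if np.any(E < 0) or np.any(E > max(p.e_max, 1.0)):
        raise ValueError("E out of range")
    A = (p.T_RRP + p.T_ARP) * (p.c_max - p.c_min) / p.T_RRP
    out = (p.c_max - A * tau / (tau + p.T_ARP)) * (1.0 - E)
    if out.ndim == 0:
        return float(out)
    return out


def camp_field_step(c: np.ndarray, s: np.ndarray, p: LevineParams,
                    bc: BoundaryCondition = BoundaryCondition.NO_FLUX) -> np.ndarray:
    """One explicit Euler step of the cAMP field equation."""
    out = c + p.dt * (-p.Gamma * c + p.r_F * s + p.D * laplacian_8pt(c, bc))
    if not np.all(np.isfinite(out)):
        raise NumericalBlowupError(-1)
    return out


def excitability_step(E: np.ndarray, c: np.ndarray, p: LevineParams) -> np.ndarray:
    """E += (eta + beta c) dt, clipped at e_max (monotone growth to the cap)."""
    return np.minimum(E + p.dt * (p.eta + p.beta * c), p.e_max)


def levine_cell_update(state: LevineState, c: np.ndarray, p: LevineParams,
                       rng: np.random.Generator,
                       pacemakers_active: bool = True) -> LevineState:
    """Advance every cell's phase machine by one dt.

    Ready and relative-refractory cells fire when local cAMP strictly exceeds
    the threshold; ready pacemakers additionally fire with probability
    p_F * dt.  Firing lasts ``firing_duration``, then absolute refractory
    (T_ARP), relative refractory (T_RRP), and back to ready.
    """
    phase, tau = state.phase, state.tau
    ready = phase == READY
    rrp = phase == RRP
    thr = np.full(c.shape, np.inf)
    if np.any(ready):
        # ready state uses tau = T_RRP, collapsing the threshold to c_min(1-E)
        thr[ready] = p.c_min * (1.0 - state.E[ready])
    if np.any(rrp):
        t_r = np.clip(tau[rrp], 0.0, p.T_RRP)
        A = (p.T_RRP + p.T_ARP) * (p.c_max - p.c_min) / p.T_RRP
        thr[rrp] = (p.c_max - A * t_r / (t_r + p.T_ARP)) * (1.0 - state.E[rrp])
    fire = (ready | rrp) & (c > thr)
    if pacemakers_active and p.p_F > 0:
        # spontaneous firing only from sufficiently long quiescence: a real
        # pacemaker cell fires on its intrinsic rhythm, i.e. out of a rested
        # state, not into the wake of a wave that just passed it
        rested = ready & (tau >= p.pm_quiescence)
        spont = rested & state.is_pacemaker & (rng.random(c.shape) < p.p_F * p.dt)
        fire |= spont
    else:
        spont = np.zeros_like(fire)

    new_phase = phase.copy()
    new_tau = tau + p.dt
    new_gain = state.emit_gain.copy()
    # phase transitions (evaluated on the pre-update phase)
    done_fire = (phase == FIRING) & (new_tau >= p.firing_duration)
    new_phase[done_fire] = ARP
    new_tau[done_fire] = 0.0
    done_arp = (phase == ARP) & (new_tau >= p.T_ARP)
    new_phase[done_arp] = RRP
    new_tau[done_arp] = 0.0
    done_rrp = (phase == RRP) & (new_tau >= p.T_RRP)
    new_phase[done_rrp] = READY
    new_tau[done_rrp] = 0.0
    # firing overrides; spontaneous pacemaker episodes emit more strongly than
    # relayed ones (pacemakers are autonomous full-pulse emitters)
    new_phase[fire] = FIRING
    new_tau[fire] = 0.0
    new_gain[fire] = 1.0
    new_gain[spont] = p.pm_gain
    return LevineState(new_phase, new_tau, state.E, state.is_pacemaker, new_gain)


def scattered_pacemakers(shape: tuple[int, int], fraction: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Fixed pacemaker layout: sites drawn uniformly at random."""
    n = int(round(fraction * shape[0] * shape[1]))
    mask = np.zeros(shape, dtype=bool)
    idx = rng.choice(shape[0] * shape[1], size=n, replace=False)
    mask.flat[idx] = True
    return mask


def clustered_pacemakers(shape: tuple[int, int], fraction: float,
                         rng: np.random.Generator, n_clusters: int = 4) -> np.ndarray:
    """Fixed pacemaker layout: the same total fraction packed into a few
    disk-shaped clusters, leaving pacemaker-free avenues between them."""
    ny, nx = shape
    n = int(round(fraction * ny * nx))
    area = n / n_clusters
    radius = max(2.0, np.sqrt(area / np.pi))
    mask = np.zeros(shape, dtype=bool)
    margin = int(np.ceil(radius)) + 1
    yy, xx = np.mgrid[0:ny, 0:nx]
    centers: list[tuple[int, int]] = []
    for _ in range(200):
        if len(centers) == n_clusters:
            break
        cy = int(rng.integers(margin, ny - margin))
        cx = int(rng.integers(margin, nx - margin))
        if all((cy - a) ** 2 + (cx - b) ** 2 > (2.5 * radius) ** 2 for a, b in centers):
            centers.append((cy, cx))
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    # grow/trim disks uniformly (never sprinkle: geometry must stay clustered)
    flat = int(mask.sum())
    r = radius
    while flat < n:
        r += 0.25
        for cy, cx in centers:
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        flat = int(mask.sum())
    if flat > n:
        dist = np.full(shape, np.inf)
        for cy, cx in centers:
            dist = np.minimum(dist, np.hypot(yy - cy, xx - cx))
        idx = np.flatnonzero(mask)
        order = idx[np.argsort(-dist.flat[idx], kind="stable")]
        mask.flat[order[: flat - n]] = False
    return mask


def cross_pacemakers(shape: tuple[int, int], points: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Small set of hand-placed pacemaker sites (default: five spread points)."""
    ny, nx = shape
    if points is None:
        points = [
            (ny // 5, nx // 5),
            (ny // 5, 4 * nx // 5),
            (ny // 2, nx // 2),
            (4 * ny // 5, nx // 5),
            (4 * ny // 5, 4 * nx // 5),
        ]
    mask = np.zeros(shape, dtype=bool)
    for r, c in points:
        mask[r, c] = True
    return mask


def levine_simulate(
    pm_mask: np.ndarray,
    p: LevineParams,
    T: float,
    seed: int = 0,
    record_every: int = 10,
    shape: tuple[int, int] | None = None,
    random_pm_delay: float = 0.0,
    return_state: bool = False,
    init_wavefront: bool = False,
    bc: BoundaryCondition = BoundaryCondition.NO_FLUX,
) -> SpaceTimeCube:
    """Full coupled run; records the cAMP field every ``record_every`` steps.

    ``pm_mask`` are the fixed pacemakers.  When ``p.eps_pm > 0`` an additional
    random fraction of cells becomes pacemakers (re-drawn per run/seed); these
    extra pacemakers stay silent for the first ``random_pm_delay`` time units,
    giving the fixed ones a time advantage.
    """
    rng = np.random.default_rng(seed)
    pm = np.asarray(pm_mask, dtype=bool)
    if shape is None:
        shape = pm.shape
    extra = np.zeros(shape, dtype=bool)
    if p.eps_pm > 0:
        extra = scattered_pacemakers(shape, p.eps_pm, rng) & ~pm
    state = LevineState(
        phase=np.full(shape, READY, dtype=np.int8),
        tau=np.zeros(shape),
        E=np.full(shape, float(p.E0)),
        is_pacemaker=pm | extra,
    )
    c = np.zeros(shape)
    if init_wavefront:
        # open wavefront: half-width firing strip with a refractory wake below
        row, half = shape[0] // 2, shape[1] // 2
        state.phase[row, :half] = FIRING
        state.phase[row + 1 : row + 3, :half] = ARP
        state.tau[row + 1 : row + 3, :half] = 0.0
    n_steps = int(round(T / p.dt))
    frames = [c.copy()]
    for step in range(1, n_steps + 1):
        t = step * p.dt
        if p.eps_pm > 0 and random_pm_delay > 0:
            state.is_pacemaker = pm | (extra & (t >= random_pm_delay))
        state = levine_cell_update(state, c, p, rng)
        c = camp_field_step(c, state.source, p, bc)
        state.E = excitability_step(state.E, c, p)
        if not np.all(np.isfinite(c)):
            raise NumericalBlowupError(step)
        if step % record_every == 0:
            frames.append(c.copy())
    cube = SpaceTimeCube(np.stack(frames), dt_record=p.dt * record_every)
    cube.meta.update(model="levine", T=T, seed=seed)
    if return_state:
        return cube, state
    return cube
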