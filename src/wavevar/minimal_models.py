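"""Minimal pattern-forming models: a three-state excitable cellular automaton
and the Schnakenberg Turing system.

The cellular automaton is the classic susceptible/excited/refractory (S/E/R)
medium on a square lattice with a von Neumann (four-element) neighborhood:
an S node becomes E when a direct neighbor is E, an E node always enters R,
and an R node regenerates to S after ``r`` steps.  A stochastic variant adds
spontaneous excitation at rate ``f`` per site and step and replaces the fixed
refractory period by a recovery probability ``p`` (the Drossel–Schwabl
forest-fire rules).  Despite its simplicity the automaton reproduces the core
excitable-media phenomenology, including the curling of an open wavefront end
into a self-sustained spiral.

The Schnakenberg system is a two-species reaction-diffusion model whose
diffusion-driven (Turing) instability produces stationary spots or stripes
depending on the feed parameter ``c2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

from .numerics import BoundaryCondition, laplacian_5pt

__all__ = [
    "S", "E", "R",
    "CAGrid",
    "CAStochasticParams",
    "SchnakenbergParams",
    "ca_step",
    "ca_step_stochastic",
    "ca_open_wavefront_init",
    "ca_run",
    "schnakenberg_rhs",
    "schnakenberg_steady_state",
    "turing_dispersion",
    "schnakenberg_simulate",
    "classify_turing_pattern",
]

# integer state codes (also the TIFF export encoding)
S, E, R = 0, 1, 2


@dataclass
class CAGrid:
    """Synchronous three-state excitable automaton grid.

    ``age`` counts completed refractory steps and is meaningful only at R
    sites (0 <= age < r).
    """

    states: np.ndarray
    r: int = 1
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.r < 1:
            raise ValueError("refractory duration r must be >= 1")
        if self.age is None:
            self.age = np.zeros_like(self.states, dtype=np.int32)
        else:
            self.age = np.asarray(self.age, dtype=np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape  # type: ignore[return-value]

    def counts(self) -> dict[int, int]:
        return {k: int(np.sum(self.states == k)) for k in (S, E, R)}


@dataclass
class CAStochasticParams:
    """Spontaneous excitation rate f and recovery probability p, per step."""

    f: float = 0.0
    p: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0 and 0.0 <= self.p <= 1.0):
            raise ValueError("f and p must be probabilities in [0, 1]")


def _excited_neighbor(states: np.ndarray) -> np.ndarray:
    """True where at least one von Neumann neighbor is excited (no wrap)."""
    e = states == E
    n = np.zeros_like(e)
    n[1:, :] |= e[:-1, :]
    n[:-1, :] |= e[1:, :]
    n[:, 1:] |= e[:, :-1]
    n[:, :-1] |= e[:, 1:]
    return n


def ca_step(g: CAGrid) -> CAGrid:
    """One deterministic synchronous update of the S/E/R rules."""
    st = g.states
    ignite = (st == S) & _excited_neighbor(st)
    new = np.full_like(st, S)
    new_age = np.zeros_like(g.age)
    new[ignite] = E
    new[st == E] = R
    # R sites have sat `age` steps already; they recover after r steps total
    still_ref = (st == R) & (g.age + 1 < g.r)
    new[still_ref] = R
    new_age[still_ref] = g.age[still_ref] + 1
    return CAGrid(new, r=g.r, age=new_age)


def ca_step_stochastic(g: CAGrid, sp: CAStochasticParams, rng: np.random.Generator) -> CAGrid:
    """Stochastic variant: S ignites spontaneously at rate f; R recovers with
    probability p per step instead of after a fixed period."""
    st = g.states
    ignite = (st == S) & _excited_neighbor(st)
    spont = (st == S) & ~ignite & (rng.random(st.shape) < sp.f)
    recover = (st == R) & (rng.random(st.shape) < sp.p)
    new = np.full_like(st, S)
    new[ignite | spont] = E
    new[st == E] = R
    new[(st == R) & ~recover] = R
    return CAGrid(new, r=g.r, age=np.zeros_like(g.age))


def ca_open_wavefront_init(nx: int, ny: int, length: int) -> CAGrid:
    """Open wavefront: a horizontal segment of excited sites with the adjacent
    row below refractory, everything else susceptible.

    The front propagates upward (toward row 0) and its open end curls into a
    spiral; a full-width front instead annihilates at the lattice edge.
    """
    if length <= 0:
        raise ValueError("wavefront length must be positive")
    if length > nx:
        raise ValueError("wavefront length must fit in the lattice")
    states = np.full((ny, nx), S, dtype=np.uint8)
    row = ny // 2
    x0 = (nx - length) // 2
    states[row, x0 : x0 + length] = E
    states[row + 1, x0 : x0 + length] = R
    return CAGrid(states, r=1)


def ca_run(
    g: CAGrid,
    n_steps: int,
    sp: CAStochasticParams | None = None,
    seed: int = 0,
    record_every: int = 1,
) -> list[CAGrid]:
    """Iterate the automaton, returning recorded grids (initial grid included)."""
    rng = np.random.default_rng(seed)
    out = [g]
    cur = g
    for step in range(1, n_steps + 1):
        cur = ca_step(cur) if sp is None else ca_step_stochastic(cur, sp, rng)
        if step % record_every == 0:
            out.append(cur)
    return out


# ---------------------------------------------------------------------------
# Schnakenberg Turing system


@dataclass
class SchnakenbergParams:
    """Kinetic constants of the Schnakenberg activator-substrate system.

    du/dt = gamma_s (c1 - c_m1 u + c3 u^2 v) + Du lap(u)
    dv/dt = gamma_s (c2 - c3 u^2 v) + Dv lap(v)
    """

    c1: float = 0.05
    c_m1: float = 1.0
    c2: float = 1.00
    c3: float = 1.0
    gamma_s: float = 2.0
    Du: float = 1.0
    Dv: float = 20.0

    def __post_init__(self) -> None:
        for name in ("c1", "c_m1", "c2", "c3", "gamma_s", "Du", "Dv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def schnakenberg_steady_state(p: SchnakenbergParams) -> tuple[float, float]:
    """Homogeneous steady state u* = (c1+c2)/c_m1, v* = c2/(c3 u*^2)."""
    u = (p.c1 + p.c2) / p.c_m1
    v = p.c2 / (p.c3 * u * u)
    return u, v


def schnakenberg_rhs(u: np.ndarray, v: np.ndarray, p: SchnakenbergParams) -> tuple[np.ndarray, np.ndarray]:
    """Reaction terms only (diffusion is added by the integrator)."""
    uv2 = p.c3 * u * u * v
    du = p.gamma_s * (p.c1 - p.c_m1 * u + uv2)
    dv = p.gamma_s * (p.c2 - uv2)
    return du, dv


def _schnakenberg_jacobian(p: SchnakenbergParams) -> np.ndarray:
    u, v = schnakenberg_steady_state(p)
    g = p.gamma_s
    return np.array(
        [
            [g * (-p.c_m1 + 2 * p.c3 * u * v), g * p.c3 * u * u],
            [g * (-2 * p.c3 * u * v), -g * p.c3 * u * u],
        ]
    )


def turing_dispersion(p: SchnakenbergParams, k: float) -> float:
    """Largest real part of the linearized growth rate at wavenumber k."""
    if k < 0:
        raise ValueError("wavenumber must be >= 0")
    J = _schnakenberg_jacobian(p) - np.diag([p.Du, p.Dv]) * k * k
    return float(np.max(np.linalg.eigvals(J).real))


def schnakenberg_simulate(
    p: SchnakenbergParams,
    shape: tuple[int, int] = (64, 64),
    T: float = 200.0,
    dt: float = 0.005,
    record_every: int | None = None,
    seed: int = 0,
    init_amplitude: float = 0.01,
    bc: BoundaryCondition = BoundaryCondition.NO_FLUX,
):
    """Integrate the Schnakenberg system from the randomly perturbed steady
    state (u, v varied uniformly within +/- init_amplitude).

    Returns the final (u, v) arrays; set ``record_every`` to also obtain a
    recorded cube of u via :func:`wavevar.numerics.integrate_explicit`.
    """
    from .numerics import integrate_explicit

    us, vs = schnakenberg_steady_state(p)
    rng = np.random.default_rng(seed)
    u0 = us + rng.uniform(-init_amplitude, init_amplitude, shape)
    v0 = vs + rng.uniform(-init_amplitude, init_amplitude, shape)
    n_steps = int(round(T / dt))

    def rhs(t, state, rng_):
        u, v = state
        du, dv = schnakenberg_rhs(u, v, p)
        du = du + p.Du * laplacian_5pt(u, bc)
        dv = dv + p.Dv * laplacian_5pt(v, bc)
        return du, dv

    rec = record_every if record_every is not None else n_steps
    cube = integrate_explicit([u0, v0], rhs, dt, n_steps, record_every=rec,
                              seed=seed, record_index=None)
    ucube, vcube = cube
    if record_every is None:
        return ucube.data[-1], vcube.data[-1]
    return ucube


def classify_turing_pattern(f: np.ndarray) -> str:
    """Classify a converged Turing snapshot as ``spots``, ``stripes`` or ``none``.

    The field is thresholded at its median; both phases are labeled with
    4-connectivity and the more fragmented phase is taken as the figure.
    Many compact, round components mean spots; elongated skeletonized
    components mean stripes.  Relative amplitude below 1e-3 means ``none``.
    """
    f = np.asarray(f, dtype=float)
    scale = np.abs(f).max()
    if scale == 0 or (f.max() - f.min()) / max(scale, 1e-300) < 1e-3:
        return "none"
    mask = f > np.median(f)

    best = None
    for phase in (mask, ~mask):
        lab = label(phase, connectivity=1)
        props = [pr for pr in regionprops(lab) if pr.area >= 4]
        if not props:
            continue
        if best is None or len(props) > len(best):
            best = props
    if best is None:
        return "none"

    ecc = float(np.median([pr.eccentricity for pr in best]))
    if len(best) >= 5 and ecc < 0.7:
        return "spots"

    # stripe test: skeleton length vs mean width per component
    ratios = []
    for pr in best:
        sk = skeletonize(pr.image)
        sk_len = int(sk.sum())
        if sk_len == 0:
            continue
        width = pr.area / sk_len
        ratios.append(sk_len / max(width, 1e-9))
    if ratios and float(np.median(ratios)) > 3.0:
        return "stripes"
    # fall back: elongated components but few of them still read as stripes,
    # compact-and-many as spots
    if len(best) >= 5 and ecc < 0.85:
        return "spots"
    return "stripes" if ecc >= 0.85 else "none"
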