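"""Kinematic ground-truth movies emulating rescaled dark-field recordings of
*Dictyostelium* colonies: rotating Archimedean spirals and expanding target
waves on a lattice, with additive Gaussian noise.

The intensity model is purely kinematic (a prescribed traveling phase, no
dynamics), so every movie comes with an exact ground-truth event plot: the
spiral tip sits at each spiral's center in every frame with the prescribed
chirality, and each target source contributes one origin event at its center
and onset frame.  This makes detector precision/recall measurable without
any simulator in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import SPIRAL_TIP, TARGET_ORIGIN, EventPlot, PatternEvent
from .numerics import SpaceTimeCube

__all__ = ["SyntheticSpec", "make_spiral_movie", "make_target_movie", "make_movie"]


@dataclass
class SyntheticSpec:
    """Specification of a kinematic wave movie.

    ``chiralities`` uses +1 for left-handed (counter-clockwise phase winding
    in array coordinates) and -1 for right-handed spirals.  ``t0`` (target
    movies) is the onset frame per source.
    """

    kind: str = "archimedean_spiral"  # "archimedean_spiral" | "target" | "mixed"
    centers: list[tuple[float, float]] = field(default_factory=lambda: [(50.0, 50.0)])
    periods: list[float] = field(default_factory=lambda: [20.0])
    wave_speeds: list[float] = field(default_factory=lambda: [1.0])
    chiralities: list[int] = field(default_factory=lambda: [1])
    t0: list[int] = field(default_factory=list)
    noise_sd: float = 0.0
    n_frames: int = 100
    shape: tuple[int, int] = (100, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.centers)
        for name in ("periods", "wave_speeds"):
            vals = getattr(self, name)
            if len(vals) == 1 and n > 1:
                setattr(self, name, vals * n)
        if len(self.chiralities) == 1 and n > 1:
            self.chiralities = self.chiralities * n
        if not self.t0:
            self.t0 = [0] * n
        if any(p <= 0 for p in self.periods) or any(v <= 0 for v in self.wave_speeds):
            raise ValueError("periods and wave speeds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for i in range(n):
            for j in range(i + 1, n):
                d = np.hypot(self.centers[i][0] - self.centers[j][0],
                             self.centers[i][1] - self.centers[j][1])
                if d < 5.0:
                    raise ValueError("source centers closer than 5 sites")


def _grids(spec: SyntheticSpec):
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    return yy, xx


def make_spiral_movie(spec: SyntheticSpec) -> tuple[SpaceTimeCube, EventPlot]:
    """Superposed Archimedean spirals; each source locally dominates through a
    smooth distance-based weight so its singularity stays at its center."""
    ny, nx = spec.shape
    yy, xx = _grids(spec)
    rng = np.random.default_rng(spec.seed)
    n_src = len(spec.centers)
    # blend scale: half the smallest inter-center distance (or the lattice)
    if n_src > 1:
        dmin = min(
            np.hypot(spec.centers[i][0] - spec.centers[j][0],
                     spec.centers[i][1] - spec.centers[j][1])
            for i in range(n_src) for j in range(i + 1, n_src)
        )
        blend = dmin / 2.0
    else:
        blend = float(max(ny, nx))

    rs, phases = [], []
    for (cx, cy), period, speed, chi in zip(spec.centers, spec.periods,
                                            spec.wave_speeds, spec.chiralities):
        omega = 2.0 * np.pi / period
        kr = omega / speed
        r = np.hypot(xx - cx, yy - cy)
        theta = np.arctan2(yy - cy, xx - cx)
        rs.append(r)
        phases.append((kr * r - chi * theta, omega))

    frames = np.empty((spec.n_frames, ny, nx), dtype=float)
    w = np.stack([np.exp(-(r / blend) ** 2) + 1e-12 for r in rs])
    wsum = w.sum(axis=0)
    for t in range(spec.n_frames):
        acc = np.zeros((ny, nx))
        for s, (ph, omega) in enumerate(phases):
            acc += w[s] * np.cos(ph - omega * t)
        frames[t] = acc / wsum
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, frames.shape)

    truth = [
        PatternEvent(SPIRAL_TIP, "left" if chi > 0 else "right",
                     x=float(cx), y=float(cy), t=t)
        for t in range(spec.n_frames)
        for (cx, cy), chi in zip(spec.centers, spec.chiralities)
    ]
    cube = SpaceTimeCube(frames, dt_record=1.0)
    cube.meta.update(model="synthetic_spiral", seed=spec.seed)
    return cube, EventPlot(truth, shape=spec.shape, n_frames=spec.n_frames)


def make_target_movie(spec: SyntheticSpec) -> tuple[SpaceTimeCube, EventPlot]:
    """Expanding concentric rings, gated to start at t0 per source.

    Quiet regions sit at intensity -1 (per source) and ramp into the
    oscillation (range [-1, 1]) as the front passes, so each source's first
    upstroke is an upward crossing of the global activation threshold.
    """
    ny, nx = spec.shape
    yy, xx = _grids(spec)
    rng = np.random.default_rng(spec.seed)
    frames = np.zeros((spec.n_frames, ny, nx), dtype=float)
    front_width = 2.0
    n_src = len(spec.centers)
    # colliding wavefronts annihilate: each site belongs to the source whose
    # front arrives first, with an amplitude taper toward the collision line
    rr = np.stack([np.hypot(xx - cx, yy - cy) for cx, cy in spec.centers])
    arrival = np.stack([
        t0 + r / v for r, t0, v in zip(rr, spec.t0, spec.wave_speeds)
    ])
    order = np.sort(arrival, axis=0)
    own_w = np.ones((n_src, ny, nx))
    if n_src > 1:
        taper = 3.0
        for s in range(n_src):
            others = np.min(np.where(np.arange(n_src)[:, None, None] == s,
                                     np.inf, arrival), axis=0)
            own_w[s] = np.clip((others - arrival[s]) / taper, 0.0, 1.0)
            own_w[s][arrival[s] > others] = 0.0
    for s, ((cx, cy), period, speed, t0) in enumerate(
            zip(spec.centers, spec.periods, spec.wave_speeds, spec.t0)):
        omega = 2.0 * np.pi / period
        kr = omega / speed
        r = rr[s]
        for t in range(spec.n_frames):
            reach = speed * (t - t0) if t >= t0 else 0.0
            amp = np.clip((reach - r) / front_width, 0.0, 1.0) * own_w[s]
            frames[t] += amp * np.cos(kr * r - omega * (t - t0)) + (amp - 1.0) / n_src
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, frames.shape)

    truth = [
        PatternEvent(TARGET_ORIGIN, "none", x=float(cx), y=float(cy), t=int(t0))
        for (cx, cy), t0 in zip(spec.centers, spec.t0)
    ]
    cube = SpaceTimeCube(frames, dt_record=1.0)
    cube.meta.update(model="synthetic_target", seed=spec.seed)
    return cube, EventPlot(truth, shape=spec.shape, n_frames=spec.n_frames)


def make_movie(spec: SyntheticSpec) -> tuple[SpaceTimeCube, EventPlot]:
    """Dispatch on ``spec.kind`` (``mixed`` sums a spiral and a target movie
    built from alternating sources)."""
    if spec.kind == "archimedean_spiral":
        return make_spiral_movie(spec)
    if spec.kind == "target":
        return make_target_movie(spec)
    if spec.kind == "mixed":
        half = max(1, len(spec.centers) // 2)
        sp = SyntheticSpec(
            kind="archimedean_spiral", centers=spec.centers[:half],
            periods=spec.periods[:half], wave_speeds=spec.wave_speeds[:half],
            chiralities=spec.chiralities[:half], noise_sd=0.0,
            n_frames=spec.n_frames, shape=spec.shape, seed=spec.seed,
        )
        tg = SyntheticSpec(
            kind="target", centers=spec.centers[half:],
            periods=spec.periods[half:], wave_speeds=spec.wave_speeds[half:],
            chiralities=spec.chiralities[half:] or [1],
            t0=spec.t0[half:], noise_sd=0.0,
            n_frames=spec.n_frames, shape=spec.shape, seed=spec.seed,
        )
        c1, e1 = make_spiral_movie(sp)
        c2, e2 = make_target_movie(tg)
        # composite by territory (nearest source wins, tapered seam): raw
        # superposition of incoherent waves would create interference
        # singularities that belong to neither source
        yy, xx = _grids(spec)
        d_sp = np.min(np.stack([np.hypot(xx - cx, yy - cy) for cx, cy in sp.centers]), axis=0)
        d_tg = np.min(np.stack([np.hypot(xx - cx, yy - cy) for cx, cy in tg.centers]), axis=0)
        taper = 3.0
        w_sp = np.clip((d_tg - d_sp) / taper * 0.5 + 0.5, 0.0, 1.0)
        # kill the seam itself: waves annihilate where territories meet
        att = np.clip(np.abs(d_tg - d_sp) / taper, 0.0, 1.0)
        rng = np.random.default_rng(spec.seed)
        data = att * (w_sp * c1.data + (1.0 - w_sp) * c2.data)
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, data.shape)
        cube = SpaceTimeCube(data, dt_record=1.0)
        cube.meta.update(model="synthetic_mixed", seed=spec.seed)
        return cube, EventPlot(e1.events + e2.events, shape=spec.shape,
                               n_frames=spec.n_frames)
    raise ValueError(f"unknown synthetic movie kind {spec.kind!r}")
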