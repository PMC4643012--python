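"""Pattern-event extraction: turn a spatiotemporal movie into a "pattern
event plot" of target-wave origins and chirality-resolved spiral tips.

Spiral tips are phase singularities.  Each site's scalar signal is normalized
(zero mean, unit variance, so detection is invariant to affine intensity
rescaling) and embedded into a phase angle by delay coordinates,

    phi(t) = atan2(z(t - delay), z(t)),

with the delay defaulting to a quarter of the dominant oscillation period
estimated from the autocorrelation of the movie.  The topological charge of
every 2x2 plaquette is the sum of wrapped phase differences around its loop;
a winding of +/- 2 pi marks a tip, and the sign of the winding fixes the
rotation sense.  Positive winding (counter-clockwise in array coordinates
with y increasing downward) is labeled "left".

Target-wave origins are first activations: a site crossing the activation
threshold upward with no prior crossing nearby, whose activated neighborhood
subsequently grows (an expanding front).  Persistence filtering and
duplicate merging suppress single-frame noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .numerics import SpaceTimeCube

__all__ = [
    "PatternEvent",
    "EventPlot",
    "dominant_period",
    "phase_embed",
    "detect_spiral_tips",
    "detect_target_origins",
    "build_event_plot",
    "top_down_view",
]

TARGET_ORIGIN = "target_origin"
SPIRAL_TIP = "spiral_tip"


@dataclass(frozen=True)
class PatternEvent:
    """A typed point event at sub-pixel position (x, y) and frame t."""

    kind: str                 # "target_origin" | "spiral_tip"
    chirality: str            # "left" | "right" | "none"
    x: float
    y: float
    t: int

    def __post_init__(self) -> None:
        if self.kind not in (TARGET_ORIGIN, SPIRAL_TIP):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == TARGET_ORIGIN and self.chirality != "none":
            raise ValueError("target origins carry no chirality")
        if self.kind == SPIRAL_TIP and self.chirality not in ("left", "right"):
            raise ValueError("spiral tips must be left- or right-handed")


@dataclass
class EventPlot:
    """All events of one movie plus the lattice geometry."""

    events: list[PatternEvent]
    shape: tuple[int, int]
    n_frames: int

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.t, e.y, e.x))

    def of_kind(self, kind: str) -> list[PatternEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.kind, e.chirality, e.x, e.y, e.t) for e in self.events],
            columns=["kind", "chirality", "x", "y", "t"],
        )


def dominant_period(cube: SpaceTimeCube, max_sites: int = 200, seed: int = 0) -> float:
    """Dominant oscillation period (in frames) from the averaged per-site
    autocorrelation of the normalized signals.  Falls back to n_frames/4 when
    no oscillation is detectable."""
    data = np.asarray(cube.data, dtype=float)
    nt = data.shape[0]
    flat = data.reshape(nt, -1)
    sd = flat.std(axis=0)
    ok = np.flatnonzero(sd > 1e-12)
    fallback = max(4.0, nt / 4.0)
    if len(ok) == 0 or nt < 8:
        return fallback
    rng = np.random.default_rng(seed)
    pick = ok if len(ok) <= max_sites else rng.choice(ok, size=max_sites, replace=False)
    z = (flat[:, pick] - flat[:, pick].mean(axis=0)) / sd[pick]
    # per-site autocorrelation; each site votes with its first post-dip peak
    # and the median vote wins (robust to sites dominated by onset steps)
    n_lag = nt // 2
    ac = np.empty((n_lag, z.shape[1]))
    ac[0] = 1.0
    for lag in range(1, n_lag):
        ac[lag] = np.mean(z[: nt - lag] * z[lag:], axis=0)
    periods = []
    for s in range(ac.shape[1]):
        col = ac[:, s]
        below = np.flatnonzero(col < 0)
        start = below[0] if len(below) else 1
        seg = col[start:]
        if len(seg) < 3:
            continue
        peaks = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1 + start
        if len(peaks):
            # the fundamental period is the FIRST strong peak; noise can lift
            # a later harmonic marginally above it, so accept the earliest
            # peak within 80% of the strongest
            h = col[peaks].max()
            if h < 0.3:  # only clearly periodic sites get a vote
                continue
            best = peaks[col[peaks] >= 0.8 * h][0]
            periods.append(best)
    if len(periods) < max(3, len(pick) // 8):
        return fallback
    return float(np.median(periods))


def phase_embed(cube: SpaceTimeCube, ref_level: float = 0.0,
                delay: int | None = None) -> tuple[np.ndarray, int]:
    """Per-site phase cube from delay-coordinate embedding.

    Returns ``(phase, delay)`` where ``phase[k]`` corresponds to original
    frame ``k + delay``; sites with (near-)constant signal are NaN-masked.
    Phases lie in (-pi, pi].
    """
    data = np.asarray(cube.data, dtype=float)
    nt = data.shape[0]
    if nt < 3:
        raise ValueError("phase embedding needs at least 3 frames")
    period = max(4, int(round(dominant_period(cube))))
    if delay is None:
        delay = max(1, int(round(period / 4.0)))
    delay = int(min(delay, nt - 2))
    # rolling normalization (window ~ two periods): each site's oscillation is
    # centered locally in time, so sites that activate late in the movie do
    # not inherit a skewed global mean/std (which would shear the embedding
    # plane and create spurious phase seams)
    nwin = int(min(nt, 2 * period + 1))
    mov_mean = ndimage.uniform_filter1d(data, size=nwin, axis=0, mode="nearest")
    mov_sq = ndimage.uniform_filter1d(data * data, size=nwin, axis=0, mode="nearest")
    mov_sd = np.sqrt(np.maximum(mov_sq - mov_mean * mov_mean, 0.0))
    ok = mov_sd > 1e-12
    z = np.where(ok, (data - mov_mean) / np.where(ok, mov_sd, 1.0) - ref_level, np.nan)
    # phase[k] belongs to frame k + delay: atan2(z(t - delay), z(t))
    phase = np.arctan2(z[:-delay], z[delay:])
    # a phase angle is only meaningful where the signal actually oscillates:
    # mask site-frames whose amplitude over the trailing period is small
    # compared to the movie's global dynamic range
    win = min(nt, period + 1)
    lo, hi = np.percentile(data, [5.0, 95.0])
    scale = max(hi - lo, 1e-12)
    rmax = ndimage.maximum_filter1d(data, size=win, axis=0, mode="nearest")
    rmin = ndimage.minimum_filter1d(data, size=win, axis=0, mode="nearest")
    # trailing window: shift the centered filter output back by win//2
    swing = (rmax - rmin)[np.clip(np.arange(nt) - win // 2, 0, nt - 1)]
    weak = swing < 0.25 * scale
    # both embedding feet (t and t - delay) must sit in oscillating stretches
    phase[weak[delay:] | weak[:-delay]] = np.nan
    return phase, delay


def _wrap(dphi: np.ndarray) -> np.ndarray:
    return (dphi + np.pi) % (2.0 * np.pi) - np.pi


def detect_spiral_tips(phase_frame: np.ndarray, t: int = 0) -> list[PatternEvent]:
    """Phase singularities of one phase frame via plaquette winding sums."""
    ph = np.asarray(phase_frame, dtype=float)
    a = ph[:-1, :-1]
    b = ph[:-1, 1:]
    c = ph[1:, 1:]
    d = ph[1:, :-1]
    winding = _wrap(b - a) + _wrap(c - b) + _wrap(d - c) + _wrap(a - d)
    winding = np.where(
        np.isnan(a) | np.isnan(b) | np.isnan(c) | np.isnan(d), 0.0, winding
    )
    tips = []
    for i, j in zip(*np.nonzero(np.abs(winding) > np.pi)):
        chir = "left" if winding[i, j] > 0 else "right"
        tips.append(PatternEvent(SPIRAL_TIP, chir, x=j + 0.5, y=i + 0.5, t=t))
    return tips


def _disk(radius: int) -> np.ndarray:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy * yy + xx * xx <= radius * radius


def detect_target_origins(
    cube: SpaceTimeCube,
    act_threshold: float | None = None,
    radius_R: float = 10.0,
    window_W: int | None = None,
    radius_causal: float = 3.0,
    quiet_frac: float = 0.65,
) -> list[PatternEvent]:
    """Target-wave origins: isolated upward threshold crossings followed by a
    growing activated region.

    A candidate at (x, y, t) requires that no site within the small causal
    radius ``radius_causal`` crossed the threshold during the preceding
    ``window_W`` frames (sites activated by an incoming wave always have a
    neighbor that crossed just before, so they are excluded), and that the
    activated area in the disk of ``radius_R`` strictly grows over the
    following frames while starting small (an expanding, not an established,
    front).  Duplicates within ``radius_R`` and ``window_W`` merge to the
    earliest event (row-major tie-break).  ``quiet_frac`` demands that the
    site spent at least that fraction of the last two periods below the
    threshold (origins emerge from quiescence or sparse pulsing, not from
    ongoing near-sinusoidal oscillation).
    """
    data = np.asarray(cube.data, dtype=float)
    nt, ny, nx = data.shape
    if act_threshold is None:
        lo, hi = np.percentile(data, [5.0, 95.0])
        act_threshold = 0.5 * (lo + hi)
    period = dominant_period(cube)
    if window_W is None:
        # well under one period, so a pacemaker's periodic re-firings are
        # seen as fresh origins (the preceding wave cleared the causal disk)
        # while sites swept by a wave are excluded by their just-activated
        # neighbors
        window_W = int(round(0.5 * period))
    W = max(2, int(window_W))
    Wq = max(W, int(round(2.0 * period)))
    # duplicate-merge window: a source cannot re-originate within 1.5 periods
    Wd = max(W, int(round(1.5 * period)))
    G = max(1, W // 6)
    foot = _disk(int(round(radius_R)))
    foot_causal = _disk(int(round(radius_causal)))
    disk_area = int(foot.sum())
    dy, dx_ = np.nonzero(foot)
    dy = dy - foot.shape[0] // 2
    dx_ = dx_ - foot.shape[1] // 2

    lo_p, hi_p = np.percentile(data, [5.0, 95.0])
    hyst = 0.05 * max(hi_p - lo_p, 1e-12)
    active = data > act_threshold
    # hysteresis debouncing: a crossing needs the site to dip below
    # threshold - hyst before it can fire again above threshold + hyst
    act_hi = data > act_threshold + hyst
    act_lo = data < act_threshold - hyst
    cross = np.zeros(data.shape, dtype=bool)
    armed = act_lo[0] | ~act_hi[0]
    for tt in range(1, nt):
        cross[tt] = act_hi[tt] & armed
        armed = (armed & ~act_hi[tt]) | act_lo[tt]

    last_cross = np.full((ny, nx), -np.inf)
    accepted: list[PatternEvent] = []

    def disk_area_at(tt: int, y: int, x: int) -> int:
        ys = np.clip(y + dy, 0, ny - 1)
        xs = np.clip(x + dx_, 0, nx - 1)
        return int(active[tt, ys, xs].sum())

    for t in range(nt):
        if t >= W and t + 2 * G < nt:
            recent = ndimage.maximum_filter(last_cross, footprint=foot_causal, mode="nearest")
            q0 = max(0, t - Wq)
            quiet = (~active[q0:t]).mean(axis=0) >= quiet_frac
            cand = cross[t] & (recent < t - W) & quiet
            if cand.any():
                for y, x in zip(*np.nonzero(cand)):
                    a0 = disk_area_at(t, y, x)
                    if a0 > 0.35 * disk_area:
                        continue
                    a1 = disk_area_at(t + G, y, x)
                    a2 = disk_area_at(t + 2 * G, y, x)
                    if not (a0 < a1 < a2):
                        continue
                    dup = any(
                        (e.t >= t - Wd) and ((e.x - x) ** 2 + (e.y - y) ** 2 <= radius_R**2)
                        for e in accepted
                    )
                    if not dup:
                        accepted.append(
                            PatternEvent(TARGET_ORIGIN, "none", x=float(x), y=float(y), t=t)
                        )
        last_cross[cross[t]] = t
    return accepted


@dataclass
class EventDetectionConfig:
    delay: int | None = None
    act_threshold: float | None = None
    radius_R: float = 10.0
    window_W: int | None = None
    persistence: int = 3
    link_radius: float = 2.0


def _persistent_tips(per_frame: list[list[PatternEvent]], persistence: int,
                     link_radius: float) -> list[PatternEvent]:
    """Greedy nearest-neighbor linking of tips across frames; only chains at
    least ``persistence`` frames long are emitted (all their members)."""
    chains: list[list[PatternEvent]] = []
    open_chains: list[list[PatternEvent]] = []
    for tips in per_frame:
        unmatched = list(tips)
        next_open: list[list[PatternEvent]] = []
        for chain in open_chains:
            last = chain[-1]
            best = None
            best_d = link_radius**2
            for e in unmatched:
                if e.chirality != last.chirality:
                    continue
                d = (e.x - last.x) ** 2 + (e.y - last.y) ** 2
                if d <= best_d:
                    best, best_d = e, d
            if best is not None:
                unmatched.remove(best)
                chain.append(best)
                next_open.append(chain)
            else:
                chains.append(chain)
        for e in unmatched:
            next_open.append([e])
        open_chains = next_open
    chains.extend(open_chains)
    out: list[PatternEvent] = []
    for chain in chains:
        if len(chain) >= persistence:
            out.extend(chain)
    return out


def build_event_plot(cube: SpaceTimeCube,
                     config: EventDetectionConfig | None = None) -> EventPlot:
    """Full detection pipeline: phase embedding, per-frame tip detection with
    temporal persistence filtering, and target-origin detection."""
    config = config or EventDetectionConfig()
    data = np.asarray(cube.data, dtype=float)
    nt, ny, nx = data.shape
    events: list[PatternEvent] = []
    if nt >= 8 and np.ptp(data) > 0:
        phase, delay = phase_embed(cube, delay=config.delay)
        per_frame = [detect_spiral_tips(phase[k], t=k + delay) for k in range(phase.shape[0])]
        events.extend(_persistent_tips(per_frame, config.persistence, config.link_radius))
        events.extend(
            detect_target_origins(cube, act_threshold=config.act_threshold,
                                  radius_R=config.radius_R, window_W=config.window_W)
        )
    return EventPlot(events, shape=(ny, nx), n_frames=nt)


def top_down_view(ep: EventPlot, kind: str) -> np.ndarray:
    """Per-site event counts collapsed over time for one event kind."""
    counts = np.zeros(ep.shape, dtype=int)
    for e in ep.events:
        if e.kind != kind:
            continue
        i = int(np.clip(round(e.y), 0, ep.shape[0] - 1))
        j = int(np.clip(round(e.x), 0, ep.shape[1] - 1))
        counts[i, j] += 1
    return counts
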