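"""Ensemble statistics relating cell-property maps to pattern-event maps.

Workflow: accumulate per-site event counts over an ensemble of runs
(occupancy maps), smooth both the occupancy and the property map with an
isotropic Gaussian of a given radius (sigma, in lattice sites), and compute
Spearman rank correlations across sites, reported as mean +/- SEM over runs
as a function of the filter radius.  A complementary geometric statistic
measures how close spiral tips lie to the Voronoi edges of a pacemaker seed
set, against a uniform-placement permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree
from scipy.stats import spearmanr

from .events import EventPlot, PatternEvent

__all__ = [
    "OccupancyMap",
    "CorrelationCurve",
    "occupancy_map",
    "gaussian_smooth",
    "spearman_map",
    "correlation_vs_radius",
    "voronoi_edges",
    "voronoi_edge_stat",
]


@dataclass
class OccupancyMap:
    """Per-site event counts accumulated over an ensemble of runs."""

    counts: np.ndarray
    n_runs: int
    kind: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("occupancy counts must be >= 0")


@dataclass
class CorrelationCurve:
    """Mean Spearman correlation (with SEM over runs) per filter radius."""

    radii: list[float]
    mean_rho: list[float]
    sem_rho: list[float]
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        if not (len(self.radii) == len(self.mean_rho) == len(self.sem_rho)):
            raise ValueError("curve fields must share length")


def occupancy_map(plots: list[EventPlot], kind: str) -> OccupancyMap:
    """Accumulate events of one kind over runs (sub-pixel binned to nearest site)."""
    if not plots:
        raise ValueError("need at least one event plot")
    shape = plots[0].shape
    if any(pl.shape != shape for pl in plots):
        raise ValueError("event plots must share the lattice shape")
    counts = np.zeros(shape, dtype=int)
    for pl in plots:
        for e in pl.events:
            if e.kind != kind:
                continue
            i = int(np.clip(round(e.y), 0, shape[0] - 1))
            j = int(np.clip(round(e.x), 0, shape[1] - 1))
            counts[i, j] += 1
    return OccupancyMap(counts, n_runs=len(plots), kind=kind)


def gaussian_smooth(m: np.ndarray, radius: float) -> np.ndarray:
    """Isotropic Gaussian filter with standard deviation ``radius`` sites.

    Boundary mode is symmetric reflection, which preserves the total sum;
    radius 0 returns the input unchanged.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    m = np.asarray(m, dtype=float)
    if radius == 0:
        return m.copy()
    return ndimage.gaussian_filter(m, sigma=radius, mode="reflect")


def spearman_map(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation over all lattice sites (average ranks for ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for a constant map")
    rho = spearmanr(a.ravel(), b.ravel()).statistic
    return float(rho)


def correlation_vs_radius(
    run_plots: list[EventPlot],
    property_map: np.ndarray | None,
    pairs: list[tuple[str, str]],
    radii: list[float] = (1.0, 2.0, 4.0, 8.0, 16.0),
) -> list[CorrelationCurve]:
    """Per-run, per-radius Spearman correlations between smoothed maps.

    Each element of ``pairs`` names two maps: an event kind
    (``"target_origin"`` / ``"spiral_tip"``) or ``"property"`` for the
    supplied property map (e.g. time offsets, pacemaker mask).  Runs in which
    one side is constant (e.g. no events) are skipped for that pair.
    """
    if len(run_plots) < 2:
        raise ValueError("need at least 2 runs for an SEM")
    curves = []
    for pair in pairs:
        per_radius: list[list[float]] = [[] for _ in radii]
        for pl in run_plots:
            maps = {}
            for side in pair:
                if side == "property":
                    if property_map is None:
                        raise ValueError("pair references the property map but none given")
                    maps[side] = np.asarray(property_map, dtype=float)
                else:
                    maps[side] = occupancy_map([pl], side).counts.astype(float)
            for k, rad in enumerate(radii):
                a = gaussian_smooth(maps[pair[0]], rad)
                b = gaussian_smooth(maps[pair[1]], rad)
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    continue
                per_radius[k].append(spearman_map(a, b))
        mean = [float(np.mean(v)) if v else float("nan") for v in per_radius]
        sem = [
            float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
            for v in per_radius
        ]
        curves.append(CorrelationCurve(list(radii), mean, sem, pair))
    return curves


def voronoi_edges(seeds: np.ndarray, bounds: tuple[float, float, float, float],
                  sample_step: float = 0.25) -> np.ndarray:
    """Voronoi edge set of ``seeds`` clipped to the rectangle ``bounds``
    (xmin, ymin, xmax, ymax), returned as densely sampled points.

    Infinite ridges are extended far beyond the bounds before clipping.
    """
    from shapely.geometry import LineString, box

    seeds = np.asarray(seeds, dtype=float)
    if len(seeds) < 3:
        raise ValueError("need at least 3 seed points")
    if np.linalg.matrix_rank(seeds[1:] - seeds[0]) < 2:
        raise ValueError("seed points are collinear")
    vor = Voronoi(seeds)
    xmin, ymin, xmax, ymax = bounds
    clip = box(xmin, ymin, xmax, ymax)
    far = 4.0 * max(xmax - xmin, ymax - ymin)
    center = seeds.mean(axis=0)
    segments = []
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 >= 0 and v2 >= 0:
            segments.append((vor.vertices[v1], vor.vertices[v2]))
        else:
            vfin = vor.vertices[v2 if v1 < 0 else v1]
            # direction: perpendicular to the seed pair, pointing away from center
            t = seeds[p2] - seeds[p1]
            t = t / np.linalg.norm(t)
            n = np.array([-t[1], t[0]])
            mid = 0.5 * (seeds[p1] + seeds[p2])
            if np.dot(mid - center, n) < 0:
                n = -n
            segments.append((vfin, vfin + far * n))
    pts = []
    for a, b in segments:
        seg = LineString([a, b]).intersection(clip)
        if seg.is_empty:
            continue
        geoms = getattr(seg, "geoms", [seg])
        for g in geoms:
            if g.length == 0:
                continue
            n_s = max(2, int(np.ceil(g.length / sample_step)) + 1)
            pts.extend(
                g.interpolate(d).coords[0] for d in np.linspace(0.0, g.length, n_s)
            )
    if not pts:
        raise ValueError("no Voronoi edges inside the bounds")
    return np.asarray(pts)


def voronoi_edge_stat(
    tips: list[PatternEvent] | np.ndarray,
    seeds: np.ndarray,
    shape: tuple[int, int],
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Mean distance of tips to the Voronoi edge set of ``seeds``, with a
    uniform-placement permutation null.

    Returns ``(mean_distance, null_mean, p_value)`` with a one-sided p-value
    (fraction of permutations with mean distance <= observed, add-one
    corrected).
    """
    rng = rng or np.random.default_rng(0)
    if isinstance(tips, list):
        pts = np.array([(e.x, e.y) for e in tips], dtype=float)
    else:
        pts = np.asarray(tips, dtype=float)
    if len(pts) < 1:
        raise ValueError("need at least one tip")
    ny, nx = shape
    edges = voronoi_edges(np.asarray(seeds, dtype=float),
                          bounds=(0.0, 0.0, nx - 1.0, ny - 1.0))
    tree = cKDTree(edges)
    obs = float(tree.query(pts)[0].mean())
    null = np.empty(n_perm)
    for k in range(n_perm):
        rand = rng.uniform([0, 0], [nx - 1, ny - 1], size=(len(pts), 2))
        null[k] = tree.query(rand)[0].mean()
    p = (1.0 + np.sum(null <= obs)) / (n_perm + 1.0)
    return obs, float(null.mean()), float(p)
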