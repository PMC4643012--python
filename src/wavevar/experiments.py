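"""Ready-made experiment recipes binding simulators, event detection and
ensemble statistics together.

Each fixture reproduces one canonical experimental setup at reduced scale
(60x60 lattices, tens to a hundred ensemble members) so a complete experiment
runs on a laptop in minutes; the lattice size, run length and ensemble size
can be overridden to the full-scale configuration.  Randomness derives from a
single base seed: ensemble member k runs with ``base_seed + k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as wio
from .events import EventDetectionConfig, EventPlot, build_event_plot
from .fhn import CellPropertyMap, FHNParams, fhn_simulate
from .goldbeter import (GBPathParams, GoldbeterParams, effective_pacemakers,
                        goldbeter_simulate, sample_offsets)
from .levine import (LevineParams, clustered_pacemakers, levine_simulate,
                     scattered_pacemakers)
from .minimal_models import (SchnakenbergParams, ca_open_wavefront_init,
                             ca_run, classify_turing_pattern, schnakenberg_simulate)
from .numerics import SpaceTimeCube
from .stats import gaussian_smooth, occupancy_map, spearman_map

__all__ = [
    "RunConfig",
    "ConfigError",
    "run_experiment",
    "FIXTURES",
    "fhn_pacemaker_map",
    "levine_ensemble",
    "goldbeter_ensemble",
    "goldbeter_correlation_curves",
    "pooled_voronoi_stat",
    "pacemaker_tip_correlation",
]

# detector settings shared by the ensemble experiments: only rotors that
# persist for at least a full rotation count as spiral tips
ENSEMBLE_DETECT = EventDetectionConfig(persistence=12)

# Levine ensemble regime (see docs/methods.md): relay marginal at the lowest
# excitability so wavefronts can break, frequent spontaneous firing
LEVINE_ENSEMBLE = dict(c_min=2.3, e_max=0.5, eta=0.0, beta=0.20, p_F=0.2,
                       pm_quiescence=0.0, pm_gain=1.0, E0=0.0)


class ConfigError(ValueError):
    """Raised for unknown configuration keys."""


@dataclass
class RunConfig:
    """Flat experiment configuration; round-trips through YAML."""

    model: str = "fhn"
    fixture: str | None = None
    shape: tuple[int, int] = (60, 60)
    T: float = 400.0
    dt: float | None = None
    record_every: int = 10
    seed: int = 0
    n_runs: int = 1
    out_dir: str = "wavevar_out"
    params: dict = field(default_factory=dict)

    _KNOWN = {"model", "fixture", "shape", "T", "dt", "record_every", "seed",
              "n_runs", "out_dir", "params"}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "model": self.model, "fixture": self.fixture,
            "shape": list(self.shape), "T": self.T, "dt": self.dt,
            "record_every": self.record_every, "seed": self.seed,
            "n_runs": self.n_runs, "out_dir": self.out_dir,
            "params": dict(self.params),
        }


def fhn_pacemaker_map(shape: tuple[int, int], c_medium: float,
                      c_pacemaker: float = 0.0, radius: float = 1.5,
                      center: tuple[int, int] | None = None) -> CellPropertyMap:
    """Uniform excitability map with a small central pacemaker patch.

    A single site cannot excite its neighbors at D = 0.1 (the diffusive load
    swamps one cell), so the pacemaker is a compact 3x3 patch.
    """
    ny, nx = shape
    cy, cx = center if center is not None else (ny // 2, nx // 2)
    c = np.full(shape, float(c_medium))
    yy, xx = np.mgrid[0:ny, 0:nx]
    c[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = c_pacemaker
    return CellPropertyMap(c)


# ---------------------------------------------------------------------------
# figure fixtures


def _fig1a_fhn(shape, T, seed, record_every):
    """Established target wave (c = 0.025 around a c = 0 pacemaker) and an
    established spiral (uniform c = 0.021, open-wave start)."""
    p = FHNParams()
    target = fhn_simulate(fhn_pacemaker_map(shape, 0.025), p, T=T, dt=0.02,
                          record_every=record_every * 10, seed=seed)
    spiral = fhn_simulate(CellPropertyMap(np.full(shape, 0.021)), p, T=T,
                          dt=0.02, record_every=record_every * 10, seed=seed,
                          init="open_wave")
    return {"target": target, "spiral": spiral}


def _fig1c_ca(shape, T, seed, record_every):
    """Open wavefront curling into a spiral in the three-state automaton."""
    nx = shape[1]
    g = ca_open_wavefront_init(nx, shape[0], nx // 2)
    grids = ca_run(g, int(T), record_every=record_every)
    cube = SpaceTimeCube(np.stack([gr.states.astype(float) for gr in grids]),
                         dt_record=float(record_every))
    cube.meta.update(model="ca", fixture="fig1C")
    return {"movie": cube, "grids": grids}


def _fig1c_levine(shape, T, seed, record_every):
    """Open-wavefront spiral genesis in the hybrid model (developed medium)."""
    p = LevineParams(E0=0.25, p_F=0.0)
    ny, nx = shape
    pm = np.zeros(shape, dtype=bool)
    cube, state = levine_simulate(pm, p, T=T, seed=seed,
                                  record_every=record_every,
                                  return_state=True, init_wavefront=True)
    return {"movie": cube}


def _fig2a_levine(shape, T, seed, record_every):
    """Levine model, static random pacemakers (fraction 0.195): spirals early,
    no sustained target phase."""
    p = LevineParams(**LEVINE_ENSEMBLE)
    rng = np.random.default_rng(seed)
    pm = scattered_pacemakers(shape, 0.195, rng)
    cube = levine_simulate(pm, p, T=T, seed=seed, record_every=record_every)
    return {"movie": cube, "events": build_event_plot(cube, ENSEMBLE_DETECT)}


def _fig2b_goldbeter(shape, T, seed, record_every):
    """Goldbeter model, Delta = 25: sustained target phase, then spirals."""
    p = GoldbeterParams()
    pp = GBPathParams(Delta=25.0)
    rng = np.random.default_rng(seed)
    off = sample_offsets(shape, pp.Delta, rng)
    cube = goldbeter_simulate(off, pp, p, T=T, seed=seed, record_every=50)
    return {"movie": cube, "offsets": off, "events": build_event_plot(cube)}


FIXTURES = {
    "fig1A": _fig1a_fhn,
    "fig1C_ca": _fig1c_ca,
    "fig1C_levine": _fig1c_levine,
    "fig2A": _fig2a_levine,
    "fig2B": _fig2b_goldbeter,
}


def run_experiment(config: RunConfig) -> dict:
    """Execute simulate -> detect -> write for one configuration.

    Returns a dict of artifact paths; the effective configuration and seed
    are logged next to the outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    if config.fixture is not None:
        if config.fixture not in FIXTURES:
            raise ConfigError(f"unknown fixture {config.fixture!r}; "
                              f"available: {sorted(FIXTURES)}")
        result = FIXTURES[config.fixture](config.shape, config.T, config.seed,
                                          config.record_every)
        for name, obj in result.items():
            if isinstance(obj, SpaceTimeCube):
                path = out / f"{config.fixture}_{name}.tif"
                wio.save_movie(obj, path)
                artifacts[name] = str(path)
            elif isinstance(obj, EventPlot):
                path = out / f"{config.fixture}_{name}.csv"
                wio.save_events(obj, path)
                artifacts[name] = str(path)
    else:
        cube = _simulate_generic(config)
        movie_path = out / f"{config.model}_movie.tif"
        wio.save_movie(cube, movie_path)
        artifacts["movie"] = str(movie_path)
        ep = build_event_plot(cube)
        events_path = out / f"{config.model}_events.csv"
        wio.save_events(ep, events_path)
        artifacts["events"] = str(events_path)

    import json as _json
    log = {"config": config.to_dict(), "versions": _versions()}
    log_path = out / "run_log.yaml"
    wio.save_config(log, log_path)
    artifacts["log"] = str(log_path)
    return artifacts


def _simulate_generic(config: RunConfig) -> SpaceTimeCube:
    params = dict(config.params)
    seed = config.seed
    if config.model == "fhn":
        c_value = params.pop("c", 0.021)
        p = FHNParams(**params)
        cmap = CellPropertyMap(np.full(config.shape, float(c_value)))
        return fhn_simulate(cmap, p, T=config.T, dt=config.dt or 0.02,
                            record_every=config.record_every, seed=seed,
                            init="open_wave")
    if config.model == "levine":
        frac = params.pop("pacemaker_fraction", 0.195)
        p = LevineParams(**params)
        rng = np.random.default_rng(seed)
        pm = scattered_pacemakers(config.shape, frac, rng)
        return levine_simulate(pm, p, T=config.T, seed=seed,
                               record_every=config.record_every)
    if config.model == "goldbeter":
        delta = params.pop("Delta", 25.0)
        p = GoldbeterParams(**params)
        pp = GBPathParams(Delta=float(delta))
        rng = np.random.default_rng(seed)
        off = sample_offsets(config.shape, pp.Delta, rng)
        return goldbeter_simulate(off, pp, p, T=config.T, seed=seed,
                                  record_every=config.record_every)
    if config.model == "schnakenberg":
        p = SchnakenbergParams(**params)
        u, v = schnakenberg_simulate(p, shape=config.shape, T=config.T,
                                     dt=config.dt or 0.005, seed=seed)
        cube = SpaceTimeCube(u[None], dt_record=config.T)
        cube.meta.update(model="schnakenberg",
                         pattern=classify_turing_pattern(u))
        return cube
    if config.model == "ca":
        g = ca_open_wavefront_init(config.shape[1], config.shape[0],
                                   int(params.pop("length", config.shape[1] // 2)))
        grids = ca_run(g, int(config.T), record_every=config.record_every)
        return SpaceTimeCube(np.stack([gr.states.astype(float) for gr in grids]),
                             dt_record=float(config.record_every))
    raise ConfigError(f"unknown model {config.model!r}")


def _versions() -> dict:
    import numpy, scipy, skimage
    from . import __version__
    return {"wavevar": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "scikit-image": skimage.__version__}


# ---------------------------------------------------------------------------
# ensemble experiments (occupancy statistics)


def levine_ensemble(pm_mask: np.ndarray, n_runs: int, base_seed: int,
                    T: float = 400.0, params: dict | None = None,
                    record_every: int = 10) -> list[EventPlot]:
    """Repeated Levine runs over a conserved pacemaker layout; per-run
    randomness is the spontaneous firing sequence."""
    p = LevineParams(**(params or LEVINE_ENSEMBLE))
    plots = []
    for k in range(n_runs):
        cube = levine_simulate(pm_mask, p, T=T, seed=base_seed + k,
                               record_every=record_every)
        plots.append(build_event_plot(cube, ENSEMBLE_DETECT))
    return plots


def goldbeter_ensemble(shape: tuple[int, int], Delta: float, n_runs: int,
                       base_seed: int, T: float = 220.0,
                       fixed_sites: list[tuple[int, int]] | None = None,
                       advantage: float = 0.0,
                       params: GoldbeterParams | None = None
                       ) -> tuple[list[EventPlot], list[CellPropertyMap]]:
    """Repeated Goldbeter runs; per-run randomness is the offset map."""
    p = params or GoldbeterParams()
    pp = GBPathParams(Delta=Delta)
    plots, offsets = [], []
    for k in range(n_runs):
        rng = np.random.default_rng(base_seed + k)
        off = sample_offsets(shape, Delta, rng, fixed_sites=fixed_sites,
                             advantage=advantage)
        cube = goldbeter_simulate(off, pp, p, T=T, seed=base_seed + k,
                                  record_every=50)
        plots.append(build_event_plot(cube))
        offsets.append(off)
    return plots, offsets


def pacemaker_tip_correlation(pm_mask: np.ndarray, plots: list[EventPlot],
                              radius: float = 4.0,
                              n_boot: int = 200, seed: int = 0
                              ) -> tuple[float, tuple[float, float]]:
    """Spearman correlation between the smoothed pacemaker layout and pooled
    spiral-tip occupancy, with a bootstrap-over-runs confidence interval."""
    occs = [occupancy_map([pl], "spiral_tip").counts for pl in plots]
    sm_pm = gaussian_smooth(pm_mask.astype(float), radius)

    def rho(sel):
        total = np.sum([occs[i] for i in sel], axis=0).astype(float)
        if np.ptp(total) == 0:
            return np.nan
        return spearman_map(sm_pm, gaussian_smooth(total, radius))

    point = rho(range(len(occs)))
    rng = np.random.default_rng(seed)
    boots = [rho(rng.integers(0, len(occs), len(occs))) for _ in range(n_boot)]
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return float(point), (float(lo), float(hi))


def goldbeter_correlation_curves(plots: list[EventPlot],
                                 offsets: list[CellPropertyMap],
                                 radii=(1.0, 2.0, 4.0, 8.0, 16.0)) -> dict:
    """Per-run Spearman correlations between smoothed per-run maps, averaged
    over runs (mean and SEM per radius) for the three canonical pairs."""
    pairs = {"origins_offsets": ("target_origin", "offsets"),
             "tips_origins": ("spiral_tip", "target_origin"),
             "tips_offsets": ("spiral_tip", "offsets")}
    acc = {name: {r: [] for r in radii} for name in pairs}
    for pl, off in zip(plots, offsets):
        maps = {
            "target_origin": occupancy_map([pl], "target_origin").counts.astype(float),
            "spiral_tip": occupancy_map([pl], "spiral_tip").counts.astype(float),
            "offsets": off.values,
        }
        for name, (a, b) in pairs.items():
            for r in radii:
                sa = gaussian_smooth(maps[a], r)
                sb = gaussian_smooth(maps[b], r)
                if np.ptp(sa) == 0 or np.ptp(sb) == 0:
                    continue
                acc[name][r].append(spearman_map(sa, sb))
    out = {}
    for name in pairs:
        out[name] = {
            "radii": list(radii),
            "mean": [float(np.mean(v)) if v else float("nan")
                     for v in acc[name].values()],
            "sem": [float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1
                    else float("nan") for v in acc[name].values()],
        }
    return out


def pooled_voronoi_stat(plots: list[EventPlot],
                        masks: list[np.ndarray],
                        shape: tuple[int, int],
                        n_perm: int = 999, seed: int = 0) -> tuple[float, float, float]:
    """Mean distance of all pooled tips to their own run's Voronoi edge set,
    against a uniform-placement null pooled the same way."""
    rng = np.random.default_rng(seed)
    from scipy.spatial import cKDTree

    from .stats import voronoi_edges

    obs_sum = 0.0
    n_tips = 0
    null_sums = np.zeros(n_perm)
    ny, nx = shape
    for pl, mask in zip(plots, masks):
        tips = pl.of_kind("spiral_tip")
        if len(tips) == 0 or mask.sum() < 3:
            continue
        ys, xs = np.nonzero(mask)
        tree = cKDTree(voronoi_edges(np.column_stack([xs, ys]).astype(float),
                                     (0.0, 0.0, nx - 1.0, ny - 1.0)))
        pts = np.array([(e.x, e.y) for e in tips])
        obs_sum += tree.query(pts)[0].sum()
        n_tips += len(pts)
        for b in range(n_perm):
            rand = rng.uniform([0, 0], [nx - 1, ny - 1], size=(len(pts), 2))
            null_sums[b] += tree.query(rand)[0].sum()
    if n_tips == 0:
        raise ValueError("no tips in any run")
    obs = obs_sum / n_tips
    null = null_sums / n_tips
    p = (1.0 + np.sum(null <= obs)) / (n_perm + 1.0)
    return float(obs), float(null.mean()), float(p)
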