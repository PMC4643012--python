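# Methods

`wavevar` studies how fixed (quenched) cell-to-cell variability shapes
self-organized spatiotemporal patterns in excitable media, with
*Dictyostelium discoideum* cAMP signaling as the anchor system.  Five
simulators of increasing biological detail feed a common event-detection
layer, which converts movies into point events (target-wave origins and
chirality-resolved spiral tips); ensemble statistics then relate
cell-property maps to event maps.  This note records the models, the
parameter choices that were genuinely open, the numerical decisions, and what
the synthetic tests do and do not demonstrate.

## Lattice conventions

All models live on a regular `ny x nx` lattice with spacing `dx = 1`
(dimensionless).  Diffusion uses the five-point Laplacian except in the
hybrid (Levine) model, which uses an equal-weight eight-point stencil
(sum of 8 neighbors minus 8x center).  Boundaries are zero-flux by default
(edge replication, which makes pure diffusion exactly mass-conserving);
periodic wrapping is available by configuration.  Time stepping is explicit
forward Euler with per-model defaults chosen inside the diffusive stability
limit `dt < dx^2 / (2 d D_max)`; every run is bit-reproducible from
`(configuration, seed)` and ensemble member `k` uses `base_seed + k`.

## Models

### Three-state cellular automaton

Susceptible/excited/refractory states on a von Neumann (4-cell)
neighborhood: S ignites next to an E, E always enters R, R regenerates after
`r` steps (default `r = 1`).  The stochastic variant adds spontaneous
excitation with probability `f` per site and step and replaces the fixed
refractory period by a recovery probability `p`.  An open wavefront (a
half-width row of E with an adjacent R wake) curls at its free end into a
self-sustained rotor; the same front at full width annihilates at the
boundary.  The open-front geometry (half the lattice width, centered) is an
operational choice; only the qualitative outcome is externally constrained.

### Schnakenberg system

Two-species activator-substrate kinetics, `c1 = 0.05`, `c-1 = 1`, `c3 = 1`,
`gamma = 2`, `Du = 1`, `Dv = 20`; the feed `c2` selects spots (1.00) or
stripes (1.57).  Initial conditions perturb the homogeneous steady state
`u* = (c1+c2)/c-1`, `v* = c2/(c3 u*^2)` uniformly within 1e-2.  Linear
stability of the steady state gives the dispersion relation used as a
diagnostic: with these constants the maximally unstable wavenumber is around
0.7-0.9, i.e. a pattern wavelength of 7-9 sites, which a 64x64 lattice
resolves comfortably.  Because spots-vs-stripes is ordinarily judged by eye, the
classifier is an explicit operational rule: threshold
at the median, label both phases with 4-connectivity, take the more
fragmented phase; many compact components of low eccentricity mean spots,
elongated skeletons (length-to-width above 3) mean stripes.

### FitzHugh-Nagumo lattice

`du/dt = (1/eps)((a-u)(u-1)u - v) + D lap(u)`, `dv/dt = b u - gamma v + c`,
with `a = -1`, `b = gamma = 0.12`, `eps = 1`, `D = 0.1` (the printed
"g = b = 0.12" is read as `gamma = b`).  With `b = gamma` the rest state has
the closed form `u* = cbrt(-c/gamma)`, and the Hopf boundary sits at
`|c| ~ 0.019`: elements are oscillatory near `c = 0` (fastest oscillation at
`c ~ 0`), excitable at `c = 0.021...0.030`, and non-oscillatory at the path
start `c = -0.02`.  Regime classification integrates a single element: a
linearly unstable rest state plus a sustained limit cycle means oscillatory;
otherwise an instantaneous kick `u -> u + 0.5` that drives `u` above 0.5
means excitable.  The developmental-path variant moves every cell along
`c(t) = c0 tanh[(t - t_c + dt_ij)/T_c]` (`c0 = 0.02`, `t_c = 1000`,
`T_c = 50`) with i.i.d. exponential time offsets of mean `Delta = 500`.

Pacemaker geometry: a single `c = 0` site cannot excite `c = 0.025`
neighbors at `D = 0.1` (the diffusive load swamps one cell), so pacemaker
fixtures use a compact 3x3 patch.  Similarly, the broken-wavefront setup
(fraction 0.4 at lower excitability `c = 0.030`) assigns the weak fraction
in spatially correlated areas (thresholded smoothed noise, correlation
length ~3 sites): isolated weak single sites average out diffusively and do
not break fronts, whereas weak *areas* do, which matches the phenomenon the
setup is meant to show.

### Hybrid automaton ("Levine" model)

Cells are discrete units (ready / firing / absolute refractory / relative
refractory) coupled to a cAMP field
`dc/dt = -Gamma c + r_F s + D lap8(c)` and a monotone excitability
`dE/dt = eta + beta c` capped at `e_max`.  Ready and relative-refractory
cells fire when local cAMP exceeds
`t(tau) = [c_max - A tau/(tau + T_ARP)](1 - E)` with
`A = (T_RRP + T_ARP)(c_max - c_min)/T_RRP`; the ready state uses
`tau = T_RRP`, so its threshold is `c_min (1 - E)`.  Firing lasts 1 time
unit; E never resets (it only grows to the cap).  Published headline values
(`beta`, pacemaker fraction, starting excitability per experiment) are used
as printed; all remaining constants are reconstructed defaults:
`Gamma = 2`, `r_F = 30`, `D = 0.5`, `c_max = 5`, `c_min = 3` (module
default), `T_ARP = 2`, `T_RRP = 8`, `e_max = 0.5`, `dt = 0.1`.  These
satisfy, by direct measurement: a plane wavefront delivers ~2.3 units of
cAMP to the next row, a single firing cell delivers ~0.7 to its neighbor,
and ambient cAMP in a fully active lattice stays near 0.9 - so relay is
robust for developed (high-E) cells, marginal at low E (fronts can break),
and quiescence is re-established between waves.

Two optional reconstruction devices exist for pacemaker behavior, both off
in the ensemble fixtures: a quiescence gate (spontaneous firing only from a
long-rested ready state) and an emission gain (spontaneous episodes produce
more cAMP than relayed ones).  The spontaneous firing probability is printed
per "time step" without the step length; the ensemble fixtures use an
effective rate of 0.2 per unit time (equivalently 0.002 per 0.01-unit step),
which makes pacemakers behave as strong rhythmic perturbations, and a relay
threshold `c_min = 2.3` so that wavefronts can break and rotors form.

### Reduced Martiel-Goldbeter relay model

Three variables per lattice element (each representing a small synchronized
cell group): receptor activity `rho_T`, intracellular cAMP `beta`,
extracellular cAMP `gamma` (the diffusing species).  Kinetic constants are
the standard literature set for the reduced model: `k1 = 0.036`,
`k2 = 0.666`, `L1 = 10`, `L2 = 0.005`, `c = 10`, `q = 4000`,
`lambda = 0.01`, `theta = 0.01`, `eps = 1`, `alpha = 3`, `ki = 1.7`,
`kt = 0.9`, `h = 5` (1/min where dimensional), `D_gamma = 0.4` sites^2/min,
`dt = 0.01` min.  The synthesis function uses the model's standard form
`Phi = alpha(lambda theta + eps Y^2) / (1 + alpha theta + eps Y^2 (1+alpha))`;
with these constants a well-mixed element oscillates with a period of 8-16
minutes in a `sigma`-`k_e` island bordered by excitable territory, matching
the model's known behavior.

The developmental path raises adenylate-cyclase activity `sigma` before the
extracellular phosphodiesterase activity `k_e`:
`sigma: 0.10 -> 0.65` centered at `t = 60` with width 25;
`k_e: 6.5 -> 12.0` centered at `t = 110` with width 10 (both sigmoidal in
min^-1; the sigma-path denominator is read as its width constant, by
symmetry with the k_e line).  A cell therefore traverses steady ->
excitable -> oscillatory -> excitable; the first excitable window is ~10 min
wide, so at the moment the excitable regime first holds the majority of a
desynchronized population, the most advanced cells are mid-oscillation -
the "effective pacemaker" scenario.  Effective pacemakers are defined
operationally as sites in the top `q` offset quantile (default 5%) that
classify oscillatory at that first-majority time, with deterministic
tie-breaks.  Per-cell time offsets are exponential with mean `Delta` (25 by
default; 15 in the five-fixed-pacemaker setup, where the fixed sites get an
additive offset bonus of 20 as their "time advantage").

## Event detection

Tips are phase singularities.  Signals are normalized per site with a
*rolling* mean and standard deviation (window two periods): a global
normalization would skew the embedding plane for sites that only start
oscillating mid-movie and create artificial phase seams.  Phase is the delay
embedding `phi(t) = atan2(z(t-delay), z(t))`, delay = quarter of the
dominant period; the period is the median of per-site autocorrelation peak
votes, counting only clearly periodic sites.  Phases are masked wherever the
trailing-window signal swing is below a quarter of the movie's dynamic range
(no oscillation, no phase) and wherever either embedding foot sits in such a
stretch.  The winding sum of wrapped phase differences around each 2x2
plaquette marks tips (|winding| = 2 pi); positive winding (counter-clockwise
in array coordinates, y down) is "left".  Tips must persist for at least 3
recorded frames within a 2-site link radius (ensemble fixtures require 12
frames, about one full rotation, so only true rotors count).

Target origins are threshold crossings out of quiescence.  The activation
threshold defaults to the midpoint of the movie's 5th/95th percentiles, with
a hysteresis band of 5% of the dynamic range to debounce grazing
oscillations.  A crossing is an origin if (i) no site within a small causal
radius (3 sites) crossed during the preceding half period - sites activated
by an incoming wave always have a neighbor that crossed just before, while a
pacemaker's periodic re-firings are clear of their own previous wave; (ii)
the site spent at least 65% of the previous two periods below threshold
(origins emerge from quiescence or sparse pulsing, not from ongoing
sinusoidal oscillation); and (iii) the activated area in the surrounding
10-site disk starts small and strictly grows (an expanding, not an
established, front).  Duplicates within 10 sites and 1.5 periods merge to
the earliest event.

## Synthetic ground-truth movies

Kinematic waves with analytically known events: Archimedean spirals
`cos(kr r - chi theta - omega t)` (tip at the center every frame, chirality
`chi`) and expanding target rings gated at per-source onset times (one
origin per source).  Colliding target fronts annihilate - each site belongs
to the source whose front arrives first, amplitude-tapered over 3 sites at
the seam - because a raw superposition of incoherent waves contains
interference singularities that belong to neither source.  Mixed movies
composite a spiral and a target territory the same way.  Noise is i.i.d.
Gaussian per site and frame.  These movies share the statistical structure
of rescaled dark-field recordings (rotating and expanding waves, additive
noise) but none of the photometric properties of real microscopy; passing
the detector suite shows correctness of the event definitions, not
robustness to real-data artifacts such as drift, vignetting or cell-scale
texture.

## Ensemble statistics

Occupancy maps accumulate per-site event counts over runs (sub-pixel events
bin to the nearest site).  Both the occupancy and the property map are
smoothed with an isotropic Gaussian (sigma = the quoted radius, reflecting
boundaries, sum-preserving) before a Spearman rank correlation over sites;
curves report mean +/- SEM (sd/sqrt(n)) over runs for radii {1, 2, 4, 8,
16}, "intermediate" meaning 4.  The Voronoi statistic clips the diagram of a
seed set to the lattice rectangle, samples its edges at 0.25-site
resolution, and compares the mean tip-to-edge distance with a uniform
re-placement null (one-sided, add-one-corrected permutation p-value).

## Reduced problem sizes

Shipped fixtures use 60x60 lattices and ensembles of 6-40 runs (the
reference setups are 100x100 with hundreds to a thousand runs); run lengths
are chosen so each experiment covers its full developmental transient plus
an established-pattern phase.  These sizes are the package defaults for a
complete analysis on a single CPU; all are overridable.

## Known limitations

- The two *Dictyostelium* models depend on many constants that are not in
  the source text; the shipped reconstructions reproduce the qualitative
  regime structure (wave relay, rotor formation, the developmental-path
  regime sequence) but not necessarily the original pattern geometry.  In
  particular, the clean anticorrelation between clustered pacemaker layouts
  and spiral-tip occupancy, and the Voronoi-edge alignment of tips around
  effective pacemakers, are weak or unstable in this reconstruction: tip
  occupancy here tracks overall excitation activity, which is itself
  concentrated where pacemakers are dense.  The corresponding acceptance
  tests state the target property and are expected to fail honestly where
  the reconstruction does not reproduce it.
- Explicit Euler only; stiff parameter regions of the relay model require
  smaller `dt` than the default.
- Detection assumes movies long enough to estimate a dominant period
  (roughly three oscillations).
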