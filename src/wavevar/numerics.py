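"""Shared lattice numerics for all simulators.

Fields live on a regular ``ny x nx`` lattice with spacing ``dx`` (dimensionless,
1.0 throughout the shipped model configurations).  Diffusive coupling uses
either the five-point or the equal-weight eight-point Laplacian stencil; the
boundary is zero-gradient ("no-flux") by default, with periodic wrapping
available.  Time integration is explicit forward Euler with seeded, bit-stable
randomness so that every run is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BoundaryCondition",
    "Field",
    "SpaceTimeCube",
    "InvalidFieldError",
    "NumericalBlowupError",
    "laplacian_5pt",
    "laplacian_8pt",
    "integrate_explicit",
]


class BoundaryCondition(str, Enum):
    """Lattice boundary handling: reflecting (zero-flux) or wrap-around."""

    NO_FLUX = "no_flux"
    PERIODIC = "periodic"


class InvalidFieldError(ValueError):
    """Raised when a field contains non-finite values or has a bad shape."""


class NumericalBlowupError(RuntimeError):
    """Raised when explicit integration produces non-finite values."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite value encountered at integration step {step}")


@dataclass
class Field:
    """A 2-D grid of real values (concentration, voltage, excitability, ...)."""

    values: np.ndarray
    dx: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 3:
            raise InvalidFieldError(
                f"field must be 2-D with both sides >= 3, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidFieldError("field contains non-finite values")
        if self.dx <= 0:
            raise InvalidFieldError("dx must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class SpaceTimeCube:
    """An ordered stack of frames with a time axis; the universal movie format.

    ``data`` has shape ``(n_frames, ny, nx)``; ``dt_record`` is the model time
    between stored frames.
    """

    data: np.ndarray
    dt_record: float = 1.0
    dx: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise InvalidFieldError(
                f"cube must be (n_frames, ny, nx) with >= 1 frame, got {self.data.shape}"
            )

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    def frame(self, i: int) -> Field:
        return Field(self.data[i], dx=self.dx)


def _as_values(f) -> tuple[np.ndarray, float]:
    if isinstance(f, Field):
        return f.values, f.dx
    return np.asarray(f, dtype=float), 1.0


def _pad(values: np.ndarray, bc: BoundaryCondition) -> np.ndarray:
    mode = "edge" if bc == BoundaryCondition.NO_FLUX else "wrap"
    return np.pad(values, 1, mode=mode)


def laplacian_5pt(f, bc: BoundaryCondition = BoundaryCondition.NO_FLUX, dx: float | None = None) -> np.ndarray:
    """Five-point discrete Laplacian (f[N]+f[S]+f[E]+f[W]-4f)/dx^2.

    No-flux boundaries replicate the edge value (zero normal gradient), which
    makes pure diffusion exactly mass-conserving on the lattice.
    """
    v, d = _as_values(f)
    if dx is not None:
        d = dx
    if not np.all(np.isfinite(v)):
        raise InvalidFieldError("laplacian input contains non-finite values")
    p = _pad(v, bc)
    lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * v
    return lap / (d * d)


def laplacian_8pt(f, bc: BoundaryCondition = BoundaryCondition.NO_FLUX, dx: float | None = None) -> np.ndarray:
    """Equal-weight eight-point Laplacian: sum of 8 neighbors - 8*center, / dx^2."""
    v, d = _as_values(f)
    if dx is not None:
        d = dx
    if not np.all(np.isfinite(v)):
        raise InvalidFieldError("laplacian input contains non-finite values")
    p = _pad(v, bc)
    lap = (
        p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
        + p[1:-1, :-2] + p[1:-1, 2:]
        + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:]
        - 8.0 * v
    )
    return lap / (d * d)


RHS = Callable[[float, Sequence[np.ndarray], np.random.Generator], Sequence[np.ndarray]]


def integrate_explicit(
    state: Sequence[np.ndarray],
    rhs: RHS,
    dt: float,
    n_steps: int,
    record_every: int = 1,
    seed: int = 0,
    record_index: int | None = 0,
    dx: float = 1.0,
    callback: Callable[[int, float, list[np.ndarray]], None] | None = None,
) -> SpaceTimeCube | list[SpaceTimeCube]:
    """Forward-Euler integration of ``d state / dt = rhs(t, state, rng)``.

    The initial state is always recorded; thereafter every ``record_every``
    steps.  Runs with identical ``(state, rhs, dt, seed)`` are bit-identical.
    ``record_index`` selects which state variable goes into the returned cube
    (``None`` returns one cube per variable).

    Raises
    ------
    NumericalBlowupError
        If any state variable becomes non-finite; the exception names the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    cur = [np.array(s, dtype=float) for s in state]
    records: list[list[np.ndarray]] = [[s.copy() for s in cur]]
    t = 0.0
    for step in range(1, n_steps + 1):
        derivs = rhs(t, cur, rng)
        for s, ds in zip(cur, derivs):
            s += dt * np.asarray(ds)
        t = step * dt
        if not all(np.all(np.isfinite(s)) for s in cur):
            raise NumericalBlowupError(step)
        if callback is not None:
            callback(step, t, cur)
        if step % record_every == 0:
            records.append([s.copy() for s in cur])

    def build(idx: int) -> SpaceTimeCube:
        return SpaceTimeCube(
            np.stack([r[idx] for r in records]),
            dt_record=dt * record_every,
            dx=dx,
        )

    if record_index is None:
        return [build(i) for i in range(len(cur))]
    return build(record_index)
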