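"""Chemical microenvironment: vector reaction–diffusion on a voxel mesh.

Each substrate (oxygen in mmHg, an immunostimulatory factor in arbitrary
units) lives on a shared Cartesian voxel grid, diffuses with coefficient
``D``, decays at rate ``λ``, and is exchanged with the cell agents that
sit inside each voxel. The solver is a locally-one-dimensional (LOD)
implicit splitting: one implicit decay substep followed by three implicit
1-D diffusion sweeps (tridiagonal solves along x, y, z), which is
unconditionally stable and lets desk-scale presets take larger steps
than the reference Δt_diff = 0.01 min.

Boundary condition is zero flux on the domain faces; a configurable
shell of Dirichlet nodes on the boundary (oxygen clamped at physioxia by
default) acts as the oxygen source. Dirichlet nodes are re-clamped after
every step, so they behave as continuous sources/sinks.

Positions are in µm with the origin at the domain corner; voxel indices
are 0-based with half-open voxel intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "VoxelGrid",
    "Substrate",
    "SubstrateState",
    "DirichletNodeSet",
    "step_diffusion",
    "apply_cell_exchange",
    "sample",
    "sample_gradient",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Cartesian voxel mesh with cubic voxels of edge ``dx`` µm."""

    extent: tuple[float, float, float]
    dx: float = 20.0

    def __post_init__(self) -> None:
        for e in self.extent:
            n = e / self.dx
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"extent {self.extent} is not an integer multiple of dx={self.dx}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.dx)) for e in self.extent)

    @property
    def voxel_volume(self) -> float:
        return self.dx**3

    def contains(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        ext = np.asarray(self.extent)
        return np.all((pos >= 0.0) & (pos <= ext), axis=1)

    def voxel_index(self, pos: np.ndarray) -> np.ndarray:
        """Map position(s) in µm to 0-based voxel index triples.

        Half-open voxel intervals; positions exactly on the far domain
        face are assigned to the last voxel.
        """
        pos = np.asarray(pos, dtype=float)
        single = pos.ndim == 1
        pos2 = np.atleast_2d(pos)
        ok = self.contains(pos2)
        if not np.all(ok):
            bad = pos2[~ok][0]
            raise ValueError(f"position {bad} outside domain extent {self.extent}")
        idx = np.floor(pos2 / self.dx).astype(np.int64)
        idx = np.minimum(idx, np.asarray(self.shape) - 1)
        return idx[0] if single else idx

    def centre(self, idx: np.ndarray) -> np.ndarray:
        return (np.asarray(idx, dtype=float) + 0.5) * self.dx


@dataclass
class Substrate:
    """One diffusing chemical species."""

    name: str
    diffusion: float  # µm²/min
    decay: float  # 1/min
    conc: np.ndarray  # (nx, ny, nz)

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.conc)):
            bad = np.argwhere(~np.isfinite(self.conc))[0]
            raise FloatingPointError(
                f"non-finite concentration in substrate {self.name!r} "
                f"at voxel {tuple(bad)}"
            )


@dataclass
class SubstrateState:
    """Named collection of substrates on one grid."""

    substrates: list[Substrate]

    def __getitem__(self, name: str) -> Substrate:
        for s in self.substrates:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.substrates]

    @classmethod
    def uniform(
        cls, grid: VoxelGrid, specs: list[tuple[str, float, float, float]]
    ) -> "SubstrateState":
        """Build from (name, D, decay, initial value) tuples."""
        subs = [
            Substrate(name, D, lam, np.full(grid.shape, c0, dtype=float))
            for name, D, lam, c0 in specs
        ]
        return cls(subs)


@dataclass
class DirichletNodeSet:
    """Voxels whose substrate value is clamped after every step.

    ``nodes[name]`` is a pair (flat voxel indices, clamped values).
    """

    nodes: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add(self, name: str, flat_index: np.ndarray, values: np.ndarray) -> None:
        flat_index = np.asarray(flat_index, dtype=np.int64).ravel()
        values = np.broadcast_to(np.asarray(values, dtype=float), flat_index.shape).copy()
        if name in self.nodes:
            old_i, old_v = self.nodes[name]
            flat_index = np.concatenate([old_i, flat_index])
            values = np.concatenate([old_v, values])
        self.nodes[name] = (flat_index, values)

    @classmethod
    def boundary_shell(
        cls, grid: VoxelGrid, name: str, value: float
    ) -> "DirichletNodeSet":
        """Clamp every voxel on the six domain faces to ``value``."""
        nx, ny, nz = grid.shape
        mask = np.zeros((nx, ny, nz), dtype=bool)
        mask[0, :, :] = mask[-1, :, :] = True
        mask[:, 0, :] = mask[:, -1, :] = True
        mask[:, :, 0] = mask[:, :, -1] = True
        flat = np.flatnonzero(mask.ravel())
        ds = cls()
        ds.add(name, flat, np.full(flat.shape, value))
        return ds

    def apply(self, state: SubstrateState) -> None:
        for name, (flat, vals) in self.nodes.items():
            sub = state[name]
            sub.conc.ravel()[flat] = vals


def _sweep_axis(conc: np.ndarray, axis: int, alpha: float) -> np.ndarray:
    """One implicit 1-D diffusion sweep (I − α·Lap_axis)c' = c, zero flux.

    α = D·dt/dx². The tridiagonal system is symmetric with zero column
    sums at λ=0, so each sweep conserves total mass exactly.
    """
    if alpha == 0.0:
        return conc
    c = np.moveaxis(conc, axis, 0)
    n = c.shape[0]
    if n == 1:
        return conc
    flat = c.reshape(n, -1)
    ab = np.zeros((3, n))
    ab[0, 1:] = -alpha
    ab[2, :-1] = -alpha
    ab[1, :] = 1.0 + 2.0 * alpha
    ab[1, 0] = 1.0 + alpha  # zero-flux ends
    ab[1, -1] = 1.0 + alpha
    out = solve_banded((1, 1), ab, flat, overwrite_b=False, check_finite=False)
    return np.moveaxis(out.reshape(c.shape), 0, axis)


def step_diffusion(
    state: SubstrateState,
    grid: VoxelGrid,
    dirichlet: DirichletNodeSet | None,
    dt: float,
) -> SubstrateState:
    """Advance every substrate one implicit diffusion+decay step (in place).

    Decay is applied as a single implicit factor 1/(1+λ·dt) (so pure
    decay with D=0 matches that closed form exactly), followed by the
    three LOD diffusion sweeps. Dirichlet voxels are re-clamped last.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for sub in state.substrates:
        sub.check_finite()
        c = sub.conc
        if sub.decay:
            c = c / (1.0 + sub.decay * dt)
        alpha = sub.diffusion * dt / grid.dx**2
        for axis in range(3):
            c = _sweep_axis(c, axis, alpha)
        sub.conc = np.ascontiguousarray(c)
        sub.check_finite()
    if dirichlet is not None:
        dirichlet.apply(state)
    return state


def apply_cell_exchange(
    state: SubstrateState,
    grid: VoxelGrid,
    positions: np.ndarray,
    secretion: np.ndarray,
    saturation: np.ndarray,
    uptake: np.ndarray,
    dt: float,
    cell_volume: float | np.ndarray = 2100.0,
) -> SubstrateState:
    """Exchange substrates between agents and their containing voxels.

    Per agent and substrate the voxel concentration is updated by the
    rate-limited implicit rule

        c ← (c + Δt·ρ·S·c*) / (1 + Δt·ρ·(S + U))

    with secretion rate S toward saturation value c*, uptake (sink) rate
    U, and ρ the agent's cell-volume-per-voxel-volume factor. Secretion
    pushes c toward c*, uptake is a proportional sink; both are
    positivity-preserving for any Δt. Agents sharing a voxel are applied
    sequentially.

    positions: (n, 3) µm; secretion/uptake: (n, n_substrates) 1/min;
    saturation: (n_substrates,).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    if n == 0:
        return state
    idx = grid.voxel_index(positions)  # raises for out-of-domain agents
    secretion = np.broadcast_to(np.asarray(secretion, dtype=float), (n, len(state.substrates)))
    uptake = np.broadcast_to(np.asarray(uptake, dtype=float), (n, len(state.substrates)))
    saturation = np.asarray(saturation, dtype=float)
    rho = np.broadcast_to(np.asarray(cell_volume, dtype=float), (n,)) / grid.voxel_volume
    for k, sub in enumerate(state.substrates):
        conc = sub.conc
        for a in range(n):
            s = secretion[a, k]
            u = uptake[a, k]
            if s == 0.0 and u == 0.0:
                continue
            i, j, l = idx[a]
            c = conc[i, j, l]
            conc[i, j, l] = (c + dt * rho[a] * s * saturation[k]) / (
                1.0 + dt * rho[a] * (s + u)
            )
    return state


def sample(state: SubstrateState, grid: VoxelGrid, pos: np.ndarray) -> np.ndarray:
    """Concentration vector (one value per substrate) at a position."""
    i, j, k = grid.voxel_index(np.asarray(pos, dtype=float))
    return np.array([s.conc[i, j, k] for s in state.substrates])


def sample_gradient(state: SubstrateState, grid: VoxelGrid, pos: np.ndarray) -> np.ndarray:
    """Finite-difference gradient of every substrate at a position.

    Central differences on voxel centres, one-sided at domain faces
    (exact for fields linear in the voxel-centre coordinates). Returns
    an (n_substrates, 3) array in units of concentration/µm.
    """
    idx = grid.voxel_index(np.asarray(pos, dtype=float))
    shape = grid.shape
    out = np.zeros((len(state.substrates), 3))
    for s_i, sub in enumerate(state.substrates):
        c = sub.conc
        for ax in range(3):
            i = idx[ax]
            lo = max(i - 1, 0)
            hi = min(i + 1, shape[ax] - 1)
            if hi == lo:
                continue
            sel_hi = list(idx)
            sel_lo = list(idx)
            sel_hi[ax] = hi
            sel_lo[ax] = lo
            out[s_i, ax] = (c[tuple(sel_hi)] - c[tuple(sel_lo)]) / ((hi - lo) * grid.dx)
    return out
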