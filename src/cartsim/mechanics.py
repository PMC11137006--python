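"""Off-lattice cell mechanics: overdamped motion from pairwise forces.

Cells are centre-based spheres. Each pair within range contributes a
polynomial contact force expressed directly as a velocity (unit drag
coefficient absorbed into the force constants, hence µm/min units):

* repulsion (elastic resistance to deformation) for centre separation
  d below contact, d < R_a + R_b:      C_ccr·(1 − d/(R_a+R_b))²
* adhesion in the ring up to the maximum adhesion distance,
  d < R_A_pair = 1.25·(R_a+R_b):       −C_cca·(1 − d/R_A_pair)²

Pair constants combine per-type values by geometric mean. Velocities are
summed over neighbours (plus the migration velocity for immune agents,
added by :mod:`cartsim.immune`) and positions advance by forward Euler.
Neighbour search uses a voxelised linked list on the mechanics grid
(30 µm edge), refreshed on a fixed cadence t_v.

This module is the readable reference implementation used by the unit
tests and small populations; the simulation engine runs the same update
through a fused numba kernel (cross-checked against this one in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MechanicsParams", "pairwise_force", "neighbors", "update_motion", "NeighborGrid"]


@dataclass(frozen=True)
class MechanicsParams:
    """Interaction constants and discretisation for cell mechanics."""

    mech_dx: float = 30.0  # mechanics voxel edge, µm
    dt_mech: float = 0.1  # min
    refresh_steps: int = 20  # neighbour list refresh cadence, t_v = 20·Δt_mech
    nu: float = 1.0  # force-constant unit, µm/min
    repulsion_cancer: float = 10.0  # ×ν
    repulsion_tcell: float = 5.0  # ×ν
    adhesion: float = 0.4  # ×ν
    adhesion_reach: float = 1.25  # R_A_pair = reach·(R_a+R_b)

    def __post_init__(self) -> None:
        if min(self.repulsion_cancer, self.repulsion_tcell, self.adhesion) < 0:
            raise ValueError("force constants must be >= 0")
        if self.adhesion_reach <= 1.0:
            raise ValueError("max adhesion distance must exceed contact distance")

    def repulsion_for(self, kind: np.ndarray) -> np.ndarray:
        """Per-agent repulsion constant: kind 0 = cancer, 1 = CAR T."""
        return self.nu * np.where(
            np.asarray(kind) == 0, self.repulsion_cancer, self.repulsion_tcell
        )


def pairwise_force(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    r_a: float,
    r_b: float,
    c_rep: float,
    c_adh: float,
    reach: float = 1.25,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Velocity contribution (µm/min) on agent *a* from agent *b*.

    ``c_rep``/``c_adh`` are the already-combined pair constants.
    Antisymmetric by construction. Coincident centres get a repulsive
    kick along a random unit axis (seeded ``rng``) so stacked cells
    separate deterministically under a fixed seed.
    """
    dvec = np.asarray(pos_a, dtype=float) - np.asarray(pos_b, dtype=float)
    d = float(np.linalg.norm(dvec))
    r_contact = r_a + r_b
    r_max = reach * r_contact
    if d >= r_max:
        return np.zeros(3)
    if d == 0.0:
        rng = rng or np.random.default_rng(0)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        return c_rep * u
    u = dvec / d
    f = -c_adh * (1.0 - d / r_max) ** 2
    if d < r_contact:
        f += c_rep * (1.0 - d / r_contact) ** 2
    return f * u


class NeighborGrid:
    """Voxelised linked list for fixed-radius neighbour queries."""

    def __init__(self, positions: np.ndarray, box: np.ndarray, dx: float):
        self.dx = float(dx)
        self.box = np.asarray(box, dtype=float)
        self.shape = np.maximum((self.box / self.dx).astype(int), 1)
        pos = np.atleast_2d(positions)
        self.n = pos.shape[0]
        idx = np.clip((pos / self.dx).astype(int), 0, self.shape - 1)
        self.flat = (idx[:, 0] * self.shape[1] + idx[:, 1]) * self.shape[2] + idx[:, 2]
        order = np.argsort(self.flat, kind="stable")
        self.sorted_agents = order
        ncell = int(np.prod(self.shape))
        self.cell_start = np.searchsorted(self.flat[order], np.arange(ncell + 1))

    def query(self, positions: np.ndarray, point: np.ndarray, radius: float) -> np.ndarray:
        """Indices of agents within ``radius`` of ``point`` (closed ball)."""
        if self.n == 0:
            return np.empty(0, dtype=int)
        point = np.asarray(point, dtype=float)
        reach = int(np.ceil(radius / self.dx))
        ctr = np.clip((point / self.dx).astype(int), 0, self.shape - 1)
        found = []
        pos = np.atleast_2d(positions)
        for di in range(-reach, reach + 1):
            i = ctr[0] + di
            if i < 0 or i >= self.shape[0]:
                continue
            for dj in range(-reach, reach + 1):
                j = ctr[1] + dj
                if j < 0 or j >= self.shape[1]:
                    continue
                for dk in range(-reach, reach + 1):
                    k = ctr[2] + dk
                    if k < 0 or k >= self.shape[2]:
                        continue
                    flat = (i * self.shape[1] + j) * self.shape[2] + k
                    cand = self.sorted_agents[self.cell_start[flat] : self.cell_start[flat + 1]]
                    if cand.size:
                        d = np.linalg.norm(pos[cand] - point, axis=1)
                        found.append(cand[d <= radius])
        if not found:
            return np.empty(0, dtype=int)
        return np.sort(np.concatenate(found))


def neighbors(
    positions: np.ndarray, box: np.ndarray, dx: float, point: np.ndarray, radius: float
) -> np.ndarray:
    """Agents within ``radius`` of ``point`` (closed-ball convention)."""
    return NeighborGrid(positions, box, dx).query(positions, point, radius)


def update_motion(
    positions: np.ndarray,
    radii: np.ndarray,
    kind: np.ndarray,
    params: MechanicsParams,
    dt: float,
    box: np.ndarray,
    motility: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One forward-Euler motion step for a whole population.

    Returns (new positions, velocities, number of face-clamp events).
    ``motility`` (n, 3) is added to the interaction velocity (zero for
    cancer cells and for attached immune agents — the caller zeroes it).
    Positions are clamped to the domain faces. Reference implementation,
    O(N²); the engine uses the equivalent linked-cell numba kernel.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float)).copy()
    n = pos.shape[0]
    vel = np.zeros_like(pos)
    crep = params.repulsion_for(kind)
    radii = np.asarray(radii, dtype=float)
    for a in range(n):
        for b in range(a + 1, n):
            c_rep = np.sqrt(crep[a] * crep[b])
            f = pairwise_force(
                pos[a], pos[b], radii[a], radii[b],
                c_rep, params.adhesion * params.nu, params.adhesion_reach, rng,
            )
            vel[a] += f
            vel[b] -= f
    if motility is not None:
        vel = vel + motility
    step = vel * dt
    too_far = np.linalg.norm(step, axis=1) > radii
    if np.any(too_far):
        import warnings

        warnings.warn(
            f"{int(too_far.sum())} agents moved more than one cell radius in one "
            f"mechanics step; time step may be too large",
            stacklevel=2,
        )
    new = pos + step
    box = np.asarray(box, dtype=float)
    clamped = np.clip(new, 0.0, box)
    n_clamp = int(np.any(clamped != new, axis=1).sum())
    return clamped, vel, n_clamp
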