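"""Cell cycle, death processes and volume relaxation.

The cycle is a directed graph G1 → S → G2 → M → (division → G1). Phase
exit is stochastic by default: a cell in phase P leaves it during a
cycle step of length Δt with probability Δt/T_P (memoryless, so the
realised phase duration is geometric with mean T_P). The default phase
means are those of a hepatocellular-carcinoma-like line:
T_G1 = 20.4 h, T_S = 13.6 h, T_G2 = 3.0 h, T_M = 1.6 h (38.6 h total).

Oncoprotein expression ``o`` and local oxygen scale only the G1-exit
rate: T_G1_eff = T_G1 / (o · f(O2)), where f ramps linearly from 0 at
the proliferation-arrest oxygen threshold to 1 at the saturation
threshold. A cell with o = 0 (or in arrested oxygen) never leaves G1; a
cell held by an attached CAR T-cell freezes its cycle entirely.

Death: a cell enters necrosis below the necrosis oxygen threshold with
per-step probability Δt/τ_nec (exponential waiting time), or apoptosis
when killed by a CAR T-cell. Dead cells stop cycling and secreting,
shrink toward zero volume, and are removed from the mechanics
population once below 5 % of the reference volume (they remain in the
cumulative dead count).

Volumes relax exponentially toward a target (implicit Euler, so pure
shrinkage is positivity-preserving); live cells grow toward twice the
reference volume and halve at division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CycleParams",
    "VolumeParams",
    "PHASE_G1",
    "PHASE_S",
    "PHASE_G2",
    "PHASE_M",
    "oxygen_proliferation_factor",
    "advance_cycle",
    "divide",
    "step_volume",
    "check_necrosis",
]

PHASE_G1, PHASE_S, PHASE_G2, PHASE_M = 0, 1, 2, 3

# death modes
DEATH_NONE, DEATH_APOPTOSIS, DEATH_NECROSIS = 0, 1, 2


@dataclass(frozen=True)
class CycleParams:
    """Phase means (min), oxygen response and necrosis kinetics."""

    t_g1: float = 20.4 * 60.0
    t_s: float = 13.6 * 60.0
    t_g2: float = 3.0 * 60.0
    t_m: float = 1.6 * 60.0
    dt_cycle: float = 6.0  # min
    o2_arrest: float = 5.0  # mmHg: no G1 progression below this
    o2_saturation: float = 10.0  # mmHg: full-speed proliferation at/above
    o2_necrosis: float = 5.0  # mmHg: necrosis becomes possible below
    tau_necrosis: float = 6.0 * 60.0  # min, mean waiting time at zero O2
    fixed_durations: bool = False  # deterministic phase lengths instead

    def __post_init__(self) -> None:
        if min(self.t_g1, self.t_s, self.t_g2, self.t_m) <= 0:
            raise ValueError("phase durations must be positive")
        if self.o2_saturation < self.o2_arrest:
            raise ValueError("oxygen saturation threshold below arrest threshold")

    @property
    def durations(self) -> np.ndarray:
        return np.array([self.t_g1, self.t_s, self.t_g2, self.t_m])

    @property
    def total_mean(self) -> float:
        return float(self.durations.sum())


@dataclass(frozen=True)
class VolumeParams:
    """Reference volume and relaxation rates (1/min)."""

    v_ref: float = 4.0 / 3.0 * np.pi * 8.4**3  # µm³, from R_cell = 8.4 µm
    growth_rate: float = 0.0017  # live cells, toward 2·v_ref over ~one cycle
    apoptosis_rate: float = 0.01  # shrink toward 0, gone in ~5 h
    necrosis_rate: float = 0.002  # slower shrinkage of necrotic corpses
    removal_fraction: float = 0.05  # remove corpse below this × v_ref
    nuclear_fraction: float = 0.1
    fluid_fraction: float = 0.75


def oxygen_proliferation_factor(o2, params: CycleParams) -> np.ndarray:
    """f(O2): 0 below the arrest threshold, linear ramp to 1 at saturation."""
    o2 = np.asarray(o2, dtype=float)
    width = params.o2_saturation - params.o2_arrest
    if width == 0:
        return (o2 >= params.o2_arrest).astype(float)
    return np.clip((o2 - params.o2_arrest) / width, 0.0, 1.0)


def advance_cycle(
    phase: np.ndarray,
    phase_clock: np.ndarray,
    o: np.ndarray,
    o2: np.ndarray,
    frozen: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    params: CycleParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance cycle phases for a population of live cancer cells.

    Returns (new phase, new phase clock, divide mask). ``frozen`` marks
    cells held by an attached CAR T-cell (no progression at all). The
    phase clock is only consulted in fixed-duration mode; in the default
    stochastic mode exits are memoryless.
    """
    o = np.asarray(o, dtype=float)
    if np.any((o < 0) | (o > 2)):
        raise ValueError("oncoprotein expression outside [0, 2]")
    phase = np.asarray(phase).copy()
    phase_clock = np.asarray(phase_clock, dtype=float).copy()
    active = ~np.asarray(frozen, dtype=bool)
    f = oxygen_proliferation_factor(o2, params)
    speed = np.where(phase == PHASE_G1, o * f, 1.0)  # only G1 is scaled
    durations = params.durations
    if params.fixed_durations:
        phase_clock[active] += dt * speed[active]
        exit_mask = active & (phase_clock >= durations[phase])
    else:
        p_exit = np.clip(dt * speed / durations[phase], 0.0, 1.0)
        draw = rng.random(phase.shape[0])
        exit_mask = active & (draw < p_exit)
    divide_mask = exit_mask & (phase == PHASE_M)
    phase[exit_mask] = (phase[exit_mask] + 1) % 4
    phase_clock[exit_mask] = 0.0
    return phase, phase_clock, divide_mask


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-uniform unit vectors (isotropic division axes)."""
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    small = norm[:, 0] < 1e-12
    if np.any(small):
        v[small] = [1.0, 0.0, 0.0]
        norm[small] = 1.0
    return v / norm


def divide(
    position: np.ndarray,
    volume: float,
    o: float,
    r_cell: float,
    rng: np.random.Generator,
    allowed: bool = True,
) -> tuple[tuple[np.ndarray, float, float], tuple[np.ndarray, float, float]]:
    """Split a mother cell at M exit into two daughters.

    Each daughter receives half the mother's total volume and the
    mother's oncoprotein expression exactly (no mutation at division:
    heterogeneity is assigned once at initialisation, and clonal
    expansion of high-o cells emerges from selection alone). Daughters
    are offset ±R_cell/2 along an isotropically random axis. CAR T-cells
    have zero divisions allowed and must never reach this call.
    """
    if not allowed:
        raise ValueError("division requested for an agent with n_div = 0 (CAR T-cell)")
    axis = random_unit_vectors(1, rng)[0]
    position = np.asarray(position, dtype=float)
    offset = 0.5 * r_cell * axis
    half = volume / 2.0
    return (position + offset, half, o), (position - offset, half, o)


def step_volume(
    volume: np.ndarray, target: np.ndarray, rate: np.ndarray, dt: float
) -> np.ndarray:
    """Implicit exponential relaxation V ← (V + r·Δt·V_target)/(1 + r·Δt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    volume = np.asarray(volume, dtype=float)
    rate = np.asarray(rate, dtype=float)
    target = np.asarray(target, dtype=float)
    out = (volume + rate * dt * target) / (1.0 + rate * dt)
    if np.any(out < 0):
        raise FloatingPointError("negative cell volume")
    return out


def check_necrosis(
    alive: np.ndarray,
    o2: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    params: CycleParams,
) -> np.ndarray:
    """Mask of cells entering necrosis this step (exponential waiting).

    Below the necrosis oxygen threshold a live cell dies with per-step
    probability Δt/τ_nec; necrosis is an absorbing state handled by the
    caller (dead cells are excluded from ``alive``).
    """
    alive = np.asarray(alive, dtype=bool)
    o2 = np.asarray(o2, dtype=float)
    at_risk = alive & (o2 < params.o2_necrosis)
    p = min(dt / params.tau_necrosis, 1.0)
    draw = rng.random(alive.shape[0])
    return at_risk & (draw < p)
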