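"""CAR T-cell agents: chemotaxis, adhesion, killing, exhaustion, dosing.

CAR T-cells are self-propelled. An unattached T-cell migrates with a
biased random walk toward the immunostimulatory-factor gradient secreted
by cancer cells:

    v_mig = v_mot · (b·d + (1−b)·d_r) / ‖b·d + (1−b)·d_r‖

where d is the unit vector along the local gradient, d_r a random unit
direction redrawn with probability Δt/t_per per mechanics step, and
b ∈ [0,1] the migration bias (b = 1: deterministic climb up the
gradient; b = 0: Brownian-like motion along d_r). The default random
direction is drawn by the spherical-coordinate recipe
d_r = [sin φ cos θ, sin φ sin θ, cos φ] with θ ~ U[0,π], φ ~ U[0,2π]
(note this is *not* area-uniform on the sphere; an area-uniform
alternative is available via ``uniform_sphere_directions``).

On contact (a recognisable cancer cell within R_LA = 18 µm) an adhesion
forms with probability r_a·Δt per step. While attached, the T-cell's
motility is off and the target's cycle is frozen; each step the T-cell
attempts to induce apoptosis with probability r_K·Δt·immunogenicity(o),
detaching on success or after the maximum attachment time t_a = 60 min.

Each T-cell carries a lifespan drawn once at dosing from a normal with
mean 10 days and sd 5 days truncated to positive values; exhausted
cells (age beyond lifespan) are removed from the simulation. In
long-term persistence mode the lifespan is infinite.

These functions are the readable per-agent reference implementation;
the engine runs the same decision logic inside its fused numba kernel,
and the two are cross-checked statistically in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heterogeneity import ANTIGEN_SPECIFIC, immunogenicity

__all__ = [
    "TCellParams",
    "DoseSchedule",
    "draw_random_direction",
    "resample_direction",
    "migration_velocity",
    "attempt_adhesion",
    "attempt_kill",
    "draw_lifespans",
    "check_exhaustion",
    "place_dose",
]

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class TCellParams:
    """CAR T-cell parameters (time in min, lengths in µm)."""

    v_mot: float = 2.0  # mean migration speed, µm/min
    bias: float = 0.5  # migration bias b
    t_per: float = 10.0  # persistence time, min
    r_kill: float = 0.06  # kill rate, 1/min
    t_attach_max: float = 60.0  # max attachment lifetime t_a, min
    r_adhesion: float = 0.2  # adhesion formation rate, 1/min
    r_la: float = 18.0  # max adhesion distance, µm
    lifespan_mean: float = 10.0 * MINUTES_PER_DAY
    lifespan_sd: float = 5.0 * MINUTES_PER_DAY
    long_term: bool = False  # persistence mode: infinite lifespan
    recognition_mode: str = ANTIGEN_SPECIFIC
    o_min: float = 0.5
    uniform_sphere_directions: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.bias <= 1.0):
            raise ValueError("migration bias must lie in [0, 1]")


@dataclass(frozen=True)
class DoseSchedule:
    """CAR T-cell dosing: list of (day, T-cell-to-cancer ratio).

    The ratio of the *first* dose is taken against the live cancer-cell
    count at that dose time; subsequent doses reuse the first dose's
    absolute T-cell count (equal-size doses).
    """

    doses: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        days = [d for d, _ in self.doses]
        if any(d < 0 for d in days):
            raise ValueError("dose days must be >= 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("dose days must be strictly increasing")
        if any(r <= 0 for _, r in self.doses):
            raise ValueError("dose ratios must be positive")


def draw_random_direction(
    rng: np.random.Generator, uniform_sphere: bool = False, n: int | None = None
) -> np.ndarray:
    """Random unit direction(s) d_r.

    Default reproduces the spherical-coordinate sampling with
    θ ~ U[0, π] and φ ~ U[0, 2π]; ``uniform_sphere=True`` draws
    area-uniform directions instead.
    """
    m = 1 if n is None else n
    if uniform_sphere:
        v = rng.standard_normal((m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    else:
        theta = rng.uniform(0.0, np.pi, size=m)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=m)
        v = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
            axis=1,
        )
    return v[0] if n is None else v


def resample_direction(
    d_r: np.ndarray, dt: float, rng: np.random.Generator, params: TCellParams
) -> np.ndarray:
    """With probability Δt/t_per, redraw the random direction d_r."""
    if params.t_per == np.inf:
        return d_r
    if rng.random() < dt / params.t_per:
        return draw_random_direction(rng, params.uniform_sphere_directions)
    return d_r


def migration_velocity(
    d: np.ndarray, d_r: np.ndarray, params: TCellParams, attached: bool = False
) -> np.ndarray:
    """Migration velocity of one T-cell (µm/min).

    ``d`` is the unit vector along the sampled immunostimulatory
    gradient (callers keep the previous d when the gradient is zero).
    Attached cells have zero motility. The bias blend is renormalised so
    ‖v_mig‖ = v_mot; in the degenerate case of an exactly zero blend the
    random direction is used.
    """
    if attached:
        return np.zeros(3)
    blend = params.bias * np.asarray(d, dtype=float) + (1.0 - params.bias) * np.asarray(
        d_r, dtype=float
    )
    norm = np.linalg.norm(blend)
    if norm < 1e-12:
        return params.v_mot * np.asarray(d_r, dtype=float)
    return params.v_mot * blend / norm


def attempt_adhesion(
    tcell_pos: np.ndarray,
    cancer_pos: np.ndarray,
    cancer_o: np.ndarray,
    cancer_alive: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    params: TCellParams,
) -> int:
    """One adhesion attempt for an unattached T-cell.

    Candidates are live cancer cells within R_LA, restricted in
    antigen-specific mode to o ≥ o_min. With probability r_a·Δt the
    T-cell adheres to the nearest candidate (ties broken by lowest
    index). Returns the target index, or −1 for no adhesion.
    """
    cancer_pos = np.atleast_2d(cancer_pos)
    if cancer_pos.shape[0] == 0:
        return -1
    d = np.linalg.norm(cancer_pos - np.asarray(tcell_pos, dtype=float), axis=1)
    eligible = (d <= params.r_la) & np.asarray(cancer_alive, dtype=bool)
    if params.recognition_mode == ANTIGEN_SPECIFIC:
        eligible &= np.asarray(cancer_o, dtype=float) >= params.o_min
    if not np.any(eligible):
        return -1
    if rng.random() >= params.r_adhesion * dt:
        return -1
    cand = np.flatnonzero(eligible)
    return int(cand[np.argmin(d[cand])])  # argmin returns first (lowest index) on ties


def attempt_kill(
    o_target: float,
    target_alive: bool,
    attach_clock: float,
    dt: float,
    rng: np.random.Generator,
    params: TCellParams,
) -> tuple[str, float]:
    """One kill attempt while attached; returns (outcome, new clock).

    Outcomes: ``"kill"`` (target enters apoptosis, T-cell detaches),
    ``"detach"`` (dead target or attachment timed out past t_a),
    ``"hold"`` (stay attached). Success probability per step is
    min(1, r_K·Δt·immunogenicity(o)).
    """
    if not target_alive:
        return "detach", 0.0
    clock = attach_clock + dt
    imm = float(immunogenicity(o_target, params.recognition_mode, params.o_min))
    p = min(1.0, params.r_kill * dt * imm)
    if p > 0.0 and rng.random() < p:
        return "kill", 0.0
    if clock > params.t_attach_max:
        return "detach", 0.0
    return "hold", clock


def draw_lifespans(n: int, rng: np.random.Generator, params: TCellParams) -> np.ndarray:
    """Lifespans (min): N(mean, sd) truncated to > 0 by resampling.

    Long-term persistence mode returns +inf (cells last the whole run).
    """
    if params.long_term:
        return np.full(n, np.inf)
    out = rng.normal(params.lifespan_mean, params.lifespan_sd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(params.lifespan_mean, params.lifespan_sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def check_exhaustion(age: np.ndarray, lifespan: np.ndarray) -> np.ndarray:
    """Alive mask: a T-cell is removed once its age exceeds its lifespan."""
    return np.asarray(age, dtype=float) <= np.asarray(lifespan, dtype=float)


def place_dose(
    n: int,
    box: np.ndarray,
    cancer_pos: np.ndarray,
    r_cell: float,
    rng: np.random.Generator,
    max_tries: int = 10000,
) -> np.ndarray:
    """Positions for a dose: uniform in free space outside the organoid.

    Points are drawn uniformly in the domain and rejected inside the
    organoid's bounding sphere (about the live-cell centre of mass)
    inflated by one cell diameter, so administered T-cells reach the
    organoid through its exposed surface with no privileged direction.
    """
    box = np.asarray(box, dtype=float)
    cancer_pos = np.atleast_2d(cancer_pos)
    if cancer_pos.shape[0]:
        com = cancer_pos.mean(axis=0)
        r_excl = float(np.max(np.linalg.norm(cancer_pos - com, axis=1))) + 2.0 * r_cell
    else:
        com = box / 2.0
        r_excl = 0.0
    out = np.empty((n, 3))
    filled = 0
    for _ in range(max_tries):
        need = n - filled
        if need == 0:
            break
        draw = rng.uniform(0.0, 1.0, size=(2 * need + 8, 3)) * box
        ok = np.linalg.norm(draw - com, axis=1) > r_excl
        good = draw[ok][:need]
        out[filled : filled + good.shape[0]] = good
        filled += good.shape[0]
    if filled < n:
        raise RuntimeError(
            "could not place dose outside the organoid bounding sphere; "
            "organoid may fill the whole domain"
        )
    return out
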