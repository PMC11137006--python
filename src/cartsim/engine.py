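"""Simulation driver: the three-clock time hierarchy.

Per cell-cycle step (Δt_cycle = 6 min): dosing checks, stochastic phase
transitions and divisions, necrosis checks, volume relaxation, corpse
removal and metrics. Nested inside, per mechanics step (Δt_mech):
pairwise forces, CAR T-cell migration/adhesion/kill/exhaustion and the
position update, with the neighbour list refreshed every t_v. Nested
inside that, per diffusion step (Δt_diff): the implicit LOD
reaction–diffusion update plus per-agent secretion/uptake and Dirichlet
re-clamping.

Runs are bitwise reproducible for a fixed (config, seed): the master
seed spawns independent streams for initial sampling, dose placement,
cycle decisions and the fused mechanics/immune kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .config import ExperimentConfig
from .cycle import (
    advance_cycle,
    check_necrosis,
    random_unit_vectors,
    step_volume,
)
from .heterogeneity import MULTI_ANTIGEN, classify_type, sample_oncoprotein
from .immune import draw_lifespans, draw_random_direction, place_dose
from .microenvironment import DirichletNodeSet, VoxelGrid

__all__ = ["Population", "RunResult", "seed_organoid", "run"]

log = logging.getLogger("cartsim")

KIND_CANCER, KIND_TCELL = 0, 1
STATUS_LIVE, STATUS_APOPTOTIC, STATUS_NECROTIC, STATUS_GONE = 0, 1, 2, 3
MINUTES_PER_DAY = 1440.0

_VEC_FIELDS = ("pos", "vel", "d_dir", "d_r")
_FIELDS = (
    "id", "kind", "status", "pos", "vel", "radius", "volume", "o", "phase",
    "phase_clock", "n_attackers", "d_dir", "d_r", "attach", "attach_clock",
    "age", "lifespan", "kills", "dose_idx",
)


class Population:
    """Structure-of-arrays container for all agents (cancer + CAR T).

    Arrays are over-allocated (geometric growth) so per-step division
    batches append in amortised O(1); every public field is a view of
    length ``len(self)``.
    """

    def __init__(self, n: int, capacity: int | None = None):
        cap = max(capacity or 0, n, 16)
        self._n = n
        self._store: dict[str, np.ndarray] = {}
        for f, dtype, fill in (
            ("id", np.int64, 0),
            ("kind", np.int8, 0),
            ("status", np.int8, 0),
            ("radius", float, 0.0),
            ("volume", float, 0.0),
            ("o", float, 0.0),
            ("phase", np.int8, 0),
            ("phase_clock", float, 0.0),
            ("n_attackers", np.int64, 0),
            ("attach", np.int64, -1),
            ("attach_clock", float, 0.0),
            ("age", float, 0.0),
            ("lifespan", float, np.inf),
            ("kills", np.int64, 0),
            ("dose_idx", np.int64, -1),
        ):
            self._store[f] = np.full(cap, fill, dtype=dtype)
        for f in _VEC_FIELDS:
            self._store[f] = np.zeros((cap, 3))

    def __len__(self) -> int:
        return self._n

    def __getattr__(self, name: str):
        store = object.__getattribute__(self, "_store")
        if name in store:
            return store[name][: self._n]
        raise AttributeError(name)

    def __setattr__(self, name: str, value) -> None:
        if name.startswith("_"):
            object.__setattr__(self, name, value)
        else:
            self._store[name][: self._n] = value

    def _grow_to(self, need: int) -> None:
        cap = self._store["id"].shape[0]
        if need <= cap:
            return
        new_cap = max(need, int(cap * 1.5) + 16)
        for f, arr in self._store.items():
            shape = (new_cap, 3) if arr.ndim == 2 else (new_cap,)
            new = np.zeros(shape, dtype=arr.dtype)
            if f in ("attach", "dose_idx"):
                new[...] = -1
            elif f == "lifespan":
                new[...] = np.inf
            new[: self._n] = arr[: self._n]
            self._store[f] = new

    def append(self, other: "Population") -> None:
        m = len(other)
        self._grow_to(self._n + m)
        for f, arr in self._store.items():
            arr[self._n : self._n + m] = getattr(other, f)
        self._n += m

    def compact(self, keep: np.ndarray) -> None:
        """Drop agents where ``keep`` is False, remapping attachments."""
        n_new = int(keep.sum())
        remap = np.full(self._n, -1, dtype=np.int64)
        remap[keep] = np.arange(n_new)
        attach = self._store["attach"][: self._n]
        attach[:] = np.where(attach >= 0, remap[np.clip(attach, 0, None)], -1)
        for arr in self._store.values():
            arr[:n_new] = arr[: self._n][keep]
        self._n = n_new

    # -- views ----------------------------------------------------------
    def live_cancer(self) -> np.ndarray:
        return (self.kind == KIND_CANCER) & (self.status == STATUS_LIVE)

    def live_tcell(self) -> np.ndarray:
        return (self.kind == KIND_TCELL) & (self.status == STATUS_LIVE)

    def snapshot_frame(self) -> pd.DataFrame:
        """Point-cloud table consumable by standard particle viewers."""
        present = self.status < STATUS_GONE
        kind = self.kind[present]
        o = self.o[present]
        type_label = np.zeros(o.shape[0], dtype=int)
        cancer = kind == KIND_CANCER
        type_label[cancer] = classify_type(np.clip(o[cancer], 0.0, 2.0))
        return pd.DataFrame(
            {
                "id": self.id[present],
                "kind": np.where(cancer, "cancer", "car_t"),
                "type_label": type_label,
                "x_um": self.pos[present, 0],
                "y_um": self.pos[present, 1],
                "z_um": self.pos[present, 2],
                "radius_um": self.radius[present],
                "oncoprotein": o,
                "phase": self.phase[present],
                "alive_flag": (self.status[present] == STATUS_LIVE).astype(int),
            }
        )


@dataclass
class RunResult:
    """Metrics series, per-T-cell kill ledger and run diagnostics."""

    metrics: pd.DataFrame
    kill_ledger: pd.DataFrame
    config: ExperimentConfig
    counters: dict[str, int]
    kills_by_type: np.ndarray  # attributed kills per target type 1..4
    administered: list[int]
    snapshots: dict[float, pd.DataFrame] = field(default_factory=dict)
    fields: dict[str, np.ndarray] = field(default_factory=dict)
    final: Population | None = None


def seed_organoid(
    n_cells: int,
    r_cell: float,
    box: np.ndarray,
    rng: np.random.Generator,
    jitter: float = 0.23,
) -> np.ndarray:
    """Positions of a spherical organoid centred in the domain.

    Cells sit on a jittered face-centred-cubic lattice at contact
    spacing 2·R_cell, trimmed outermost-first to exactly ``n_cells``.
    The small jitter (±0.23 µm per axis) breaks lattice symmetry while
    keeping the minimum pairwise separation above 1.8·R_cell.
    """
    box = np.asarray(box, dtype=float)
    spacing = r_cell * np.sqrt(2.0)  # FCC: nearest-neighbour distance 2·R_cell
    # generous half-width in lattice units for the target count
    half = int(np.ceil((n_cells * 8.0 / (np.pi / 6)) ** (1 / 3) / 2)) + 2
    r = np.arange(-half, half + 1)
    i, j, k = np.meshgrid(r, r, r, indexing="ij")
    mask = (i + j + k) % 2 == 0
    pts = np.stack([i[mask], j[mask], k[mask]], axis=1) * spacing
    d = np.linalg.norm(pts, axis=1)
    order = np.argsort(d, kind="stable")
    if order.shape[0] < n_cells:
        raise RuntimeError("lattice too small for requested organoid")
    pts = pts[order[:n_cells]]
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    centre = box / 2.0
    pts = pts + centre
    if np.any(pts < 0) or np.any(pts > box):
        raise ValueError(
            f"organoid of {n_cells} cells does not fit the domain {tuple(box)}"
        )
    return pts


def _init_population(cfg: ExperimentConfig, rng: np.random.Generator) -> Population:
    n = cfg.organoid_cells
    p = Population(n)
    p.id = np.arange(n, dtype=np.int64)
    p.pos = seed_organoid(n, cfg.r_cell, np.asarray(cfg.box), rng)
    p.radius = np.full(n, cfg.r_cell)
    p.volume = np.full(n, cfg.volume.v_ref)
    p.o = sample_oncoprotein(n, rng, cfg.oncoprotein)
    durations = cfg.cycle.durations
    p.phase = rng.choice(4, size=n, p=durations / durations.sum()).astype(np.int8)
    return p


def _radius_from_volume(v: np.ndarray) -> np.ndarray:
    return (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)


def run(
    cfg: ExperimentConfig,
    save_snapshots: bool = False,
    keep_final: bool = False,
    progress: bool = False,
) -> RunResult:
    """Execute one full simulation and collect metrics.

    Raises RuntimeError with the simulation time in the message if the
    solver reports non-finite concentrations (instability diagnostic).
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_place, s_cycle, s_kernel = ss.spawn(4)
    rng_init = np.random.default_rng(s_init)
    rng_place = np.random.default_rng(s_place)
    rng_cycle = np.random.default_rng(s_cycle)
    _kernels.seed_kernel_rng(int(s_kernel.generate_state(1)[0] % (2**31)))

    grid = VoxelGrid(cfg.box, cfg.grid_dx)
    names = [s.name for s in cfg.substrates]
    if "oxygen" not in names or "immunostimulatory" not in names:
        raise ValueError("config must define 'oxygen' and 'immunostimulatory' substrates")
    i_o2 = names.index("oxygen")
    i_if = names.index("immunostimulatory")
    conc = np.stack(
        [np.full(grid.shape, s.initial, dtype=float) for s in cfg.substrates]
    )
    sub_diffusion = np.array([s.diffusion for s in cfg.substrates])
    sub_decay = np.array([s.decay for s in cfg.substrates])
    # flat Dirichlet-node arrays (boundary shells), grouped per substrate
    dir_start = [0]
    dir_i: list[np.ndarray] = []
    dir_j: list[np.ndarray] = []
    dir_k: list[np.ndarray] = []
    dir_val: list[np.ndarray] = []
    ny, nz = grid.shape[1], grid.shape[2]
    for s in cfg.substrates:
        if s.dirichlet_boundary is not None:
            shell = DirichletNodeSet.boundary_shell(grid, s.name, s.dirichlet_boundary)
            flat, vals = shell.nodes[s.name]
            dir_i.append(flat // (ny * nz))
            dir_j.append((flat // nz) % ny)
            dir_k.append(flat % nz)
            dir_val.append(vals)
            dir_start.append(dir_start[-1] + flat.shape[0])
        else:
            dir_start.append(dir_start[-1])
    dir_start = np.asarray(dir_start, dtype=np.int64)
    dir_i = np.concatenate(dir_i) if dir_i else np.empty(0, dtype=np.int64)
    dir_j = np.concatenate(dir_j) if dir_j else np.empty(0, dtype=np.int64)
    dir_k = np.concatenate(dir_k) if dir_k else np.empty(0, dtype=np.int64)
    dir_val = np.concatenate(dir_val) if dir_val else np.empty(0)
    # clamp the initial field too
    for s in range(len(cfg.substrates)):
        for m in range(dir_start[s], dir_start[s + 1]):
            conc[s, dir_i[m], dir_j[m], dir_k[m]] = dir_val[m]
    conc_o2 = conc[i_o2]
    conc_if = conc[i_if]
    gshape = np.asarray(grid.shape)

    pop = _init_population(cfg, rng_init)
    box = np.asarray(cfg.box, dtype=float)

    mech = cfg.mechanics
    tc = cfg.tcell
    multi = tc.recognition_mode == MULTI_ANTIGEN
    n_mech = int(round(cfg.dt_cycle / cfg.dt_mech))
    n_diff = max(
        1, int(round(cfg.dt_mech * cfg.field_subcycle_fraction / cfg.dt_diff))
    )
    n_cycle_steps = int(round(cfg.t_total / cfg.dt_cycle))

    counters = np.zeros(8, dtype=np.int64)
    kills_by_type = np.zeros(4, dtype=np.int64)
    cum_necrosis = 0
    next_id = len(pop)
    dose_given = [False] * len(cfg.dose.doses)
    first_dose_n: int | None = None
    administered: list[int] = []
    removed_ledger: list[tuple[int, int, int, float]] = []
    removed_kills_by_dose = [0] * max(len(cfg.dose.doses), 1)

    metrics_rows: list[dict] = []
    snapshots: dict[float, pd.DataFrame] = {}
    n_doses = len(cfg.dose.doses)

    def kills_per_dose() -> list[int]:
        out = list(removed_kills_by_dose[:n_doses]) if n_doses else []
        for d in range(n_doses):
            out[d] += int(pop.kills[pop.dose_idx == d].sum())
        return out

    def record(t: float) -> None:
        lc = pop.live_cancer()
        n_live = int(lc.sum())
        o_live = pop.o[lc]
        fracs = np.zeros(4)
        if n_live:
            lbl = classify_type(o_live)
            fracs = np.bincount(lbl - 1, minlength=4) / n_live
        row = {
            "time_min": t,
            "time_day": t / MINUTES_PER_DAY,
            "n_cancer_live": n_live,
            "n_dead_cum": int(counters[2]) + cum_necrosis,
            "n_killed_cum": int(counters[2]),
            "n_necrotic_cum": cum_necrosis,
            "mean_oncoprotein": float(o_live.mean()) if n_live else np.nan,
            "frac_type1": fracs[0],
            "frac_type2": fracs[1],
            "frac_type3": fracs[2],
            "frac_type4": fracs[3],
            "n_tcell_live": int(pop.live_tcell().sum()),
            "n_tcell_administered": int(sum(administered)),
        }
        for d, kk in enumerate(kills_per_dose()):
            row[f"kills_dose{d}"] = kk
        metrics_rows.append(row)
        if save_snapshots:
            snapshots[t] = pop.snapshot_frame()

    def administer(dose_i: int, ratio: float, t: float) -> None:
        nonlocal first_dose_n, next_id
        n_live = int(pop.live_cancer().sum())
        n_new = first_dose_n if first_dose_n is not None else int(round(ratio * n_live))
        if first_dose_n is None:
            first_dose_n = n_new
        if n_new == 0:
            administered.append(0)
            return
        tp = Population(n_new)
        tp.id = np.arange(next_id, next_id + n_new, dtype=np.int64)
        next_id += n_new
        tp.kind = np.full(n_new, KIND_TCELL, dtype=np.int8)
        tp.pos = place_dose(
            n_new, box, pop.pos[pop.live_cancer()], cfg.r_cell, rng_place
        )
        tp.radius = np.full(n_new, cfg.r_cell)
        tp.volume = np.full(n_new, cfg.volume.v_ref)
        tp.d_r = draw_random_direction(rng_place, tc.uniform_sphere_directions, n_new)
        tp.d_dir = tp.d_r.copy()
        tp.lifespan = draw_lifespans(n_new, rng_place, tc)
        tp.dose_idx = np.full(n_new, dose_i, dtype=np.int64)
        pop.append(tp)
        administered.append(n_new)
        log.info("dose %d at day %.2f: %d CAR T-cells", dose_i, t / 1440.0, n_new)

    t = 0.0
    record(t)
    next_save = cfg.t_save
    mech_step_count = 0
    cell_list = None
    rho = None
    iterator = range(n_cycle_steps)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="cartsim", unit="cycle-step")

    sqrt_crep = None
    dirty = True

    for _ in iterator:
        # -- dosing checks ---------------------------------------------
        for d, (day, ratio) in enumerate(cfg.dose.doses):
            if not dose_given[d] and t >= day * MINUTES_PER_DAY - 1e-9:
                administer(d, ratio, t)
                dose_given[d] = True
                dirty = True

        if dirty:
            sqrt_crep = np.sqrt(mech.repulsion_for(pop.kind) * 1.0)
        rho = pop.volume / grid.voxel_volume

        # -- mechanics + diffusion substeps -----------------------------
        for m in range(n_mech):
            if dirty or mech_step_count % mech.refresh_steps == 0:
                cell_list = _kernels.build_cell_list(pop.pos, box, mech.mech_dx)
                dirty = False
            cell_start, sorted_idx, mshape = cell_list
            _kernels.mech_substep(
                pop.pos, pop.vel, pop.radius, pop.kind, pop.status, pop.o,
                sqrt_crep, mech.adhesion * mech.nu, mech.adhesion_reach,
                pop.d_dir, pop.d_r, pop.attach, pop.attach_clock, pop.age,
                pop.lifespan, pop.kills, pop.n_attackers, kills_by_type,
                box, cfg.dt_mech,
                cell_start, sorted_idx, mshape, mech.mech_dx,
                tc.v_mot, tc.bias, tc.t_per, tc.r_kill, tc.t_attach_max,
                tc.r_adhesion, tc.r_la, tc.o_min, multi,
                tc.uniform_sphere_directions,
                conc_if, cfg.grid_dx, counters,
            )
            mech_step_count += 1
            vox = np.clip(
                (pop.pos / cfg.grid_dx).astype(np.int64), 0, gshape - 1
            )
            _kernels.diffusion_block(
                conc, sub_diffusion, sub_decay, cfg.grid_dx, cfg.dt_diff, n_diff,
                dir_start, dir_i, dir_j, dir_k, dir_val,
                vox, pop.kind, pop.status, rho,
                cfg.if_saturation, cfg.if_secretion,
                cfg.o2_uptake_cancer, cfg.o2_uptake_tcell, i_o2, i_if,
            )

        t += cfg.dt_cycle
        if not np.all(np.isfinite(conc)):
            bad = np.argwhere(~np.isfinite(conc))[0]
            raise RuntimeError(
                f"non-finite concentration at t={t:.2f} min in substrate "
                f"{names[bad[0]]!r}, voxel {tuple(bad[1:])}"
            )

        # -- cycle, death, volume at Δt_cycle ---------------------------
        lc = pop.live_cancer()
        if np.any(lc):
            vox_c = np.clip(
                (pop.pos[lc] / cfg.grid_dx).astype(np.int64), 0, gshape - 1
            )
            o2_at = conc_o2[vox_c[:, 0], vox_c[:, 1], vox_c[:, 2]]
            frozen = pop.n_attackers[lc] > 0
            phase, clock, divide_mask = advance_cycle(
                pop.phase[lc], pop.phase_clock[lc], pop.o[lc], o2_at, frozen,
                cfg.dt_cycle, rng_cycle, cfg.cycle,
            )
            pop.phase[lc] = phase
            pop.phase_clock[lc] = clock

            nec = check_necrosis(
                np.ones(int(lc.sum()), dtype=bool), o2_at, cfg.dt_cycle,
                rng_cycle, cfg.cycle,
            )
            lc_idx = np.flatnonzero(lc)
            if np.any(nec):
                pop.status[lc_idx[nec]] = STATUS_NECROTIC
                cum_necrosis += int(nec.sum())
            divide_mask &= ~nec

            div_idx = lc_idx[divide_mask]
            if div_idx.size:
                axes = random_unit_vectors(div_idx.size, rng_cycle)
                off = 0.5 * cfg.r_cell * axes
                mother_pos = pop.pos[div_idx].copy()
                half_v = pop.volume[div_idx] / 2.0
                pop.pos[div_idx] = np.clip(mother_pos + off, 0.0, box)
                pop.volume[div_idx] = half_v
                nd = div_idx.size
                dgt = Population(nd)
                dgt.id = np.arange(next_id, next_id + nd, dtype=np.int64)
                next_id += nd
                dgt.pos = np.clip(mother_pos - off, 0.0, box)
                dgt.volume = half_v
                dgt.radius = _radius_from_volume(half_v)
                dgt.o = pop.o[div_idx].copy()  # daughters inherit o exactly
                pop.append(dgt)
                dirty = True

        # volume relaxation for everything still present
        present = pop.status < STATUS_GONE
        if np.any(present):
            st = pop.status[present]
            kd = pop.kind[present]
            target = np.where(
                st == STATUS_LIVE,
                np.where(kd == KIND_CANCER, 2.0 * cfg.volume.v_ref, cfg.volume.v_ref),
                0.0,
            )
            rate = np.where(
                st == STATUS_LIVE,
                cfg.volume.growth_rate,
                np.where(
                    st == STATUS_APOPTOTIC,
                    cfg.volume.apoptosis_rate,
                    cfg.volume.necrosis_rate,
                ),
            )
            pop.volume[present] = step_volume(
                pop.volume[present], target, rate, cfg.dt_cycle
            )
            pop.radius[present] = _radius_from_volume(pop.volume[present])

        # corpse + exhausted-cell removal
        corpse = (pop.status == STATUS_APOPTOTIC) | (pop.status == STATUS_NECROTIC)
        remove = (corpse & (pop.volume < cfg.volume.removal_fraction * cfg.volume.v_ref)) | (
            pop.status == STATUS_GONE
        )
        if np.any(remove):
            gone_t = remove & (pop.kind == KIND_TCELL)
            for i in np.flatnonzero(gone_t):
                removed_ledger.append(
                    (int(pop.id[i]), int(pop.dose_idx[i]), int(pop.kills[i]), t / MINUTES_PER_DAY)
                )
                removed_kills_by_dose[int(pop.dose_idx[i])] += int(pop.kills[i])
            pop.compact(~remove)
            dirty = True

        if t >= next_save - 1e-9:
            record(t)
            next_save += cfg.t_save

    # final ledger: survivors (and corpses of cancer cells are not T cells)
    rows = [
        {"tcell_id": i, "dose_index": d, "kills": k, "exhaustion_day": day}
        for (i, d, k, day) in removed_ledger
    ]
    for i in np.flatnonzero(pop.kind == KIND_TCELL):
        rows.append(
            {
                "tcell_id": int(pop.id[i]),
                "dose_index": int(pop.dose_idx[i]),
                "kills": int(pop.kills[i]),
                "exhaustion_day": np.nan,
            }
        )
    kill_ledger = pd.DataFrame(
        rows, columns=["tcell_id", "dose_index", "kills", "exhaustion_day"]
    )

    if counters[1] > 0:
        log.warning(
            "%d mechanics steps moved an agent more than one cell radius; "
            "the mechanics time step may be too large",
            int(counters[1]),
        )
    counter_names = ["face_clamps", "big_steps", "kills", "exhaustions", "coincident"]
    fields = {name: conc[i].copy() for i, name in enumerate(names)}
    return RunResult(
        metrics=pd.DataFrame(metrics_rows),
        kill_ledger=kill_ledger,
        config=cfg,
        counters={n: int(counters[i]) for i, n in enumerate(counter_names)},
        kills_by_type=kills_by_type.copy(),
        administered=administered,
        snapshots=snapshots,
        fields=fields,
        final=pop if keep_final else None,
    )
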