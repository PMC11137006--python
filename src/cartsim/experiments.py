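"""Experiment presets and the observables reported from each run.

``full_scale_config`` reproduces the reference study conditions (3963
cells, 1000³ µm, 30 days, reference time steps); a full run at that
scale is a multi-hour single-core computation. ``desk_config`` scales
domain, counts and duration together for interactive work and the test
suite. It relaxes the mechanics step to Δt_mech = 0.5 min (the
overdamped contact dynamics remain stable well beyond that — stability
bound ≈ 3 min — and all event probabilities stay ≪ 1 per step) and
advances the diffusion subcycle for a tenth of each mechanics step at
the accurate Δt_diff = 0.01 min: the fields are relaxation-type with
sub-minute time constants, so at quasi-steady state the shortened
subcycle reproduces the full hierarchy; a dedicated accuracy test
compares the first simulated hour against the reference steps.

Observables: organoid growth rate (log-linear fit of the live-cell
count), dead-cells-per-CAR-T ratio with the free-CAR-T count, and the
per-type radial distribution g(r) in spherical shells about the
organoid's centre of mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .engine import RunResult, run
from .immune import DoseSchedule

__all__ = [
    "full_scale_config",
    "desk_config",
    "growth_rate",
    "dead_per_cart",
    "radial_distribution",
    "replicate_runs",
]

MINUTES_PER_DAY = 1440.0


def full_scale_config(**overrides) -> ExperimentConfig:
    """The reference study conditions (30 days, 3963 cells, 1000³ µm)."""
    return ExperimentConfig(**overrides)


def desk_config(
    n_cells: int = 500,
    box_um: float = 300.0,
    days: float = 3.0,
    seed: int = 0,
    dose_ratio: float | None = None,
    dose_days: tuple[float, ...] = (1.0,),
    **overrides,
) -> ExperimentConfig:
    """Scaled-down preset: smaller organoid, domain and duration.

    Doses (if any) default to day 1, matching the reference protocol.
    """
    dose = DoseSchedule(
        tuple((d, dose_ratio) for d in dose_days) if dose_ratio else ()
    )
    cfg = ExperimentConfig(
        box=(box_um, box_um, box_um),
        t_total=days * MINUTES_PER_DAY,
        dt_mech=0.5,
        dt_diff=0.01,
        field_subcycle_fraction=0.1,
        organoid_cells=n_cells,
        dose=dose,
        seed=seed,
    )
    return cfg.replace(**overrides) if overrides else cfg


def growth_rate(
    metrics: pd.DataFrame, window_days: float = 5.0, column: str = "n_cancer_live"
) -> float:
    """Organoid growth rate (1/day) over a trailing window.

    Least-squares slope of ln(live cancer count) against time over the
    last ``window_days`` of the series. Returns NaN (flagged undefined)
    if any count in the window is zero or fewer than 3 save points fall
    inside the window.
    """
    t_end = metrics["time_day"].iloc[-1]
    win = metrics[metrics["time_day"] >= t_end - window_days]
    if len(win) < 3:
        raise ValueError("need at least 3 save points in the growth-rate window")
    counts = win[column].to_numpy(dtype=float)
    if np.any(counts <= 0):
        import warnings

        warnings.warn("zero cell count in growth-rate window; rate undefined", stacklevel=2)
        return float("nan")
    slope = np.polyfit(win["time_day"].to_numpy(dtype=float), np.log(counts), 1)[0]
    return float(slope)


def dead_per_cart(result: RunResult) -> tuple[float, int]:
    """(attributed kills ÷ administered CAR T-cells, free-CAR-T count).

    A "free" CAR T-cell is an administered T-cell that never killed a
    cancer cell — the proxy for off-target side-effect risk.
    """
    n_admin = int(sum(result.administered))
    if n_admin == 0:
        raise ValueError("no CAR T-cells administered")
    ledger = result.kill_ledger
    kills = int(ledger["kills"].sum())
    free = int((ledger["kills"] == 0).sum())
    return kills / n_admin, free


def radial_distribution(
    positions: np.ndarray,
    o: np.ndarray,
    kind: np.ndarray,
    status: np.ndarray,
    shell_width: float,
) -> pd.DataFrame:
    """Per-type number density g(r) in spherical shells.

    Shells of the given width are centred on the live-cancer-cell centre
    of mass; per shell the count of each type (1–4, live cancer cells
    binned by oncoprotein) and of dead cells (any death cause) is
    divided by the shell volume. CAR T-cells are excluded.
    """
    from .heterogeneity import classify_type

    positions = np.atleast_2d(positions)
    cancer = np.asarray(kind) == 0
    live = cancer & (np.asarray(status) == 0)
    dead = cancer & np.isin(np.asarray(status), (1, 2))
    if not np.any(cancer):
        raise ValueError("population contains no cancer cells")
    com = positions[live].mean(axis=0) if np.any(live) else positions[cancer].mean(axis=0)
    r = np.linalg.norm(positions - com, axis=1)
    r_max = float(r[cancer].max())
    edges = np.arange(0.0, r_max + shell_width, shell_width)
    if edges[-1] < r_max + 1e-9:
        edges = np.append(edges, edges[-1] + shell_width)
    labels = np.zeros(positions.shape[0], dtype=int)
    labels[live] = classify_type(np.clip(np.asarray(o)[live], 0.0, 2.0))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        vol = 4.0 / 3.0 * np.pi * (hi**3 - lo**3)
        in_shell = (r >= lo) & (r < hi)
        row = {"r_lo_um": lo, "r_hi_um": hi, "shell_volume_um3": vol}
        for tp in (1, 2, 3, 4):
            row[f"density_type{tp}"] = int(np.sum(in_shell & (labels == tp))) / vol
        row["density_dead"] = int(np.sum(in_shell & dead)) / vol
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_runs(
    base: ExperimentConfig, n_replicates: int, seed0: int = 0, **run_kw
) -> list[RunResult]:
    """Run ``n_replicates`` copies of a config with consecutive seeds."""
    return [run(base.replace(seed=seed0 + i), **run_kw) for i in range(n_replicates)]


def control_study(
    n_replicates: int = 3,
    n_cells: int = 500,
    days: float = 5.0,
    box_um: float = 300.0,
    seed0: int = 0,
) -> pd.DataFrame:
    """Untreated-organoid replicates: oncoprotein drift under selection.

    High-oncoprotein cells cycle faster, so clonal selection drives the
    organoid's mean expression upward from its initial value of 1.0.
    Returns one row per replicate with the fitted linear drift of the
    mean-oncoprotein series (1/day), its start/final values, and the
    trailing growth rate.
    """
    rows = []
    for res in replicate_runs(desk_config(n_cells, box_um, days), n_replicates, seed0):
        m = res.metrics
        drift = np.polyfit(m["time_day"], m["mean_oncoprotein"], 1)[0]
        rows.append(
            {
                "seed": res.config.seed,
                "mean_o_initial": m["mean_oncoprotein"].iloc[0],
                "mean_o_final": m["mean_oncoprotein"].iloc[-1],
                "mean_o_drift_per_day": drift,
                "n_final": m["n_cancer_live"].iloc[-1],
                "growth_rate_per_day": growth_rate(m, window_days=days / 2),
            }
        )
    return pd.DataFrame(rows)


def dose_scan_study(
    ratios: tuple[float, ...] = (0.25, 1.0, 2.0),
    n_replicates: int = 3,
    n_cells: int = 500,
    days: float = 12.0,
    box_um: float = 500.0,
    dose_day: float = 1.0,
    seed0: int = 0,
    field_subcycle_fraction: float = 0.04,
    t_save: float = 360.0,
    **config_overrides,
) -> pd.DataFrame:
    """Single-dose scan over T-cell-to-cancer ratios (day-1 dosing).

    Returns one row per (ratio, replicate) with the pre-exhaustion
    tumour minimum (lowest live-cancer count saved before day 10), the
    dead-cells-per-CAR-T ratio, the free-CAR-T count and the end-of-run
    growth rate and survivor mean oncoprotein. Saves default to every
    6 h so the sharp post-dose trough of a desk-scale run is resolved.
    """
    rows = []
    for ratio in ratios:
        base = desk_config(
            n_cells, box_um, days, dose_ratio=ratio, dose_days=(dose_day,),
            field_subcycle_fraction=field_subcycle_fraction, t_save=t_save,
            **config_overrides,
        )
        for res in replicate_runs(base, n_replicates, seed0):
            m = res.metrics
            pre = m[m["time_day"] < 10.0]
            dpc, free = dead_per_cart(res)
            rows.append(
                {
                    "ratio": ratio,
                    "seed": res.config.seed,
                    "n_min_pre_day10": int(pre["n_cancer_live"].min()),
                    "n_final": int(m["n_cancer_live"].iloc[-1]),
                    "dead_per_cart": dpc,
                    "free_tcells": free,
                    "administered": int(sum(res.administered)),
                    "mean_o_final": m["mean_oncoprotein"].iloc[-1],
                    "growth_rate_per_day": growth_rate(m, window_days=days / 2),
                    "type4_kills": int(res.kills_by_type[3]),
                }
            )
    return pd.DataFrame(rows)
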