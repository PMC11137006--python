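"""Artifact readers/writers: metrics, snapshots, kill ledger, manifest.

All artifacts are plain text: CSV tables whose column names carry their
units (``*_min``, ``*_um``, dimensionless otherwise), a YAML config echo
inside a JSON run manifest, and an ISO-timestamped plain-text log.
``read_metrics`` re-checks the cumulative-dead monotonicity invariant on
load and warns if a file violates it.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig, config_from_dict, config_hash, config_to_dict

__all__ = [
    "write_metrics",
    "read_metrics",
    "write_snapshot",
    "read_snapshot",
    "write_kill_ledger",
    "write_field",
    "read_field",
    "write_manifest",
    "read_manifest",
    "setup_logging",
]

_SNAPSHOT_COLUMNS = [
    "id", "kind", "type_label", "x_um", "y_um", "z_um",
    "radius_um", "oncoprotein", "phase", "alive_flag",
]


def write_metrics(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, index=False, float_format="%.12g")


def read_metrics(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed metrics file {path}: {exc}") from exc
    if "n_dead_cum" in df.columns and np.any(np.diff(df["n_dead_cum"].to_numpy()) < 0):
        warnings.warn(
            f"{path}: cumulative dead-cell count is not non-decreasing",
            stacklevel=2,
        )
    return df


def write_snapshot(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=_SNAPSHOT_COLUMNS, float_format="%.12g")


def read_snapshot(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed snapshot file {path}: {exc}") from exc
    missing = set(_SNAPSHOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot file {path} missing columns {sorted(missing)}")
    return df


def write_kill_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, index=False, float_format="%.12g")


def write_field(conc: np.ndarray, grid_dx: float, path) -> None:
    """Substrate field as a (voxel index, centre coordinates, value) CSV."""
    nx, ny, nz = conc.shape
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pd.DataFrame(
        {
            "i": i.ravel(),
            "j": j.ravel(),
            "k": k.ravel(),
            "x_um": (i.ravel() + 0.5) * grid_dx,
            "y_um": (j.ravel() + 0.5) * grid_dx,
            "z_um": (k.ravel() + 0.5) * grid_dx,
            "value": conc.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_field(path) -> np.ndarray:
    df = pd.read_csv(path)
    shape = (df["i"].max() + 1, df["j"].max() + 1, df["k"].max() + 1)
    out = np.empty(shape)
    out[df["i"], df["j"], df["k"]] = df["value"]
    return out


def write_manifest(
    cfg: ExperimentConfig,
    path,
    started: datetime.datetime | None = None,
    finished: datetime.datetime | None = None,
    extra: dict | None = None,
) -> dict:
    """Write the run manifest: config echo, seed, version, hash, times.

    A run re-launched from the manifest's config echo and seed
    reproduces the metrics bitwise.
    """
    from . import __version__

    manifest = {
        "config": config_to_dict(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "config_hash": config_hash(cfg),
        "started": started.isoformat() if started else None,
        "finished": finished.isoformat() if finished else None,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_manifest(path) -> tuple[ExperimentConfig, dict]:
    data = json.loads(Path(path).read_text())
    return config_from_dict(data["config"]), data


def setup_logging(path=None, level=logging.INFO) -> logging.Logger:
    """Plain-text log with ISO timestamps, optionally to a file."""
    logger = logging.getLogger("cartsim")
    logger.setLevel(level)
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"
    )
    handler = logging.FileHandler(path) if path else logging.StreamHandler()
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    return logger
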