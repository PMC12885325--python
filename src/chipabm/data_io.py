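"""Trajectory-table ingestion, coordinate mapping, synthetic observations
and configuration.

Observed leukocyte positions arrive as the long-format table produced by
blob-tracking software: one row per (frame, track id, x, y) detection.
Image coordinates use the microscopy convention (origin top-left, y
increasing downward, possibly in pixels); the chip frame used by the
simulator has y increasing upward, so ingestion applies the scale factor
and the axis flip explicitly.  Video frame f corresponds to simulation
time ``video_start + 2 f`` minutes (2-minute microphotograph cadence).

Spatial cells are half-open ([lo, hi)) everywhere, with the final cell
closed so the domain edge still maps to a grid square.

Because the original tracking data are not deposited, synthetic
pseudo-observations (one seeded simulation at a known theta, summarized
exactly as real data would be) stand in for them in parameter-recovery
experiments.
"""

from __future__ import annotations

import logging
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .annexin_field import AnnexinKinetics
from .chip_domain import ChipDomain, ChipGeometry, build_domain
from .errors import CoverageError, SchemaError
from .simulator import FixedParameters, ParameterVector, run_simulation
from .summary_stats import ObservedSummary, summarize_frames

logger = logging.getLogger(__name__)

_COLUMN_ALIASES = {"particle": "track_id", "track": "track_id", "id": "track_id"}
_REQUIRED = ("frame", "track_id", "x", "y")


def read_trajectories(
    path,
    geometry: ChipGeometry,
    scale: float = 1.0,
    origin: str = "top-left",
) -> pd.DataFrame:
    """Read a blob-tracking trajectory table into chip-frame coordinates.

    Parameters
    ----------
    scale : micrometers per pixel (1.0 if positions are already in um).
    origin : "top-left" (image convention; y flipped to chip frame) or
        "bottom-left" (already chip frame).

    Positions outside [0, Lx] x [0, Ly] are clipped with a logged count;
    rows with missing values are dropped and counted as malformed.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={c: _COLUMN_ALIASES.get(c, c) for c in df.columns})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory table missing columns: {missing}")
    df = df[list(_REQUIRED)].copy()
    n_raw = len(df)
    df = df.dropna()
    n_malformed = n_raw - len(df)
    if n_malformed:
        logger.warning("dropped %d malformed trajectory rows", n_malformed)
    df["x"] = df["x"].astype(float) * scale
    y = df["y"].astype(float) * scale
    if origin == "top-left":
        df["y"] = geometry.ly - y
    elif origin == "bottom-left":
        df["y"] = y
    else:
        raise ValueError(f"unknown origin convention {origin!r}")
    out_of_domain = (
        (df["x"] < 0) | (df["x"] > geometry.lx)
        | (df["y"] < 0) | (df["y"] > geometry.ly)
    ).sum()
    if out_of_domain:
        logger.warning("clipped %d out-of-domain positions", int(out_of_domain))
        df["x"] = df["x"].clip(0.0, geometry.lx)
        df["y"] = df["y"].clip(0.0, geometry.ly)
    df["frame"] = df["frame"].astype(int)
    if (df["frame"] < 0).any():
        raise SchemaError("negative frame indices in trajectory table")
    return df.reset_index(drop=True)


def position_to_square(
    x: float, y: float, domain: ChipDomain
) -> tuple[int, int]:
    """Map a chip-frame (x, y) in um to its 1-based grid square (i, j).

    Half-open cells [lo, hi); the last row/column is closed so the domain
    edge remains in-grid.  Row 1 is the top of the filmed region (largest y).
    """
    g = domain.geometry
    j = min(int(x // g.dx) + 1, domain.n_col)
    ly_model = domain.n_row * g.dy
    i = min(int((ly_model - y) // g.dy) + 1, domain.n_row)
    return max(i, 1), max(j, 1)


def trajectories_to_summary(
    traj: pd.DataFrame,
    domain: ChipDomain,
    eval_frames: np.ndarray,
) -> ObservedSummary:
    """Reduce a trajectory table to bin/quadrant counts per evaluation frame.

    Raises :class:`CoverageError` listing any requested frame absent from
    the table.
    """
    eval_frames = np.asarray(eval_frames, dtype=int)
    present = set(traj["frame"].unique())
    gaps = [int(f) for f in eval_frames if int(f) not in present]
    if gaps:
        raise CoverageError(f"evaluation frames missing from trajectories: {gaps}")
    bins = np.zeros((len(eval_frames), 10), dtype=int)
    quads = np.zeros((len(eval_frames), 9), dtype=int)
    for t, f in enumerate(eval_frames):
        sub = traj[traj["frame"] == int(f)]
        for x, y in zip(sub["x"], sub["y"]):
            i, j = position_to_square(float(x), float(y), domain)
            bins[t, domain.bin_index(j) - 1] += 1
            quads[t, domain.quadrant_index(i, j) - 1] += 1
    return ObservedSummary(eval_frames=eval_frames, bins=bins, quadrants=quads)


def make_pseudo_observations(
    theta_true: ParameterVector,
    fixed: FixedParameters,
    domain: ChipDomain,
    seed: int,
    eval_frames: np.ndarray | None = None,
) -> tuple[ObservedSummary, dict[str, Any]]:
    """Simulate once at a known theta and summarize it like observed data.

    Stands in for the unreleased video-tracking data in parameter-recovery
    experiments.  Returns the summary plus a provenance record (theta_true
    and seed) for recovery scoring.
    """
    frames = run_simulation(theta_true, fixed, domain, seed)
    summary = summarize_frames(frames, domain, eval_frames)
    provenance = {
        "theta_true": {k: float(v) for k, v in vars(theta_true).items()},
        "seed": int(seed),
        "synthetic": True,
    }
    return summary, provenance


# -- configuration ------------------------------------------------------

def load_config(path) -> tuple[ChipGeometry, FixedParameters]:
    """Load chip geometry and fixed parameters from a YAML config file.

    Recognized top-level keys: ``geometry`` (um lengths and channel
    counts), ``fixed`` (dt, horizon, video_start, lifetimes, n_tumor) and
    ``kinetics`` (k_a, d, k_xa).  Missing keys fall back to the package
    defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    geom = ChipGeometry(**(cfg.get("geometry") or {}))
    fixed_kwargs = dict(cfg.get("fixed") or {})
    if "kinetics" in cfg:
        fixed_kwargs["kinetics"] = AnnexinKinetics(**cfg["kinetics"])
    fixed = FixedParameters(**fixed_kwargs)
    return geom, fixed


def load_theta(path) -> ParameterVector:
    """Load a free-parameter vector from a JSON/YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ParameterVector(**{k: float(v) for k, v in data.items()})


def frames_to_csv(frames, path) -> None:
    """Write a frame series as long-format CSV (time, agent_type, row, col)."""
    rows = []
    for k, t in enumerate(frames.times):
        for (i, j) in frames.leukocytes[k]:
            rows.append((t, "leukocyte", i, j))
        for (i, j) in frames.tumors[k]:
            rows.append((t, "tumor", i, j))
    pd.DataFrame(rows, columns=["time", "agent_type", "row", "col"]).to_csv(
        path, index=False
    )


def build_default_domain() -> ChipDomain:
    """The reference chip domain (144 x 121 grid)."""
    return build_domain(ChipGeometry())
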