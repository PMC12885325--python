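"""Summary statistics and losses for observed or simulated frame series.

A frame series is reduced, at a fixed set of evaluation video frames
(default every 40 frames of the 720-frame video, i.e. T = 19 frames), to

* the "Bins" statistic: absolute leukocyte counts in 10 vertical column
  bands, and
* the "Quadrants" statistic: counts in the 3x3 partition of the domain.

The distances to observations are weighted/unweighted L1 norms summed over
evaluation frames:

    LossB = sum_t sum_j |f_j^sim(t) - f_j^obs(t)| * w_j
    LossQ = sum_t sum_k |n_k^sim(t) - n_k^obs(t)|

with w = (5, 1, ..., 1): the leftmost band is up-weighted so candidate
parameters are penalized for failing to drive leukocytes across the full
chamber width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chip_domain import ChipDomain
from .errors import AlignmentError, CoverageError
from .simulator import FrameSeries

N_BINS = 10
N_QUADRANTS = 9


def default_eval_frames() -> np.ndarray:
    """Video frames 0, 40, ..., 720 (T = 19)."""
    return np.arange(0, 721, 40)


def eval_frames_for(fixed, stride: int = 40, frame_minutes: float = 2.0) -> np.ndarray:
    """Evaluation video frames covered by a simulation's recording window.

    With the reference settings (horizon 2880, video_start 1440) this
    reproduces :func:`default_eval_frames`.
    """
    last = int((fixed.horizon - fixed.video_start) / frame_minutes)
    return np.arange(0, last + 1, stride)


@dataclass(frozen=True)
class LossWeights:
    """Per-bin weights of the Bins loss; bin 1 counts five-fold by default."""

    omega: tuple[float, ...] = (5.0,) + (1.0,) * 9

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.omega):
            raise ValueError("all bin weights must be positive")


@dataclass
class ObservedSummary:
    """Per-evaluation-frame bin and quadrant leukocyte counts.

    Identical container for observed and simulated data; per frame both
    statistics sum to the same total tracked-leukocyte count.
    """

    eval_frames: np.ndarray
    bins: np.ndarray       # shape (T, 10)
    quadrants: np.ndarray  # shape (T, 9)

    def __post_init__(self) -> None:
        self.eval_frames = np.asarray(self.eval_frames, dtype=int)
        self.bins = np.asarray(self.bins, dtype=int)
        self.quadrants = np.asarray(self.quadrants, dtype=int)
        t = len(self.eval_frames)
        if self.bins.shape != (t, N_BINS) or self.quadrants.shape != (t, N_QUADRANTS):
            raise ValueError("bins/quadrants shapes do not match eval_frames")
        if (self.bins < 0).any() or (self.quadrants < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.array_equal(self.bins.sum(axis=1), self.quadrants.sum(axis=1)):
            raise ValueError("per-frame bin and quadrant totals disagree")

    # -- tidy CSV round-trip -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, f in enumerate(self.eval_frames):
            for j in range(N_BINS):
                rows.append((int(f), "bins", j + 1, int(self.bins[t, j])))
            for k in range(N_QUADRANTS):
                rows.append((int(f), "quadrants", k + 1, int(self.quadrants[t, k])))
        return pd.DataFrame(rows, columns=["frame", "statistic", "cell_id", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedSummary":
        frames = np.sort(df["frame"].unique())
        bins = np.zeros((len(frames), N_BINS), dtype=int)
        quads = np.zeros((len(frames), N_QUADRANTS), dtype=int)
        pos = {int(f): t for t, f in enumerate(frames)}
        for _, r in df.iterrows():
            arr = bins if r["statistic"] == "bins" else quads
            arr[pos[int(r["frame"])], int(r["cell_id"]) - 1] = int(r["count"])
        return cls(eval_frames=frames, bins=bins, quadrants=quads)

    @classmethod
    def from_csv(cls, path) -> "ObservedSummary":
        return cls.from_frame(pd.read_csv(path))


def summarize_frames(
    frames: FrameSeries,
    domain: ChipDomain,
    eval_frames: np.ndarray | None = None,
) -> ObservedSummary:
    """Reduce a frame series to bin/quadrant counts at the evaluation frames.

    Video frame f corresponds to simulation time ``video_start +
    frame_minutes * f``; odd frames not aligned with a simulation step are
    carried forward from the latest recorded step.  Raises
    :class:`CoverageError` if a requested frame falls outside the recording.
    """
    if eval_frames is None:
        eval_frames = default_eval_frames()
    eval_frames = np.asarray(eval_frames, dtype=int)
    if len(frames.times) == 0:
        raise CoverageError("frame series is empty")
    t_max = frames.times[-1]
    bins = np.zeros((len(eval_frames), N_BINS), dtype=int)
    quads = np.zeros((len(eval_frames), N_QUADRANTS), dtype=int)
    for t, f in enumerate(eval_frames):
        t_sim = frames.video_start + frames.frame_minutes * float(f)
        if t_sim > t_max + 1e-9:
            raise CoverageError(
                f"evaluation frame {f} (t={t_sim} min) beyond last recorded "
                f"frame (t={t_max} min)"
            )
        k = frames.frame_at_or_before(t_sim + 1e-9)
        for (i, j) in frames.leukocytes[k]:
            bins[t, domain.bin_index(j) - 1] += 1
            quads[t, domain.quadrant_index(i, j) - 1] += 1
    return ObservedSummary(eval_frames=eval_frames, bins=bins, quadrants=quads)


def _check_aligned(sim: ObservedSummary, obs: ObservedSummary) -> None:
    if not np.array_equal(sim.eval_frames, obs.eval_frames):
        raise AlignmentError("summaries computed on different evaluation frames")


def loss_bins(
    sim: ObservedSummary,
    obs: ObservedSummary,
    w: LossWeights | None = None,
) -> float:
    """Weighted L1 Bins loss summed over evaluation frames."""
    _check_aligned(sim, obs)
    omega = np.asarray((w or LossWeights()).omega)
    return float((np.abs(sim.bins - obs.bins) * omega).sum())


def loss_quadrants(sim: ObservedSummary, obs: ObservedSummary) -> float:
    """Unweighted L1 Quadrants loss summed over evaluation frames."""
    _check_aligned(sim, obs)
    return float(np.abs(sim.quadrants - obs.quadrants).sum())


def _chi_squared(sim_counts: np.ndarray, obs_counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared of simulated counts against observed as expected.

    Zero-expected cells are pooled into the nearest cell with positive
    expectation; returns (statistic, p-value) with dof = cells - 1, or
    (nan, nan) when every expected count is zero.
    """
    exp = obs_counts.astype(float)
    simc = sim_counts.astype(float)
    nz = np.flatnonzero(exp > 0)
    if len(nz) == 0:
        return float("nan"), float("nan")
    pooled_exp = exp[nz].copy()
    pooled_sim = simc[nz].copy()
    for z in np.flatnonzero(exp == 0):
        target = int(np.argmin(np.abs(nz - z)))
        pooled_sim[target] += simc[z]
    stat = float(((pooled_sim - pooled_exp) ** 2 / pooled_exp).sum())
    dof = max(len(nz) - 1, 1)
    return stat, float(stats.chi2.sf(stat, dof))


def goodness_report(sim: ObservedSummary, obs: ObservedSummary) -> pd.DataFrame:
    """Per-frame chi-squared (observed counts as expected) and RMSE.

    One row per (evaluation frame, statistic) with columns ``chi2``,
    ``p_value`` and ``rmse``; frames with an all-zero observed vector are
    reported as missing (NaN).
    """
    _check_aligned(sim, obs)
    rows = []
    for t, f in enumerate(sim.eval_frames):
        for name, s, o in (
            ("bins", sim.bins[t], obs.bins[t]),
            ("quadrants", sim.quadrants[t], obs.quadrants[t]),
        ):
            chi2, p = _chi_squared(s, o)
            rmse = float(np.sqrt(np.mean((s.astype(float) - o) ** 2)))
            rows.append((int(f), name, chi2, p, rmse))
    return pd.DataFrame(rows, columns=["frame", "statistic", "chi2", "p_value", "rmse"])
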