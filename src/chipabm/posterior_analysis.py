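"""Posterior summaries: highest-density intervals/regions, delta
distributions between paired posteriors, and HDI overlap percentages.

A highest-density region (HDR) at level 1 - alpha is the smallest region
whose enclosed probability mass reaches 1 - alpha; it is the superlevel
set {theta : p(theta) >= c} of the kernel density estimate for the
threshold c at which the enclosed mass first reaches the target.  In one
dimension the region (an HDI) may be a union of disjoint intervals when
the posterior is multimodal.

Densities are Gaussian KDEs with Silverman bandwidth, evaluated on a
regular grid spanning the sample range padded by three bandwidths.
SMC populations carry importance weights; the weighted KDE is used by
default (pass ``weights=None`` for the unweighted reading).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde


@dataclass
class HDRResult:
    """A 2-D highest-density region on an evaluation grid.

    ``mask`` flags grid cells with density >= ``density_level``; ``mass``
    is the achieved enclosed probability (the smallest value >= 1 - alpha
    attainable on the grid).
    """

    alpha: float
    density_level: float
    xs: np.ndarray
    ys: np.ndarray
    density: np.ndarray  # (len(ys), len(xs))
    mask: np.ndarray
    mass: float

    def contains(self, x: float, y: float) -> bool:
        """Whether the point falls in a grid cell belonging to the region."""
        ix = int(np.clip(np.searchsorted(self.xs, x) - 1, 0, len(self.xs) - 1))
        iy = int(np.clip(np.searchsorted(self.ys, y) - 1, 0, len(self.ys) - 1))
        return bool(self.mask[iy, ix])


def _kde_1d(sample: np.ndarray, weights: np.ndarray | None) -> gaussian_kde:
    return gaussian_kde(sample, bw_method="silverman", weights=weights)


def hdi_1d(
    sample: np.ndarray,
    mass: float = 0.95,
    weights: np.ndarray | None = None,
    grid_size: int = 4096,
) -> list[tuple[float, float]]:
    """Highest-density interval(s) of a 1-D sample at the requested mass.

    Returns the smallest KDE superlevel set reaching the mass, as a list
    of (lo, hi) intervals ordered left to right (more than one for
    well-separated modes).  A degenerate sample yields a zero-width
    interval with a warning.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2 or np.ptp(sample) == 0.0:
        warnings.warn("degenerate sample; returning zero-width interval")
        v = float(sample[0]) if sample.size else float("nan")
        return [(v, v)]
    kde = _kde_1d(sample, weights)
    bw = np.sqrt(float(kde.covariance[0, 0]))
    lo, hi = sample.min() - 3 * bw, sample.max() + 3 * bw
    xs = np.linspace(lo, hi, grid_size)
    dens = kde(xs)
    dx = xs[1] - xs[0]
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order]) * dx
    total = dens.sum() * dx
    k = int(np.searchsorted(cum, mass * total, side="left"))
    level = dens[order[min(k, grid_size - 1)]]
    above = dens >= level
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(xs[start]), float(xs[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(xs[start]), float(xs[-1])))
    return intervals


def hdr_2d(
    sample: np.ndarray,
    alpha: float = 0.05,
    weights: np.ndarray | None = None,
    grid_size: int = 256,
) -> HDRResult:
    """Highest-density region of paired draws at level 1 - alpha.

    ``sample`` has shape (n, 2) with n >= 100.  The KDE is evaluated on a
    ``grid_size`` x ``grid_size`` grid over the padded sample range; the
    density threshold is the largest level whose superlevel set encloses
    at least 1 - alpha of the grid mass.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2 or sample.shape[1] != 2:
        raise ValueError("sample must have shape (n, 2)")
    if sample.shape[0] < 100:
        raise ValueError("need at least 100 paired draws")
    if np.linalg.matrix_rank(np.cov(sample.T)) < 2:
        raise np.linalg.LinAlgError(
            "rank-deficient sample; jitter the draws before KDE"
        )
    kde = gaussian_kde(sample.T, bw_method="silverman", weights=weights)
    bws = np.sqrt(np.diag(kde.covariance))
    xs = np.linspace(sample[:, 0].min() - 3 * bws[0],
                     sample[:, 0].max() + 3 * bws[0], grid_size)
    ys = np.linspace(sample[:, 1].min() - 3 * bws[1],
                     sample[:, 1].max() + 3 * bws[1], grid_size)
    xx, yy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    flat = dens.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order]) * cell
    total = flat.sum() * cell
    k = int(np.searchsorted(cum, (1.0 - alpha) * total, side="left"))
    level = float(flat[order[min(k, flat.size - 1)]])
    mask = dens >= level
    mass = float(flat[flat >= level].sum() * cell / total)
    return HDRResult(alpha=alpha, density_level=level, xs=xs, ys=ys,
                     density=dens, mask=mask, mass=mass)


@dataclass
class DeltaResult:
    """Paired differences a - b with equal-tailed credible intervals."""

    differences: np.ndarray
    ci90: tuple[float, float]
    ci95: tuple[float, float]
    zero_in_90: bool
    zero_in_95: bool


def delta_distribution(sample_a: np.ndarray, sample_b: np.ndarray) -> DeltaResult:
    """Element-wise posterior differences between two equally sized samples.

    Differences are taken by sample index (``a - b``); the 90% and 95%
    credible intervals are equal-tailed percentile intervals, each flagged
    for whether it contains zero.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have identical shapes "
                         "(subsample the larger one first)")
    d = a - b
    ci90 = tuple(np.percentile(d, [5.0, 95.0]))
    ci95 = tuple(np.percentile(d, [2.5, 97.5]))
    return DeltaResult(
        differences=d,
        ci90=(float(ci90[0]), float(ci90[1])),
        ci95=(float(ci95[0]), float(ci95[1])),
        zero_in_90=bool(ci90[0] <= 0.0 <= ci90[1]),
        zero_in_95=bool(ci95[0] <= 0.0 <= ci95[1]),
    )


def hdi_overlap(
    interval_a: tuple[float, float],
    interval_b: tuple[float, float],
) -> tuple[float, float, float]:
    """Overlap of two intervals and its percentage of each interval's width.

    Returns ``(overlap_length, pct_of_a, pct_of_b)`` with percentages on
    the 0-100 scale; disjoint intervals give (0, 0, 0).
    """
    (a_lo, a_hi), (b_lo, b_hi) = interval_a, interval_b
    if a_hi < a_lo or b_hi < b_lo:
        raise ValueError("intervals must satisfy lo <= hi")
    overlap = max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))
    pct = lambda width: 100.0 * overlap / width if width > 0 else 0.0
    return overlap, pct(a_hi - a_lo), pct(b_hi - b_lo)


def weighted_mean_sd(
    sample: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """(Weighted) posterior mean and SD of a 1-D marginal sample."""
    sample = np.asarray(sample, dtype=float)
    if weights is None:
        return float(sample.mean()), float(sample.std(ddof=0))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    m = float(np.sum(w * sample))
    return m, float(np.sqrt(np.sum(w * (sample - m) ** 2)))
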