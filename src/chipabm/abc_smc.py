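"""Likelihood-free parameter estimation by sequential Monte Carlo ABC.

The model's likelihood is intractable, so candidate parameter vectors are
judged by the distance (Bins or Quadrants loss) between summaries of one
simulated realization and the observed summaries.  Particles flow through
a strictly decreasing tolerance schedule eps_1 > ... > eps_P: population 1
is drawn from the uniform prior box by Latin hypercube sampling, later
populations resample the previous one by its importance weights, perturb
with a component-wise Gaussian kernel of scale 0.25*|theta*|, and accept
candidates whose loss is at or below the current tolerance.  Importance
weights follow the standard SMC correction

    w_p(i) = pi(theta_i) / sum_g w_{p-1}(g) * Ke(theta_i | theta_g),

with w_1 = 1.  For synthetic-data experiments an adaptive schedule is
available that sets each tolerance to a quantile of the previous
population's accepted losses.

Candidate simulations are independent; evaluation may be parallelized
(joblib) and results are deterministic in the seed and independent of the
worker count, because candidate RNG streams are keyed by candidate index
and acceptance is processed in candidate order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import norm, qmc

from .chip_domain import ChipDomain
from .errors import ConfigurationError
from .simulator import (
    PARAM_BOUNDS,
    PARAM_NAMES,
    FixedParameters,
    ParameterVector,
    run_simulation,
)
from .summary_stats import (
    LossWeights,
    ObservedSummary,
    loss_bins,
    loss_quadrants,
    summarize_frames,
)

logger = logging.getLogger(__name__)

#: Default tolerance schedules (from percentage-deviation targets of
#: 80/70/60/50%, plus ~40% for Quadrants).
DEFAULT_EPSILONS = {
    "bins": (2303.0, 2015.0, 1727.0, 1439.0),
    "quadrants": (2303.0, 2015.0, 1727.0, 1439.0, 1200.0),
}

KERNEL_SCALE = 0.25  # Gaussian perturbation SD as a fraction of |theta*|


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform prior over a box; per-parameter (min, max)."""

    names: tuple[str, ...]
    lows: tuple[float, ...]
    highs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lows) == len(self.highs)):
            raise ConfigurationError("prior box fields must have equal length")
        if any(lo >= hi for lo, hi in zip(self.lows, self.highs)):
            raise ConfigurationError("each prior interval needs min < max")

    @classmethod
    def default(cls) -> "PriorBox":
        return cls(
            names=PARAM_NAMES,
            lows=tuple(PARAM_BOUNDS[n][0] for n in PARAM_NAMES),
            highs=tuple(PARAM_BOUNDS[n][1] for n in PARAM_NAMES),
        )

    @property
    def n_dim(self) -> int:
        return len(self.names)

    def contains(self, theta: np.ndarray) -> bool:
        lo = np.asarray(self.lows)
        hi = np.asarray(self.highs)
        return bool(np.all(theta >= lo) and np.all(theta <= hi))


def lhs_sample(box: PriorBox, n: int, rng: np.random.Generator) -> np.ndarray:
    """Latin hypercube sample of n parameter vectors from the prior box.

    Per dimension, exactly one draw falls in each of the n equal strata of
    [0, 1] before the affine map theta_s = m_s + u_s * (M_s - m_s).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=box.n_dim, seed=rng)
    u = sampler.random(n)
    return qmc.scale(u, np.asarray(box.lows), np.asarray(box.highs))


def prior_density(theta: np.ndarray, box: PriorBox) -> float:
    """Uniform-box density: 1/volume inside, 0 outside."""
    if not box.contains(np.asarray(theta, dtype=float)):
        return 0.0
    volume = float(np.prod(np.asarray(box.highs) - np.asarray(box.lows)))
    return 1.0 / volume

def perturb(theta_star: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian perturbation kernel: each component ~ N(theta*_s, (0.25*|theta*_s|)^2).

    A zero component has zero kernel scale and is returned unchanged.
    """
    theta_star = np.asarray(theta_star, dtype=float)
    scale = KERNEL_SCALE * np.abs(theta_star)
    return theta_star + rng.normal(0.0, 1.0, size=theta_star.shape) * scale


def kernel_density(theta: np.ndarray, theta_prev: np.ndarray) -> float:
    """Density of the perturbation kernel Ke(theta | theta_prev).

    Product of component normals with scale 0.25*|theta_prev_s|; a zero
    component contributes a point mass (factor 1 on exact equality, else 0).
    """
    theta = np.asarray(theta, dtype=float)
    theta_prev = np.asarray(theta_prev, dtype=float)
    scale = KERNEL_SCALE * np.abs(theta_prev)
    degenerate = scale == 0.0
    if np.any(degenerate) and not np.array_equal(
        theta[degenerate], theta_prev[degenerate]
    ):
        return 0.0
    ok = ~degenerate
    if not ok.any():
        return 1.0
    return float(np.prod(norm.pdf(theta[ok], loc=theta_prev[ok], scale=scale[ok])))


def compute_weight(
    theta: np.ndarray,
    prev_thetas: np.ndarray,
    prev_weights: np.ndarray,
    box: PriorBox,
) -> float:
    """Unnormalized SMC importance weight for an accepted particle (p > 1).

    ``prev_weights`` must be normalized.  Returns 0 (with a warning) when
    the proposal is unreachable from the previous population.
    """
    denom = float(
        sum(w * kernel_density(theta, tp) for tp, w in zip(prev_thetas, prev_weights))
    )
    if denom <= 0.0:
        logger.warning("particle unreachable from previous population; weight set to 0")
        return 0.0
    return prior_density(theta, box) / denom


@dataclass
class Particle:
    """One accepted candidate: parameters, importance weight, loss, population."""

    theta: np.ndarray
    weight: float
    loss: float
    population_index: int


@dataclass
class Population:
    """Accepted particle set at one tolerance level."""

    epsilon: float
    thetas: np.ndarray      # (n_particles, S)
    weights: np.ndarray     # normalized
    losses: np.ndarray
    n_sims: int             # simulations spent to fill this population

    @property
    def acceptance_rate(self) -> float:
        return len(self.losses) / self.n_sims if self.n_sims else float("nan")

    def particles(self, population_index: int = 0) -> list[Particle]:
        return [
            Particle(theta=t, weight=float(w), loss=float(l),
                     population_index=population_index)
            for t, w, l in zip(self.thetas, self.weights, self.losses)
        ]


@dataclass(frozen=True)
class ToleranceSchedule:
    """Strictly decreasing tolerances plus the summary method they apply to."""

    epsilons: tuple[float, ...]
    method: str = "bins"

    def __post_init__(self) -> None:
        if self.method not in ("bins", "quadrants"):
            raise ConfigurationError("method must be 'bins' or 'quadrants'")
        eps = self.epsilons
        if len(eps) == 0 or any(a <= b for a, b in zip(eps, eps[1:])):
            raise ConfigurationError("tolerances must be strictly decreasing")

    @classmethod
    def default(cls, method: str) -> "ToleranceSchedule":
        return cls(epsilons=DEFAULT_EPSILONS[method], method=method)


def _candidate_rng(seed: int, pop: int, index: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one candidate simulation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(pop, index))
    )


def _systematic_resample(
    weights: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Systematic resampling of n parent indices from normalized weights."""
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, len(weights) - 1)


def smc_sampler(
    loss_fn,
    box: PriorBox,
    n_particles: int,
    seed: int,
    epsilons: tuple[float, ...] | None = None,
    n_populations: int | None = None,
    adapt_quantile: float = 0.5,
    workers: int = 1,
    acceptance_floor: float = 1e-3,
    batch_size: int | None = None,
) -> tuple[list[Population], dict]:
    """Generic ABC-SMC loop over an arbitrary loss function.

    Parameters
    ----------
    loss_fn : callable ``(theta: ndarray, rng: Generator) -> float``
        One stochastic realization's distance to the observations.
    epsilons : fixed strictly decreasing schedule, or None to adapt:
        population 1 accepts the full LHS prior sample and each later
        tolerance is the ``adapt_quantile`` quantile of the previous
        accepted losses (requires ``n_populations``).
    acceptance_floor : abort a population once it has consumed more than
        ``n_particles / acceptance_floor`` simulations.

    Returns the populations and a log dict (per-population simulation
    counts, acceptance rates and tolerances).
    """
    if (epsilons is None) == (n_populations is None):
        raise ConfigurationError("give exactly one of epsilons / n_populations")
    adaptive = epsilons is None
    n_pops = n_populations if adaptive else len(epsilons)
    proposal_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    )
    batch = batch_size or max(n_particles, 16)
    max_sims = math.ceil(n_particles / acceptance_floor)
    parallel = Parallel(n_jobs=workers) if workers != 1 else None

    populations: list[Population] = []
    log: dict = {"epsilons": [], "n_sims": [], "acceptance_rates": []}

    for p in range(1, n_pops + 1):
        if adaptive:
            eps = (
                math.inf if p == 1
                else float(np.quantile(populations[-1].losses, adapt_quantile))
            )
        else:
            eps = float(epsilons[p - 1])
        acc_thetas: list[np.ndarray] = []
        acc_losses: list[float] = []
        acc_weights: list[float] = []
        n_sims = 0
        cand_index = 0
        while len(acc_thetas) < n_particles:
            if n_sims > max_sims:
                rate = len(acc_thetas) / n_sims
                raise RuntimeError(
                    f"population {p}: acceptance rate {rate:.2e} below floor "
                    f"{acceptance_floor:.0e} after {n_sims} simulations "
                    f"(epsilon={eps:g}); loosen the schedule or raise the floor"
                )
            # --- propose a batch (sequential, seed-deterministic) -------
            if p == 1:
                cand = lhs_sample(box, batch, proposal_rng)
            else:
                prev = populations[-1]
                parents = _systematic_resample(prev.weights, batch, proposal_rng)
                cand = np.empty((batch, box.n_dim))
                for b, g in enumerate(parents):
                    theta = perturb(prev.thetas[g], proposal_rng)
                    while not box.contains(theta):
                        g2 = proposal_rng.choice(len(prev.weights), p=prev.weights)
                        theta = perturb(prev.thetas[g2], proposal_rng)
                    cand[b] = theta
            # --- evaluate (parallelizable, candidate-indexed streams) ---
            seeds = [cand_index + b for b in range(batch)]
            cand_index += batch
            if parallel is not None:
                losses = parallel(
                    delayed(loss_fn)(cand[b], _candidate_rng(seed, p, seeds[b]))
                    for b in range(batch)
                )
            else:
                losses = [
                    loss_fn(cand[b], _candidate_rng(seed, p, seeds[b]))
                    for b in range(batch)
                ]
            n_sims += batch
            # --- accept in candidate order ------------------------------
            for b in range(batch):
                if losses[b] <= eps and len(acc_thetas) < n_particles:
                    acc_thetas.append(cand[b])
                    acc_losses.append(float(losses[b]))
                    if p == 1:
                        acc_weights.append(1.0)
                    else:
                        prev = populations[-1]
                        acc_weights.append(
                            compute_weight(cand[b], prev.thetas, prev.weights, box)
                        )
        thetas = np.asarray(acc_thetas)
        weights = np.asarray(acc_weights, dtype=float)
        total = weights.sum()
        if total <= 0:
            raise RuntimeError(f"population {p}: all importance weights are zero")
        weights = weights / total
        pop = Population(
            epsilon=eps, thetas=thetas, weights=weights,
            losses=np.asarray(acc_losses), n_sims=n_sims,
        )
        populations.append(pop)
        log["epsilons"].append(eps)
        log["n_sims"].append(n_sims)
        log["acceptance_rates"].append(pop.acceptance_rate)
        logger.info(
            "population %d: epsilon=%g, %d sims, acceptance %.1f%%",
            p, eps, n_sims, 100 * pop.acceptance_rate,
        )
    return populations, log


def run_abc_smc(
    obs: ObservedSummary,
    schedule: ToleranceSchedule | None,
    n_particles: int,
    fixed: FixedParameters,
    domain: ChipDomain,
    seed: int,
    workers: int = 1,
    n_populations: int | None = None,
    adapt_quantile: float = 0.5,
    loss_weights: LossWeights | None = None,
    method: str | None = None,
    acceptance_floor: float = 1e-3,
) -> tuple[list[Population], dict]:
    """ABC-SMC over the chip simulator against observed summaries.

    One simulation realization is run per candidate theta.  Pass a
    :class:`ToleranceSchedule` for the fixed printed tolerances, or
    ``schedule=None`` with ``n_populations`` for the adaptive
    quantile schedule used in synthetic-data experiments.
    """
    if schedule is None:
        if method is None:
            raise ConfigurationError("method required when schedule is None")
        eps = None
    else:
        method = schedule.method
        eps = schedule.epsilons
    eval_frames = obs.eval_frames
    box = PriorBox.default()

    def loss_fn(theta_arr: np.ndarray, rng: np.random.Generator) -> float:
        theta = ParameterVector.from_array(theta_arr)
        frames = run_simulation(theta, fixed, domain, rng)
        sim = summarize_frames(frames, domain, eval_frames)
        if method == "bins":
            return loss_bins(sim, obs, loss_weights)
        return loss_quadrants(sim, obs)

    return smc_sampler(
        loss_fn, box, n_particles, seed,
        epsilons=eps, n_populations=n_populations,
        adapt_quantile=adapt_quantile, workers=workers,
        acceptance_floor=acceptance_floor,
    )


def populations_to_frame(populations: list[Population]) -> "pd.DataFrame":
    """Long-format table of all populations (one row per particle)."""
    import pandas as pd

    rows = []
    for p, pop in enumerate(populations, start=1):
        for k in range(len(pop.losses)):
            rows.append(
                (p, k, *pop.thetas[k], float(pop.weights[k]), float(pop.losses[k]))
            )
    cols = ["population", "particle", *PARAM_NAMES, "weight", "loss"]
    return pd.DataFrame(rows, columns=cols)
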