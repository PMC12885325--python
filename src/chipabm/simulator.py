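"""Full stochastic simulation of the chip experiment.

One run maps a free-parameter vector theta to a time series of leukocyte
positions (and live tumor positions), mirroring the filmed experiment:
tumor cells are seeded in the left chamber (split between lower and upper
half by ``k_dis``), leukocytes accrue stochastically in the rightmost half
of the right chamber at rate ``k_leu1`` and — after the delay ``t_dly`` —
on the top boundary of the left chamber at rate ``k_leu2``.  Each step of
length ``dt`` executes, in this fixed order:

    spawn -> annexin field step -> leukocyte moves (seeded shuffled order)
          -> contact interactions -> aging and death.

The simulation covers ``horizon`` minutes but the video only starts at
``video_start`` (the experiment runs 24 h before filming begins); frames
are recorded at every step from ``video_start`` on.  Runs are bit-for-bit
reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .annexin_field import AnnexinField, AnnexinKinetics, step_annexin
from .cell_agents import (
    Leukocyte,
    MovementParams,
    TumorCell,
    apply_interaction,
)
from .chip_domain import FREE, ChipDomain
from .errors import ConfigurationError, StateError

#: Free-parameter prior domains (minimum, maximum) used for validation and
#: as the uniform prior box for inference.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "k_leu1": (0.001, 0.2),
    "gamma": (100.0, 1e7),
    "lam": (0.0, 6.0),
    "k_tl": (10.0, 1e4),
    "k_dis": (0.5, 1.0),
    "k_leu2": (0.0001, 0.1),
    "t_dly": (60.0, 1440.0),
}

PARAM_NAMES = tuple(PARAM_BOUNDS)


@dataclass(frozen=True)
class ParameterVector:
    """The seven free model parameters.

    k_leu1 : leukocyte accrual rate in the right chamber, 1/min.
    gamma  : annexin sensitivity threshold (dimensionless).
    lam    : chemotactic exponent (dimensionless); 0 = isotropic walk.
    k_tl   : intensity of the leukocyte -> tumor aging interaction, min.
    k_dis  : fraction of tumor cells seeded in the lower half-chamber.
    k_leu2 : leukocyte accrual rate on the left-chamber top boundary, 1/min.
    t_dly  : onset delay for left-chamber accrual, min.
    """

    k_leu1: float
    gamma: float
    lam: float
    k_tl: float
    k_dis: float
    k_leu2: float
    t_dly: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ParameterVector":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, arr)})

    def validate(self) -> None:
        """Structural validity for simulation.

        Rates and exponents must be nonnegative and ``k_dis`` must lie in
        [0.5, 1].  Membership in the Table-2-style prior box is only
        required of prior draws and is checked by the inference layer.
        """
        for name in ("k_leu1", "gamma", "lam", "k_tl", "k_leu2", "t_dly"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"parameter {name} must be nonnegative")
        if not 0.5 <= self.k_dis <= 1.0:
            raise ConfigurationError(f"k_dis={self.k_dis} outside [0.5, 1]")

    def in_prior_box(self) -> bool:
        """Whether every component lies inside its prior domain."""
        return all(
            lo <= getattr(self, n) <= hi for n, (lo, hi) in PARAM_BOUNDS.items()
        )


@dataclass(frozen=True)
class FixedParameters:
    """Fixed simulation settings.

    ``dt = 4`` min over a ``horizon`` of 2880 min gives 720 steps; the
    video covers the second half (from ``video_start = 1440`` min).
    Lifetimes, the initial tumor count and the annexin kinetics are not
    printed in the available text and carry documented package defaults.
    """

    dt: float = 4.0
    horizon: float = 2880.0
    video_start: float = 1440.0
    l_l: float = 2880.0
    l_c: float = 5760.0
    n_tumor: int = 20
    kinetics: AnnexinKinetics = dc_field(
        default_factory=lambda: AnnexinKinetics(k_a=10.0, d=0.14, k_xa=0.0005)
    )
    annexin_scheme: str = "conservative"
    record_annexin: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if abs(self.horizon / self.dt - round(self.horizon / self.dt)) > 1e-9:
            raise ConfigurationError("horizon must be a multiple of dt")
        if not 0 <= self.video_start < self.horizon:
            raise ConfigurationError("video_start must lie in [0, horizon)")
        if self.l_l <= 0 or self.l_c <= 0:
            raise ConfigurationError("lifetimes must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))


@dataclass
class FrameSeries:
    """Recorded simulation output: per frame, time and agent squares.

    ``times`` are strictly increasing simulation times (min);
    ``video_frame(t) = (t - video_start) / frame_minutes`` with 2-minute
    video frames, so recorded steps at dt = 4 land on even video frames.
    """

    times: list[float] = dc_field(default_factory=list)
    leukocytes: list[list[tuple[int, int]]] = dc_field(default_factory=list)
    tumors: list[list[tuple[int, int]]] = dc_field(default_factory=list)
    annexin: list[np.ndarray] | None = None
    video_start: float = 1440.0
    frame_minutes: float = 2.0
    n_steps: int = 0

    def frame_at_or_before(self, t: float) -> int:
        """Index of the latest recorded frame with time <= t (carry-forward)."""
        k = int(np.searchsorted(np.asarray(self.times), t, side="right")) - 1
        if k < 0:
            raise StateError(f"no frame recorded at or before t={t}")
        return k


class SimulationState:
    """Mutable in-run state: field, agents, occupancy bookkeeping, clock."""

    def __init__(self, domain: ChipDomain, fixed: FixedParameters,
                 rng: np.random.Generator):
        self.domain = domain
        self.fixed = fixed
        self.rng = rng
        self.t = 0.0
        self.field = AnnexinField.zeros(domain)
        self.leukocytes: list[Leukocyte] = []
        self.tumors: list[TumorCell] = []
        self.tumor_by_square: dict[tuple[int, int], TumorCell] = {}
        self.tumor_count = np.zeros((domain.n_row, domain.n_col))
        # leukocyte count per square, for channel volume exclusion & spawning
        self.leu_count = np.zeros((domain.n_row, domain.n_col), dtype=np.int32)
        self.spawn_right = _spawn_squares_right(domain)
        self.spawn_left_top = _spawn_squares_left_top(domain)
        # flat boolean mask of channel-section columns (volume exclusion)
        channel = np.zeros(domain.n_col, dtype=bool)
        channel[domain.n_left:domain.n_left + domain.n_center] = True
        self.channel_col_flat = np.tile(channel, domain.n_row)

    def add_leukocyte(self, pos: tuple[int, int], age: float) -> None:
        self.leukocytes.append(Leukocyte(pos=pos, age=age))
        self.leu_count[pos[0] - 1, pos[1] - 1] += 1

    def add_tumor(self, pos: tuple[int, int]) -> None:
        cell = TumorCell(pos=pos)
        self.tumors.append(cell)
        self.tumor_by_square[pos] = cell
        self.tumor_count[pos[0] - 1, pos[1] - 1] += 1


def _half_chamber_squares(domain: ChipDomain, section: str, half: str) -> list[tuple[int, int]]:
    """Free squares of the upper or lower half of a chamber section."""
    cols = domain.section_columns(section)
    mid = domain.n_row // 2
    rows = range(1, mid + 1) if half == "upper" else range(mid + 1, domain.n_row + 1)
    return [(i, int(j)) for i in rows for j in cols
            if domain.occupancy[i - 1, j - 1] == FREE]


def place_tumor_cells(
    theta: ParameterVector,
    fixed: FixedParameters,
    domain: ChipDomain,
    rng: np.random.Generator,
) -> list[TumorCell]:
    """Seed the initial tumor cells in the left chamber.

    ``round(k_dis * n_tumor)`` cells go on uniformly random distinct free
    squares of the lower half of the left chamber, the remainder in the
    upper half.
    """
    if not 0.5 <= theta.k_dis <= 1.0:
        raise ConfigurationError(f"k_dis={theta.k_dis} outside [0.5, 1]")
    n_lower = int(round(theta.k_dis * fixed.n_tumor))
    n_upper = fixed.n_tumor - n_lower
    cells: list[TumorCell] = []
    for half, n in (("lower", n_lower), ("upper", n_upper)):
        squares = _half_chamber_squares(domain, "left", half)
        if n > len(squares):
            raise StateError(
                f"cannot place {n} tumor cells on {len(squares)} free squares "
                f"({half} half of the left chamber)"
            )
        chosen = rng.choice(len(squares), size=n, replace=False)
        cells.extend(TumorCell(pos=squares[k]) for k in chosen)
    return cells


def _spawn_squares_right(domain: ChipDomain) -> list[tuple[int, int]]:
    """Squares of the rightmost half of the right chamber."""
    cols = domain.section_columns("right")
    cols = cols[len(cols) // 2:]
    return [(i, int(j)) for i in range(1, domain.n_row + 1) for j in cols]

def _spawn_squares_left_top(domain: ChipDomain) -> list[tuple[int, int]]:
    """Top-row squares restricted to left-chamber columns."""
    return [(1, int(j)) for j in domain.section_columns("left")]


def spawn_step(state: SimulationState, theta: ParameterVector) -> None:
    """Stochastic leukocyte accrual for the current step (at most one per
    chamber): probability ``min(k_leu1 * dt, 1)`` for the right chamber and,
    once ``t >= t_dly``, ``min(k_leu2 * dt, 1)`` for the left-chamber top
    boundary.  New leukocytes draw age ~ Uniform(0, L_L).  A full chamber
    silently skips its spawn."""
    fixed, rng = state.fixed, state.rng
    attempts = [(theta.k_leu1, state.spawn_right)]
    if state.t >= theta.t_dly:
        attempts.append((theta.k_leu2, state.spawn_left_top))
    for rate, squares in attempts:
        if rng.random() >= min(rate * fixed.dt, 1.0):
            continue
        free = [q for q in squares if state.leu_count[q[0] - 1, q[1] - 1] == 0]
        if not free:
            continue  # chamber region full; spawn skipped
        q = free[rng.integers(len(free))]
        state.add_leukocyte(q, age=float(rng.uniform(0.0, fixed.l_l)))


def _move_leukocytes(state: SimulationState, mp: MovementParams) -> None:
    """Move every live leukocyte once, in seeded shuffled order, honoring
    one-leukocyte-per-channel-square volume exclusion.

    Hot path over cached flat-index neighborhoods; equivalent to
    :func:`chipabm.cell_agents.movement_probabilities` +
    :func:`chipabm.cell_agents.sample_move` (asserted by the test suite).
    """
    domain, rng = state.domain, state.rng
    n_col = domain.n_col
    a_flat = state.field.a.ravel()
    leu_flat = state.leu_count.ravel()
    channel_flat = state.channel_col_flat
    nbhds = domain.ext_neighborhoods
    gamma, lam = mp.gamma, mp.lam
    order = rng.permutation(len(state.leukocytes))
    for k in order:
        leu = state.leukocytes[k]
        i0, j0 = leu.pos
        flat0 = (i0 - 1) * n_col + (j0 - 1)
        nb = nbhds[flat0]
        # volume exclusion: occupied channel squares (other than own) leave N̄(p)
        occupied = leu_flat[nb] > 0
        if occupied.any():
            drop = occupied & channel_flat[nb] & (nb != flat0)
            if drop.any():
                nb = nb[~drop]
        weights = np.power(a_flat[nb], lam) if lam != 0.0 else np.ones(len(nb))
        ta = weights.sum()
        if ta <= 0.0:
            probs = np.full(len(nb), 1.0 / len(nb))
        else:
            p_mt = np.exp(-gamma * ta)
            probs = p_mt / len(nb) + (1.0 - p_mt) * weights / ta
        new_flat = int(nb[np.searchsorted(np.cumsum(probs), rng.random(),
                                          side="right").clip(0, len(nb) - 1)])
        if new_flat != flat0:
            leu_flat[flat0] -= 1
            leu_flat[new_flat] += 1
            leu.pos = (new_flat // n_col + 1, new_flat % n_col + 1)


def _apply_contacts(state: SimulationState, theta: ParameterVector) -> None:
    """Each leukocyte co-occupying a live tumor cell's square applies one
    interaction (every step of co-occupancy counts as a contact)."""
    order = state.rng.permutation(len(state.leukocytes))
    for k in order:
        cell = state.tumor_by_square.get(state.leukocytes[k].pos)
        if cell is not None and cell.alive:
            apply_interaction(cell, theta.k_tl, state.fixed.l_c)


def _age_and_reap(state: SimulationState) -> None:
    fixed = state.fixed
    survivors = []
    for leu in state.leukocytes:
        leu.age += fixed.dt
        if leu.age > fixed.l_l:
            leu.alive = False
            state.leu_count[leu.pos[0] - 1, leu.pos[1] - 1] -= 1
        else:
            survivors.append(leu)
    state.leukocytes = survivors
    live_tumors = []
    for cell in state.tumors:
        cell.age_c += fixed.dt
        if cell.age_c > fixed.l_c:
            cell.alive = False
            del state.tumor_by_square[cell.pos]
            state.tumor_count[cell.pos[0] - 1, cell.pos[1] - 1] -= 1
        else:
            live_tumors.append(cell)
    state.tumors = live_tumors


def run_simulation(
    theta: ParameterVector,
    fixed: FixedParameters,
    domain: ChipDomain,
    seed: int | np.random.Generator,
) -> FrameSeries:
    """Run one realization of the model and return the recorded frames.

    Validates theta against the prior domains, seeds all randomness from
    ``seed``, executes ``horizon / dt`` steps and records every step from
    ``video_start`` on (including the state at ``video_start`` itself).
    """
    theta.validate()
    fixed.kinetics.check_stability(domain, fixed.dt)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = SimulationState(domain, fixed, rng)
    for cell in place_tumor_cells(theta, fixed, domain, rng):
        state.add_tumor(cell.pos)
    mp = MovementParams(gamma=theta.gamma, lam=theta.lam)
    frames = FrameSeries(
        video_start=fixed.video_start,
        annexin=[] if fixed.record_annexin else None,
        n_steps=fixed.n_steps,
    )

    def record() -> None:
        frames.times.append(state.t)
        frames.leukocytes.append([leu.pos for leu in state.leukocytes])
        frames.tumors.append([c.pos for c in state.tumors])
        if frames.annexin is not None:
            frames.annexin.append(state.field.a.copy())

    if fixed.video_start == 0.0:
        record()
    for _ in range(fixed.n_steps):
        spawn_step(state, theta)
        state.field = step_annexin(
            state.field, state.tumor_count, fixed.kinetics, domain,
            fixed.dt, scheme=fixed.annexin_scheme,
        )
        _move_leukocytes(state, mp)
        _apply_contacts(state, theta)
        _age_and_reap(state)
        state.t += fixed.dt
        if state.t >= fixed.video_start:
            record()
    return frames
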