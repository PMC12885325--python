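"""Leukocyte and tumor-cell agents: movement law and contact interaction.

A leukocyte at square p moves within its extended Moore neighborhood
N̄(p) = N(p) ∪ {p} (admissible squares only: in-grid, non-obstacle).  The
probability of an isotropic step is

    P_MT = exp(-gamma * TA),     TA = sum_{q in N̄(p)} A(q)^lambda,

and the probability of landing on square q is

    P(q) = P_MT / |N̄(p)| + (1 - P_MT) * A(q)^lambda / TA,

which sums to 1 over N̄(p).  ``gamma`` sets the annexin sensitivity
threshold (larger gamma -> chemotaxis kicks in at lower concentrations)
and ``lambda`` the strength of the bias toward higher concentrations;
``lambda = 0`` gives an exact isotropic random walk (with the 0^0 = 1
convention so a zero field raises no error).

When a leukocyte lands on a live tumor cell's square, the tumor cell's
biological age advances by

    age_c := age_c + k_TL * (age_c / L_c + 1),

so older cells receive larger increments and die sooner (death at
age_c > L_c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annexin_field import AnnexinField
from .chip_domain import ChipDomain
from .errors import ConfigurationError, StateError


@dataclass
class Leukocyte:
    """A leukocyte agent: grid square, age (min) and live flag."""

    pos: tuple[int, int]
    age: float
    alive: bool = True


@dataclass
class TumorCell:
    """A tumor-cell agent: grid square, biological age (min) and live flag."""

    pos: tuple[int, int]
    age_c: float = 0.0
    alive: bool = True


@dataclass(frozen=True)
class MovementParams:
    """Chemotactic movement parameters gamma (threshold) and lambda (bias)."""

    gamma: float
    lam: float

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.lam < 0:
            raise ConfigurationError("gamma and lambda must be nonnegative")


def extended_neighborhood(p: tuple[int, int], domain: ChipDomain) -> list[tuple[int, int]]:
    """Admissible extended Moore neighborhood of p, ordered row-major.

    Contains p itself plus every in-grid, non-obstacle Moore neighbor
    (at most 9 squares).  Raises :class:`StateError` if p sits on an
    obstacle square.
    """
    i, j = p
    if not domain.in_grid(i, j):
        raise StateError(f"square {p} outside the grid")
    flat = (i - 1) * domain.n_col + (j - 1)
    idx = domain.ext_neighborhoods[flat]
    if idx is None:
        raise StateError(f"agent on obstacle square {p}")
    return [(int(f // domain.n_col) + 1, int(f % domain.n_col) + 1) for f in idx]


def _powers(a_vals: np.ndarray, lam: float) -> np.ndarray:
    """A^lambda with the 0^0 = 1 convention (exact isotropy at lambda = 0)."""
    if lam == 0.0:
        return np.ones_like(a_vals)
    return np.power(a_vals, lam)


def movement_probabilities(
    p: tuple[int, int],
    field: AnnexinField,
    mp: MovementParams,
    domain: ChipDomain,
    blocked: set[tuple[int, int]] | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Landing probabilities over the admissible extended neighborhood of p.

    ``blocked`` squares (channel squares already holding a leukocyte, under
    volume exclusion) are removed before normalization; p itself is never
    removed.  If the lambda-adjusted total concentration TA is zero the
    distribution is uniform.

    Returns the ordered list of candidate squares and their probabilities
    (summing to 1).
    """
    squares = extended_neighborhood(p, domain)
    if blocked:
        squares = [q for q in squares if q == p or q not in blocked]
    n = len(squares)
    a_flat = field.a.ravel()
    idx = np.asarray([(i - 1) * domain.n_col + (j - 1) for i, j in squares])
    weights = _powers(a_flat[idx], mp.lam)
    ta = float(weights.sum())
    if ta <= 0.0:
        return squares, np.full(n, 1.0 / n)
    p_mt = np.exp(-mp.gamma * ta)
    probs = p_mt / n + (1.0 - p_mt) * weights / ta
    return squares, probs


def sample_move(
    squares: list[tuple[int, int]],
    probs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw one landing square from a categorical distribution.

    Deterministic given the generator state; rejects degenerate inputs
    (NaN or negative probabilities).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or len(probs) != len(squares):
        raise ValueError("probs must align with squares")
    if np.any(~np.isfinite(probs)) or np.any(probs < 0):
        raise FloatingPointError("degenerate movement distribution")
    cum = np.cumsum(probs)
    if not np.isclose(cum[-1], 1.0, atol=1e-9):
        raise FloatingPointError("movement probabilities do not sum to 1")
    k = int(np.searchsorted(cum, rng.random(), side="right"))
    return squares[min(k, len(squares) - 1)]


def apply_interaction(cell: TumorCell, k_tl: float, l_c: float) -> TumorCell:
    """Apply one leukocyte contact to a live tumor cell (in place).

    Advances the biological age by ``k_tl * (age_c / l_c + 1)``; called once
    per contacting leukocyte per step.
    """
    if l_c <= 0:
        raise ConfigurationError("tumor maximum lifetime l_c must be positive")
    if k_tl < 0:
        raise ConfigurationError("k_tl must be nonnegative")
    if not cell.alive:
        raise StateError("interaction applied to a dead tumor cell")
    cell.age_c += k_tl * (cell.age_c / l_c + 1.0)
    return cell
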