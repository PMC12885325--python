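"""Annexin A1 chemoattractant field on the discretized chip domain.

Doxorubicin-treated tumor cells release annexin A1, which diffuses across
the lattice and is eliminated at a first-order rate.  The continuous
dynamics are

    dA/dt = k_A * N_C(x, y, t) + D lap(A) - k_XA * A,    A(x, y, 0) = 0,

stepped explicitly on the grid.  Two discretizations are provided:

* ``"conservative"`` (default): each square sends the share
  ``D * A(p) / d_n`` to each admissible Moore neighbor (``d_n`` = 1
  orthogonal, sqrt(2) diagonal, in grid units) and loses the total sent.
  With production and elimination off this scheme conserves total mass.
* ``"literal"``: the verbatim printed update, in which a neighbor receives
  ``A(p)/d_n`` while p loses ``D * (sum_n A(p)/d_n - A(p))``; it creates
  mass and is retained only for fidelity experiments.

Obstacle squares carry no concentration and are not diffusion neighbors
(no-flux walls); elimination and diffusion act on every free square,
production only where tumor cells sit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chip_domain import OBSTACLE, ChipDomain, _shift_slices
from .errors import ConfigurationError


@dataclass(frozen=True)
class AnnexinKinetics:
    """Annexin production, diffusion-sharing and elimination rates.

    Parameters
    ----------
    k_a : production rate per tumor cell, concentration units / min.
    d : dimensionless diffusion sharing factor (fraction of a square's
        content sent to each neighbor, scaled by 1/d_n).
    k_xa : first-order elimination rate, 1/min.
    """

    k_a: float
    d: float
    k_xa: float

    def __post_init__(self) -> None:
        if self.k_a < 0 or self.d < 0 or self.k_xa < 0:
            raise ConfigurationError("annexin kinetic rates must be nonnegative")

    def check_stability(self, domain: ChipDomain, dt: float) -> None:
        """Reject configurations whose explicit step can go negative.

        Requires ``k_xa * dt + d * max_p sum_n 1/d_n <= 1`` (the update
        coefficient of A(p) stays nonnegative on every square).
        """
        max_coef = float(domain.outflow_coefficient.max())
        if self.k_xa * dt + self.d * max_coef > 1.0 + 1e-12:
            raise ConfigurationError(
                f"unstable annexin step: k_xa*dt + d*sum(1/d_n) = "
                f"{self.k_xa * dt + self.d * max_coef:.4f} > 1"
            )


@dataclass
class AnnexinField:
    """Nonnegative annexin concentration per grid square, plus the clock."""

    a: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, domain: ChipDomain) -> "AnnexinField":
        return cls(a=np.zeros((domain.n_row, domain.n_col)), t=0.0)


def step_annexin(
    field: AnnexinField,
    tumor_count: np.ndarray,
    kin: AnnexinKinetics,
    domain: ChipDomain,
    dt: float,
    scheme: str = "conservative",
) -> AnnexinField:
    """Advance the annexin field by one step of length ``dt`` minutes.

    ``tumor_count`` is the per-square live tumor-cell count N_C(p, t);
    production is ``k_a * N_C * dt`` (zero where no tumor cell sits).
    All terms are evaluated on the pre-step field.
    """
    kin.check_stability(domain, dt)
    a = field.a
    if scheme == "conservative":
        new = a * (1.0 - kin.k_xa * dt - kin.d * domain.outflow_coefficient)
        for (di, dj), w, mask in domain.diffusion_edges:
            src = _shift_slices(domain.n_row, domain.n_col, di, dj)
            dst = _shift_slices(domain.n_row, domain.n_col, -di, -dj)
            new[dst] += (kin.d * w) * a[src] * mask[src]
    elif scheme == "literal":
        # Verbatim printed update: p keeps D*(A - sum A/d_n), each neighbor
        # receives A/d_n without the factor D -> not mass-conserving.
        new = a * (1.0 - kin.k_xa * dt) + kin.d * (
            a - a * domain.outflow_coefficient
        )
        for (di, dj), w, mask in domain.diffusion_edges:
            src = _shift_slices(domain.n_row, domain.n_col, di, dj)
            dst = _shift_slices(domain.n_row, domain.n_col, -di, -dj)
            new[dst] += w * a[src] * mask[src]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    new += kin.k_a * dt * tumor_count
    new[domain.occupancy == OBSTACLE] = 0.0
    if scheme == "conservative":
        np.maximum(new, 0.0, out=new)
    return AnnexinField(a=new, t=field.t + dt)


def total_mass(field: AnnexinField) -> float:
    """Total annexin over all squares (conserved by the conservative scheme
    when production and elimination are switched off)."""
    return float(field.a.sum())
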