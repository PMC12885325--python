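"""Shared fixtures: reference and scaled-down chip worlds."""

import numpy as np
import pytest

from chipabm import (
    AnnexinKinetics,
    ChipGeometry,
    FixedParameters,
    ParameterVector,
    build_domain,
)


@pytest.fixture(scope="session")
def domain():
    """The reference chip domain (121 x 144 grid)."""
    return build_domain(ChipGeometry())


@pytest.fixture(scope="session")
def small_geometry():
    """A scaled-down chip: same three-section layout, 29 x 38 grid."""
    return ChipGeometry(
        lx=456.0, ly=348.0,
        left_width=168.0, center_width=120.0, right_width=168.0,
        n_channels=8, n_interspaces=7,
    )


@pytest.fixture(scope="session")
def small_domain(small_geometry):
    return build_domain(small_geometry)


@pytest.fixture(scope="session")
def fast_fixed():
    """Short-horizon fixed parameters for simulation tests (240 steps).

    The kinetics flood the scaled chip with an O(1)-or-larger annexin
    gradient within the pre-video period, as the filmed experiment shows.
    """
    return FixedParameters(
        horizon=960.0, video_start=480.0, n_tumor=8,
        kinetics=AnnexinKinetics(k_a=10.0, d=0.14, k_xa=0.0005),
    )


@pytest.fixture(scope="session")
def theta_cc():
    """A chemotactically sensitive parameter set (CC-genotype-like)."""
    return ParameterVector(
        k_leu1=0.05, gamma=1e4, lam=2.65, k_tl=5000.0,
        k_dis=0.8, k_leu2=0.01, t_dly=240.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
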