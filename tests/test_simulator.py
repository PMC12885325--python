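"""Simulation orchestration: placement, spawning, stepping, reproducibility."""

import numpy as np
import pytest

from chipabm import (
    FixedParameters,
    ParameterVector,
    place_tumor_cells,
    run_simulation,
)
from chipabm.chip_domain import OBSTACLE
from chipabm.errors import ConfigurationError
from chipabm.simulator import SimulationState, spawn_step


def make_theta(**overrides):
    base = dict(k_leu1=0.05, gamma=1e4, lam=1.0, k_tl=100.0,
                k_dis=0.8, k_leu2=0.01, t_dly=240.0)
    base.update(overrides)
    return ParameterVector(**base)


class TestPlaceTumorCells:
    def test_all_lower_when_k_dis_one(self, small_domain, fast_fixed, rng):
        theta = make_theta(k_dis=1.0)
        fixed = FixedParameters(horizon=960.0, video_start=480.0, n_tumor=10)
        cells = place_tumor_cells(theta, fixed, small_domain, rng)
        mid = small_domain.n_row // 2
        assert len(cells) == 10
        assert all(c.pos[0] > mid for c in cells)

    def test_even_split_when_k_dis_half(self, small_domain, rng):
        theta = make_theta(k_dis=0.5)
        fixed = FixedParameters(horizon=960.0, video_start=480.0, n_tumor=10)
        cells = place_tumor_cells(theta, fixed, small_domain, rng)
        mid = small_domain.n_row // 2
        lower = sum(c.pos[0] > mid for c in cells)
        assert lower == 5 and len(cells) == 10

    def test_all_in_left_chamber_distinct_squares(self, domain, rng):
        theta = make_theta(k_dis=0.7)
        fixed = FixedParameters(n_tumor=40)
        cells = place_tumor_cells(theta, fixed, domain, rng)
        assert all(c.pos[1] <= 57 for c in cells)
        assert len({c.pos for c in cells}) == 40

    def test_overfull_half_rejected(self, small_domain, rng):
        theta = make_theta(k_dis=1.0)
        fixed = FixedParameters(n_tumor=10_000)
        with pytest.raises(Exception, match="cannot place"):
            place_tumor_cells(theta, fixed, small_domain, rng)


class TestSpawning:
    def test_zero_rates_spawn_nothing(self, small_domain, fast_fixed):
        state = SimulationState(small_domain, fast_fixed, np.random.default_rng(0))
        zero = make_theta(k_leu1=0.0, k_leu2=0.0)
        for _ in range(200):
            spawn_step(state, zero)
            state.t += fast_fixed.dt
        assert len(state.leukocytes) == 0

    def test_no_left_spawns_before_delay(self, small_domain, fast_fixed):
        state = SimulationState(small_domain, fast_fixed, np.random.default_rng(1))
        theta = make_theta(k_leu1=0.0001, k_leu2=0.1, t_dly=1e9)
        left_cols = set(small_domain.section_columns("left"))
        for _ in range(200):
            spawn_step(state, theta)
            state.t += fast_fixed.dt
        assert all(leu.pos[1] not in left_cols for leu in state.leukocytes)

    def test_right_spawns_in_rightmost_half(self, small_domain, fast_fixed):
        state = SimulationState(small_domain, fast_fixed, np.random.default_rng(2))
        theta = make_theta(k_leu1=0.2, k_leu2=0.0001, t_dly=1e9)
        right = small_domain.section_columns("right")
        rightmost = set(right[len(right) // 2:])
        for _ in range(100):
            spawn_step(state, theta)
            state.t += fast_fixed.dt
        assert len(state.leukocytes) > 0
        assert all(leu.pos[1] in rightmost for leu in state.leukocytes)

    def test_binomial_spawn_count(self, small_domain, fast_fixed):
        """Spawn probability k_leu1 * dt: counts match a binomial within 3 sigma."""
        theta = make_theta(k_leu1=0.05, k_leu2=0.0001, t_dly=1e9)
        p = 0.05 * fast_fixed.dt  # 0.2
        n = 10_000
        state = SimulationState(small_domain, fast_fixed, np.random.default_rng(3))
        count = 0
        for _ in range(n):
            spawn_step(state, theta)
            count += len(state.leukocytes)
            # reset occupancy so the spawn region never saturates
            for leu in state.leukocytes:
                state.leu_count[leu.pos[0] - 1, leu.pos[1] - 1] -= 1
            state.leukocytes.clear()
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(count - n * p) < 3 * sigma

    def test_left_spawns_on_top_row_after_delay(self, small_domain, fast_fixed):
        state = SimulationState(small_domain, fast_fixed, np.random.default_rng(4))
        state.t = 500.0
        theta = make_theta(k_leu1=0.0, k_leu2=0.1, t_dly=240.0)
        for _ in range(50):
            spawn_step(state, theta)
        left_cols = set(small_domain.section_columns("left"))
        assert len(state.leukocytes) > 0
        assert all(leu.pos[0] == 1 and leu.pos[1] in left_cols
                   for leu in state.leukocytes)


class TestRunSimulation:
    def test_seeded_bit_reproducibility(self, small_domain, fast_fixed, theta_cc):
        a = run_simulation(theta_cc, fast_fixed, small_domain, seed=99)
        b = run_simulation(theta_cc, fast_fixed, small_domain, seed=99)
        assert a.times == b.times
        assert a.leukocytes == b.leukocytes
        assert a.tumors == b.tumors

    def test_zero_spawn_rates_zero_leukocytes(self, small_domain, fast_fixed):
        theta = make_theta(k_leu1=0.0, k_leu2=0.0)
        frames = run_simulation(theta, fast_fixed, small_domain, seed=0)
        assert all(len(f) == 0 for f in frames.leukocytes)

    def test_reference_step_count(self, small_domain, theta_cc):
        fixed = FixedParameters(n_tumor=8)  # dt=4, horizon=2880
        frames = run_simulation(theta_cc, fixed, small_domain, seed=5)
        assert frames.n_steps == 720
        assert len(frames.times) == 361  # every step from t=1440 to 2880
        assert frames.times[0] == pytest.approx(1440.0)
        assert frames.times[-1] == pytest.approx(2880.0)

    def test_invalid_theta_rejected(self, small_domain, fast_fixed):
        with pytest.raises(ConfigurationError):
            run_simulation(make_theta(k_dis=0.3), fast_fixed, small_domain, seed=0)
        with pytest.raises(ConfigurationError):
            run_simulation(make_theta(gamma=-1.0), fast_fixed, small_domain, seed=0)
        # outside the prior box but structurally fine: flagged, not fatal
        assert not make_theta(lam=7.0).in_prior_box()

    def test_agents_never_on_obstacles(self, small_domain, fast_fixed, theta_cc):
        frames = run_simulation(theta_cc, fast_fixed, small_domain, seed=11)
        occ = small_domain.occupancy
        for k in range(len(frames.times)):
            for (i, j) in frames.leukocytes[k] + frames.tumors[k]:
                assert occ[i - 1, j - 1] != OBSTACLE

    def test_channel_squares_never_hold_two(self, small_domain, fast_fixed):
        theta = make_theta(k_leu1=0.2, lam=3.0, gamma=1e5)
        frames = run_simulation(theta, fast_fixed, small_domain, seed=13)
        channel = set(int(j) for j in small_domain.section_columns("channel"))
        for k in range(len(frames.times)):
            in_channel = [p for p in frames.leukocytes[k] if p[1] in channel]
            assert len(in_channel) == len(set(in_channel))

    def test_tumor_count_non_increasing(self, small_domain, fast_fixed, theta_cc):
        frames = run_simulation(theta_cc, fast_fixed, small_domain, seed=17)
        counts = [len(t) for t in frames.tumors]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_leukocyte_count_bounded_by_spawn_opportunities(
        self, small_domain, fast_fixed, theta_cc
    ):
        frames = run_simulation(theta_cc, fast_fixed, small_domain, seed=19)
        for k, t in enumerate(frames.times):
            max_spawns = 2 * int(t / fast_fixed.dt)
            assert len(frames.leukocytes[k]) <= max_spawns

    def test_contact_shortens_tumor_lifetime(self, small_domain):
        """Under heavy contact, k_TL large kills tumors sooner than k_TL = 0
        (stochastic ordering over seeds)."""
        fixed = FixedParameters(horizon=960.0, video_start=480.0, n_tumor=8,
                                l_c=1200.0)
        survivors_hi, survivors_off = [], []
        for seed in range(6):
            hi = run_simulation(make_theta(k_tl=1e4, k_leu1=0.2, lam=4.0),
                                fixed, small_domain, seed=seed)
            off = run_simulation(make_theta(k_tl=0.0, k_leu1=0.2, lam=4.0),
                                 fixed, small_domain, seed=seed)
            survivors_hi.append(len(hi.tumors[-1]))
            survivors_off.append(len(off.tumors[-1]))
        assert sum(survivors_hi) < sum(survivors_off)
        # without contact aging, no tumor reaches l_c within the horizon
        assert survivors_off == [8] * 6

    def test_move_fast_path_matches_public_movement_law(self, small_domain,
                                                        fast_fixed):
        """The simulator's flat-index move kernel reproduces exactly the
        public movement_probabilities + sample_move composition."""
        from chipabm import AnnexinField, MovementParams
        from chipabm.cell_agents import movement_probabilities, sample_move
        from chipabm.simulator import _move_leukocytes

        rng_field = np.random.default_rng(8)
        mp = MovementParams(gamma=1e3, lam=2.0)
        for start in [(3, 4), (1, 1), (9, 16)]:  # chamber, corner, channel row
            for seed in range(5):
                state = SimulationState(small_domain, fast_fixed,
                                        np.random.default_rng(seed))
                state.field = AnnexinField.zeros(small_domain)
                state.field.a[small_domain.occupancy == 0] = rng_field.random(
                    int((small_domain.occupancy == 0).sum())
                )
                state.add_leukocyte(start, age=0.0)
                _move_leukocytes(state, mp)
                # replay with the public API and an identically seeded stream
                rng = np.random.default_rng(seed)
                rng.permutation(1)
                squares, probs = movement_probabilities(
                    start, state.field, mp, small_domain
                )
                expected = sample_move(squares, probs, rng)
                assert state.leukocytes[0].pos == expected

    def test_chemotaxis_direction(self, small_domain, fast_fixed):
        """Large lambda pulls leukocytes left (toward tumor annexin); with
        lambda = 0 the bin-1 cumulative count stays smaller (sign of the
        genotype contrast)."""
        left_counts = {0.0: 0, 4.0: 0}
        for lam in left_counts:
            for seed in range(5):
                theta = make_theta(lam=lam, gamma=1e6, k_leu1=0.1)
                frames = run_simulation(theta, fast_fixed, small_domain, seed=seed)
                # count leukocytes in the left chamber at the final frame
                left_counts[lam] += sum(
                    1 for (i, j) in frames.leukocytes[-1] if j <= small_domain.n_left
                )
        assert left_counts[4.0] > left_counts[0.0]
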