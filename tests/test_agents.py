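import numpy as np
import pytest

from algalink.agents import (BehaviorParams, enforce_walls, init_population,
                             step_chlamy, step_euglena)
from algalink.errors import ConfigurationError
from algalink.geometry import build_layout, in_interior, square_index_of

LIT_NONE = np.zeros(25, dtype=bool)
LIT_ALL = np.ones(25, dtype=bool)


def quiet_params(**over):
    """Noise-free parameters for deterministic kinematics checks."""
    base = dict(euglena_heading_noise=0.0, wall_turn_jitter=0.0,
                chlamy_heading_noise=0.0)
    base.update(over)
    return BehaviorParams(**base)


class TestInitPopulation:
    def test_euglena_ranges(self, layout, rng):
        pop = init_population("euglena", 400, layout, rng)
        assert pop.n == 400
        assert np.all((pop.speed >= 30) & (pop.speed <= 90))
        assert np.all((pop.body_length >= 20) & (pop.body_length <= 100))
        assert np.all(in_interior(pop.x, pop.y, layout))
        assert not pop.tumbling.any()  # all start swimming

    def test_chlamy_ranges(self, layout, rng):
        pop = init_population("chlamy", 1300, layout, rng)
        assert pop.n == 1300
        assert np.all((pop.diameter >= 10) & (pop.diameter <= 30))
        assert np.all((pop.speed >= 20) & (pop.speed <= 100))
        # default resting fraction 0.5
        assert 0.4 < pop.active.mean() < 0.6

    def test_seed_determinism(self, layout):
        a = init_population("euglena", 50, layout, np.random.default_rng(3))
        b = init_population("euglena", 50, layout, np.random.default_rng(3))
        assert np.array_equal(a.x, b.x) and np.array_equal(a.heading, b.heading)

    @pytest.mark.parametrize("n", [0, -5])
    def test_bad_count(self, layout, rng, n):
        with pytest.raises(ConfigurationError):
            init_population("euglena", n, layout, rng)


class TestStepEuglena:
    def test_dark_ballistic_advance(self, layout, rng):
        pop = init_population("euglena", 1, layout, rng)
        pop.x[0], pop.y[0] = 240.0, 240.0
        pop.heading[0], pop.speed[0] = 0.0, 60.0
        step_euglena(pop, LIT_NONE, layout, quiet_params(), 0.147, rng)
        assert pop.x[0] == pytest.approx(240.0 + 8.82)
        assert pop.y[0] == pytest.approx(240.0)
        assert not pop.tumbling[0]

    def test_tumble_brownian_rms(self, layout):
        # RMS displacement over 100 sub-ticks must follow <|dx|^2>=4*D*t
        rng = np.random.default_rng(5)
        n = 10_000
        pop = init_population("euglena", n, layout, rng)
        pop.x[:], pop.y[:] = 240.0, 240.0  # centre of square 1
        params = quiet_params(euglena_tumble_D=25.0)
        for _ in range(100):
            step_euglena(pop, LIT_ALL, layout, params, 0.147, rng)
        rms = np.sqrt(np.mean((pop.x - 240.0) ** 2 + (pop.y - 240.0) ** 2))
        expected = np.sqrt(4 * 25.0 * 14.7)  # 38.34 um
        assert rms == pytest.approx(expected, rel=0.03)
        assert pop.tumbling.all()

    def test_border_turn_certain_blocks_entry(self, layout):
        # cell in the passage heading into a lit square never enters it
        rng = np.random.default_rng(0)
        lit = np.zeros(25, dtype=bool)
        lit[1] = True  # square 2 illuminated
        pop = init_population("euglena", 1, layout, rng)
        params = quiet_params(euglena_border_turn_prob=1.0)
        for _ in range(200):
            pop.x[0], pop.y[0] = 560.0, 240.0  # h-passage, near square 2
            pop.heading[0], pop.speed[0] = 0.0, 90.0
            step_euglena(pop, lit, layout, params, 0.147, rng)
            assert square_index_of(pop.x[0], pop.y[0], layout) != 2

    def test_border_crossing_allowed_when_prob_zero(self, layout):
        rng = np.random.default_rng(0)
        lit = np.zeros(25, dtype=bool)
        lit[1] = True
        pop = init_population("euglena", 1, layout, rng)
        pop.x[0], pop.y[0] = 565.0, 240.0
        pop.heading[0], pop.speed[0] = 0.0, 90.0
        step_euglena(pop, lit, layout, quiet_params(euglena_border_turn_prob=0.0),
                     layout.passage_length / 90.0, rng)
        assert square_index_of(pop.x[0], pop.y[0], layout) == 2

    def test_bad_dt(self, layout, rng):
        pop = init_population("euglena", 2, layout, rng)
        with pytest.raises(ConfigurationError):
            step_euglena(pop, LIT_NONE, layout, quiet_params(), 0.0, rng)


class TestStepChlamy:
    def test_resting_dark_stays_resting(self, layout, rng):
        pop = init_population("chlamy", 100, layout, rng,
                              BehaviorParams(chlamy_resting_fraction_init=1.0))
        x0 = pop.x.copy()
        for _ in range(20):
            step_chlamy(pop, LIT_NONE, layout, quiet_params(), 0.147, rng)
        assert not pop.active.any()
        assert np.array_equal(pop.x, x0)  # resting cells do not move

    def test_activation_follows_exponential_law(self, layout):
        # resting fraction after t=14.7 s at k_act=0.1/s: 1-exp(-1.47)=0.770
        rng = np.random.default_rng(8)
        pop = init_population("chlamy", 10_000, layout, rng,
                              BehaviorParams(chlamy_resting_fraction_init=1.0))
        params = quiet_params(chlamy_k_act=0.1)
        for _ in range(100):
            step_chlamy(pop, LIT_ALL, layout, params, 0.147, rng)
        assert pop.active.mean() == pytest.approx(1 - np.exp(-1.47), abs=0.02)

    def test_resting_follows_exponential_law(self, layout):
        # active fraction after t=147 s at k_rest=0.01/s: exp(-1.47)=0.230
        rng = np.random.default_rng(9)
        pop = init_population("chlamy", 10_000, layout, rng,
                              BehaviorParams(chlamy_resting_fraction_init=0.0))
        params = quiet_params(chlamy_k_rest=0.01)
        for _ in range(100):
            step_chlamy(pop, LIT_NONE, layout, params, 1.47, rng)
        assert pop.active.mean() == pytest.approx(np.exp(-1.47), abs=0.02)

    def test_exit_damping_traps_active_cells(self, layout):
        # with damping 0 an activated cell can never leave its lit square
        rng = np.random.default_rng(10)
        pop = init_population("chlamy", 200, layout, rng,
                              BehaviorParams(chlamy_resting_fraction_init=0.0))
        pop.x[:], pop.y[:] = 240.0, 240.0
        params = quiet_params(chlamy_k_act=1.0, chlamy_exit_damping=0.0,
                              chlamy_heading_noise=2.0)
        for _ in range(100):
            step_chlamy(pop, LIT_ALL, layout, params, 0.147, rng)
        assert np.all(square_index_of(pop.x, pop.y, layout) == 1)


class TestEnforceWalls:
    def test_head_on_reflection_reverses_normal(self, layout, rng):
        # moving straight right into the wall of square 1
        x, y, h, _ = enforce_walls(np.array([475.0]), np.array([100.0]),
                                   np.array([489.0]), np.array([100.0]),
                                   np.array([0.0]), layout, rng, jitter=0.0)
        assert x[0] == pytest.approx(2 * 480 - 489)  # specular fold
        assert np.cos(h[0]) < 0  # normal component reversed
        assert y[0] == pytest.approx(100.0)

    def test_passage_is_open(self, layout, rng):
        x, y, h, refl = enforce_walls(np.array([475.0]), np.array([240.0]),
                                      np.array([495.0]), np.array([240.0]),
                                      np.array([0.0]), layout, rng)
        assert not refl[0]
        assert x[0] == pytest.approx(495.0)

    def test_mass_containment(self, layout):
        # 10^6 random proposed steps never leave the interior
        rng = np.random.default_rng(12)
        n = 10_000
        pop = init_population("euglena", n, layout, rng)
        params = BehaviorParams(euglena_tumble_D=2000.0)
        lit = np.zeros(25, dtype=bool)
        lit[rng.choice(25, 12, replace=False)] = True
        for _ in range(100):
            step_euglena(pop, lit, layout, params, 0.147, rng)
            assert in_interior(pop.x, pop.y, layout).all()


class TestPhotophobicFluxes:
    """Monte-Carlo direction-of-effect checks with one group statically lit."""

    def test_euglena_vacate_lit_squares(self, layout):
        rng = np.random.default_rng(21)
        lit = build_layout().group_mask("I")
        pop = init_population("euglena", 2000, layout, rng)
        params = BehaviorParams()
        counts = []
        for block in range(3):
            for _ in range(200):
                step_euglena(pop, lit, layout, params, 0.147, rng)
            sq = square_index_of(pop.x, pop.y, layout)
            counts.append(np.isin(sq - 1, np.flatnonzero(lit)).sum())
        assert counts[0] > counts[1] > counts[2]

    def test_chlamy_activate_in_lit_squares(self, layout):
        rng = np.random.default_rng(22)
        lit = build_layout().group_mask("I")
        pop = init_population("chlamy", 2000, layout, rng,
                              BehaviorParams(chlamy_resting_fraction_init=1.0))
        params = BehaviorParams()
        active = []
        for block in range(2):
            for _ in range(100):
                step_chlamy(pop, lit, layout, params, 0.147, rng)
            sq = square_index_of(pop.x, pop.y, layout)
            in_lit = np.isin(sq - 1, np.flatnonzero(lit))
            active.append((pop.active & in_lit).sum())
        assert active[1] > active[0] >= 0
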