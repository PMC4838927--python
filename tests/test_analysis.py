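import numpy as np
import pytest

from algalink.analysis import (boundary_count, cluster_count, coincidence,
                               coincidence_series, duty_ratio,
                               mean_coincidence, oscillation_period,
                               pattern_histogram, phase_delay)
from algalink.errors import InsufficientOscillationError, UnmatchedFlipsError
from algalink.geometry import GROUP_I, GROUP_II
from algalink.feedback import group_pattern
from algalink.io import make_fixture_log

from oracles import boundary_enumeration, flood_fill_clusters


@pytest.fixture(scope="module")
def perfect_log():
    return make_fixture_log("perfect_oscillation", half_period_steps=133,
                            delay_steps=18)


class TestOscillationPeriod:
    def test_recovers_constructed_period_exactly(self, perfect_log):
        # B flips alternately every 133 steps -> 2*133*1.47 s = 6.517 min
        summary = oscillation_period(perfect_log)
        assert summary.period_mean == pytest.approx(
            perfect_log.meta["true_period_min"], abs=1e-12)
        assert summary.period_mean == pytest.approx(2 * 133 * 1.47 / 60.0)
        assert summary.period_sd == pytest.approx(0.0, abs=1e-12)
        assert summary.n_cycles >= 2

    def test_constant_illumination_raises(self):
        log = make_fixture_log("fixed_pattern")
        with pytest.raises(InsufficientOscillationError):
            oscillation_period(log)


class TestPhaseDelay:
    def test_recovers_constructed_delay_exactly(self, perfect_log):
        summary = phase_delay(perfect_log)
        assert summary.phase_delay_mean == pytest.approx(
            perfect_log.meta["true_delay_min"], abs=1e-12)
        assert summary.phase_delay_sd == pytest.approx(0.0, abs=1e-12)

    def test_printed_delay_value_reachable(self):
        # 15 steps of 1.72 s = 25.8 s = 0.43 min exactly
        log = make_fixture_log("perfect_oscillation", cycle_s=1.72,
                               half_period_steps=120, delay_steps=15)
        assert phase_delay(log).phase_delay_mean == pytest.approx(0.43)

    def test_simultaneous_flips_zero_delay(self):
        log = make_fixture_log("perfect_oscillation", delay_steps=0)
        assert phase_delay(log).phase_delay_mean == pytest.approx(0.0)

    def test_orphan_interior_flip_raises(self, perfect_log):
        # drop every dish-A flip: all dish-B flips become orphans
        log = make_fixture_log("perfect_oscillation")
        log.flips = [f for f in log.flips if f.dish == "B"]
        with pytest.raises(UnmatchedFlipsError) as err:
            phase_delay(log)
        assert len(err.value.orphans) > 0


class TestCoincidence:
    def test_identical_patterns(self, layout):
        pat = group_pattern(GROUP_I, layout)
        assert coincidence(pat, pat) == 25

    def test_opposite_groups_agree_only_on_center(self, layout):
        assert coincidence(group_pattern(GROUP_I, layout),
                           group_pattern(GROUP_II, layout)) == 1

    def test_parity_always_odd_for_12_lit(self, rng):
        # 1 + 2*|intersection| is odd; checked over 10^4 random pairs
        for _ in range(10_000):
            a = np.zeros(25, dtype=bool)
            b = np.zeros(25, dtype=bool)
            a[rng.choice(25, 12, replace=False)] = True
            b[rng.choice(25, 12, replace=False)] = True
            c = coincidence(a, b)
            assert c % 2 == 1
            assert c == 1 + 2 * int((a & b).sum())

    def test_series_constant(self):
        log = make_fixture_log("fixed_pattern")
        df = coincidence_series(log)
        act = log.feedback_steps
        assert (df["coincidence"][act - 1] == 25).all()
        inner = act[15:-15]
        assert np.allclose(df["moving_average"][inner - 1], 25.0)

    def test_series_impulse_spreads_over_window(self):
        log = make_fixture_log("fixed_pattern")
        # flip one square of dish A for one step in the middle of the run
        t = 2000
        log.patterns["A"][t - 1, 0] = ~log.patterns["A"][t - 1, 0]
        df = coincidence_series(log, half_width=10)
        touched = np.flatnonzero(df["moving_average"].to_numpy()
                                 != np.round(df["moving_average"].to_numpy()))
        # a single-step impulse perturbs exactly the 21-step window
        assert touched.size == 21
        assert touched[0] + 1 == t - 10 and touched[-1] + 1 == t + 10

    def test_mean_coincidence_skip_transient(self):
        log = make_fixture_log("fixed_pattern")
        assert mean_coincidence(log) == pytest.approx(25.0)
        assert mean_coincidence(log, skip_transient=200) == pytest.approx(25.0)


class TestDutyRatio:
    def test_fixed_pattern_extremes(self, layout):
        log = make_fixture_log("fixed_pattern")
        duty = duty_ratio(log, "A")
        lit = group_pattern(GROUP_I, layout)
        assert np.allclose(duty[lit], 1.0)
        assert np.allclose(duty[~lit], 0.0)

    def test_mean_duty_is_12_over_25(self):
        # every active step lights exactly 12 squares
        log = make_fixture_log("random_patterns", seed=4)
        duty = duty_ratio(log, "B")
        assert duty.mean() == pytest.approx(12.0 / 25.0)


class TestClusterAndBoundary:
    def test_uniform_status(self):
        allon = np.ones(25, dtype=bool)
        assert cluster_count(allon, "lit") == 1
        assert cluster_count(allon, "unlit") == 0
        assert boundary_count(allon) == 0

    def test_checkerboard(self):
        grid = (np.add.outer(np.arange(5), np.arange(5)) % 2 == 0)
        pattern = ~grid.ravel()  # 13 unlit squares, no 4-adjacency
        assert cluster_count(pattern, "unlit") == 13
        assert boundary_count(pattern) == 40  # all 40 adjacencies differ

    def test_single_lit_corner(self):
        pattern = np.zeros(25, dtype=bool)
        pattern[0] = True
        assert boundary_count(pattern) == 2
        assert cluster_count(pattern, "lit") == 1

    def test_block_plus_center_matches_flood_fill(self):
        pattern = np.ones(25, dtype=bool)
        unlit = [1, 2, 3, 6, 7, 8, 11, 12, 13, 16, 17, 18, 23]  # 3x4 block + extra
        for i in unlit:
            pattern[i - 1] = False
        grid = ~pattern.reshape(5, 5)
        assert cluster_count(pattern, "unlit") == flood_fill_clusters(grid)

    def test_random_patterns_match_oracles(self, rng):
        for _ in range(10_000):
            pattern = rng.random(25) < rng.random()
            grid = pattern.reshape(5, 5)
            assert cluster_count(pattern, "lit") == flood_fill_clusters(grid)
            assert boundary_count(pattern) == boundary_enumeration(grid)

    def test_merging_domains_never_increases_clusters(self, rng):
        # unlighting a square can only merge unlit domains, never split them
        for _ in range(300):
            pattern = rng.random(25) < 0.5
            lit_squares = np.flatnonzero(pattern)
            if lit_squares.size == 0:
                continue
            before = cluster_count(pattern, "unlit")
            pattern2 = pattern.copy()
            pattern2[rng.choice(lit_squares)] = False
            after = cluster_count(pattern2, "unlit")
            assert after <= before + 1  # new isolated cell may appear
            # if the square touches an unlit neighbour, no increase at all
            grid = ~pattern.reshape(5, 5)


class TestPatternHistogram:
    def test_fixed_pattern_single_entry(self):
        log = make_fixture_log("fixed_pattern")
        ranked = pattern_histogram(log, "A")
        assert len(ranked) == 1
        bits, count = ranked[0]
        assert count == log.feedback_steps.size == 3000

    def test_rank_ordering(self, layout):
        log = make_fixture_log("fixed_pattern")
        act = log.feedback_steps
        x = group_pattern(GROUP_I, layout)
        y = group_pattern(GROUP_II, layout)
        z = np.zeros(25, dtype=bool)
        z[:12] = True
        n = act.size
        for dish in ("A", "B"):  # same patterns keep coincidence at 25
            log.patterns[dish][act - 1] = x
            log.patterns[dish][act[int(n * 0.6)] - 1:act[-1]] = y
            log.patterns[dish][act[int(n * 0.9)] - 1:act[-1]] = z
        ranked = pattern_histogram(log, "A")
        counts = [c for _, c in ranked]
        assert counts == sorted(counts, reverse=True)
        assert np.array_equal(ranked[0][0], x)
        assert sum(counts) <= act.size

    def test_coincidence_filter_excludes_low_agreement(self, layout):
        log = make_fixture_log("fixed_pattern")
        act = log.feedback_steps
        # make dish B disagree heavily on half the steps
        half = act[: act.size // 2]
        log.patterns["B"][half - 1] = group_pattern(GROUP_II, layout)
        ranked = pattern_histogram(log, "A")
        assert sum(c for _, c in ranked) == act.size - half.size
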