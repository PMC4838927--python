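"""Interlink feedback algorithms and the closed-loop scheduler.

Two isolated dishes are coupled only through their exchanged TM
datasets.  Every feedback cycle (0.68 Hz, 1.47 s) each dish's trace
image is reduced to 25 TM values; the counter-dish's next illumination
pattern is computed from them:

* two-state flipping ("oscillation"): the squares are split into groups
  I and II of 12; when a dish's group imbalance ratio
  (TM_I - TM_II)/(TM_I + TM_II) exceeds a prefixed threshold in
  magnitude, the TM-dominant group is illuminated in the *counter* dish
  at the next step.  Both dishes start lit on group I.  The centre
  square is never illuminated.
* ranking ("separation"): illuminate in dish B the squares holding the
  12 lowest TMs of dish A, and in dish A the squares holding the 12
  highest TMs of dish B (ties broken toward lower square index).

A run is 4000 steps with the feedback suspended during the first and
last 500 steps (lights off), i.e. 98 min of simulated time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import (BehaviorParams, advance_cycle_chlamy,
                     advance_cycle_euglena, init_population)
from .errors import ConfigurationError, UndefinedRatioError
from .geometry import GROUP_I, GROUP_II, GridLayout, build_layout
from .log import ExperimentLog, FlipEvent
from .trace_imaging import (DEFAULT_RESOLUTION, TMVector, pixel_labels,
                            raster_shape, tm_ratio)
from . import _kernels


@dataclass(frozen=True)
class ScheduleConfig:
    """Timing of the feedback experiment."""

    total_steps: int = 4000
    warmup_steps: int = 500
    cooldown_steps: int = 500
    cycle_s: float = 1.47
    subticks: int = 10
    sync_jitter_cycles: int = 0

    @property
    def cycle_rate_hz(self) -> float:
        return 1.0 / self.cycle_s

    @property
    def dt(self) -> float:
        return self.cycle_s / self.subticks

    @property
    def duration_min(self) -> float:
        return self.total_steps * self.cycle_s / 60.0

    def validate(self) -> "ScheduleConfig":
        if self.total_steps <= 0 or self.cycle_s <= 0 or self.subticks <= 0:
            raise ConfigurationError("steps, cycle_s and subticks must be positive")
        if self.warmup_steps < 0 or self.cooldown_steps < 0:
            raise ConfigurationError("warmup/cooldown must be non-negative")
        if self.warmup_steps + self.cooldown_steps >= self.total_steps:
            raise ConfigurationError("warmup + cooldown must be < total_steps")
        if not 0 <= self.sync_jitter_cycles <= 1:
            raise ConfigurationError("sync_jitter_cycles must be 0 or 1")
        return self


@dataclass
class ExperimentConfig:
    """Full configuration of one interlinked run."""

    n_euglena: int = 400
    n_chlamy: int = 1300
    algorithm: str = "oscillation"  # or "ranking"
    threshold: float = 0.40
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    layout: GridLayout = field(default_factory=build_layout)
    resolution: float = DEFAULT_RESOLUTION
    seed: int = 0

    def validate(self) -> "ExperimentConfig":
        if self.n_euglena <= 0 or self.n_chlamy <= 0:
            raise ConfigurationError("cell counts must be positive")
        if self.algorithm not in ("oscillation", "ranking"):
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must lie in (0, 1)")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        self.behavior.validate()
        self.schedule.validate()
        return self


# ----------------------------------------------------------------------
# pattern rules

def flip_target(ratio: float, threshold: float) -> str | None:
    """Group to illuminate in the counter-dish, or None below threshold.

    When |ratio| >= threshold the TM-dominant group (I for positive,
    II for negative ratio) is returned; an exactly-zero ratio at
    threshold 0 would be ambiguous but thresholds are constrained > 0.
    """
    if ratio is None or np.isnan(ratio):
        return None
    if abs(ratio) < threshold:
        return None
    return GROUP_I if ratio > 0 else GROUP_II


def group_pattern(group: str, layout: GridLayout) -> np.ndarray:
    """Boolean 25-pattern lighting one group; the centre stays dark."""
    if group not in (GROUP_I, GROUP_II):
        raise ConfigurationError(f"unknown group {group!r}")
    return layout.group_mask(group)


def ranking_pattern(tm, select: str, k: int = 12) -> np.ndarray:
    """Light the squares with the k lowest (or highest) TM values.

    Ties are broken toward the lower square index.  The centre square
    participates like any other.
    """
    values = tm.tm if isinstance(tm, TMVector) else np.asarray(tm)
    if k > values.size:
        raise ConfigurationError("k exceeds number of squares")
    idx = np.arange(values.size)
    if select == "lowest":
        order = np.lexsort((idx, values))
    elif select == "highest":
        order = np.lexsort((idx, -values))
    else:
        raise ConfigurationError(f"select must be 'lowest' or 'highest', got {select!r}")
    pattern = np.zeros(values.size, dtype=bool)
    pattern[order[:k]] = True
    return pattern


@dataclass
class FlipControllerState:
    """Per-dish lit group under the two-state flipping algorithm."""

    threshold: float
    lit_group: dict[str, str | None] = field(
        default_factory=lambda: {"A": None, "B": None})

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must lie in (0, 1)")


def interlink_step(tm_a, tm_b, state: FlipControllerState, algorithm: str,
                   layout: GridLayout):
    """One exchange of TM datasets; returns the next patterns.

    Returns ``(pattern_a_next, pattern_b_next, state, flips)`` where
    ``flips`` lists ``(dish, new_group)`` for dishes whose lit group
    changed.  Oscillation mode is level-triggered and idempotent: the
    dominant group of dish A decides dish B's next group and vice versa;
    re-selecting an already-lit group is a no-op.
    """
    if isinstance(tm_a, TMVector) and isinstance(tm_b, TMVector):
        if tm_a.step != tm_b.step:
            raise ConfigurationError("TM vectors must come from the same step")
    flips: list[tuple[str, str]] = []
    if algorithm == "oscillation":
        ratios = {}
        for dish, tm in (("A", tm_a), ("B", tm_b)):
            try:
                ratios[dish] = tm_ratio(tm, layout)
            except UndefinedRatioError:
                ratios[dish] = float("nan")
        # dish A's imbalance commands dish B and vice versa
        for src, dst in (("A", "B"), ("B", "A")):
            target = flip_target(ratios[src], state.threshold)
            if target is not None and target != state.lit_group[dst]:
                state.lit_group[dst] = target
                flips.append((dst, target))
        pat_a = group_pattern(state.lit_group["A"], layout)
        pat_b = group_pattern(state.lit_group["B"], layout)
    elif algorithm == "ranking":
        pat_b = ranking_pattern(tm_a, "lowest")
        pat_a = ranking_pattern(tm_b, "highest")
    else:
        raise ConfigurationError(f"unknown algorithm {algorithm!r}")
    return pat_a, pat_b, state, flips


# ----------------------------------------------------------------------
# closed-loop runner

def run_experiment(config: ExperimentConfig) -> ExperimentLog:
    """Simulate both interlinked dishes cycle by cycle.

    Each step advances the agents ``subticks`` sub-ticks under the
    current patterns, renders the traces, computes and exchanges the TM
    vectors and derives the next patterns, which always apply at the
    *next* step.  Steps 1..warmup and the final cooldown steps have all
    lights off.  The optional synchronisation jitter delays the
    exchanged TM dataset by a uniform 0/1 extra cycle, mimicking the
    +-1-cycle refresh misalignment of two free-running systems.
    """
    config.validate()
    sched = config.schedule
    layout = config.layout
    res = config.resolution

    ss = np.random.SeedSequence(config.seed)
    seed_a, seed_b, seed_j = ss.spawn(3)
    rng_a = np.random.default_rng(seed_a)
    rng_b = np.random.default_rng(seed_b)
    rng_j = np.random.default_rng(seed_j)

    pop_a = init_population("euglena", config.n_euglena, layout, rng_a, config.behavior)
    pop_b = init_population("chlamy", config.n_chlamy, layout, rng_b, config.behavior)

    labels = pixel_labels(layout, res)
    raster = np.zeros(raster_shape(layout, res), dtype=np.bool_)

    T = sched.total_steps
    nsq = layout.n_squares
    patterns = {d: np.zeros((T, nsq), dtype=bool) for d in ("A", "B")}
    tms = {d: np.zeros((T, nsq), dtype=np.int64) for d in ("A", "B")}
    ratios = {d: np.full(T, np.nan) for d in ("A", "B")}
    flips: list[FlipEvent] = []

    state = FlipControllerState(threshold=config.threshold)
    pat_a = np.zeros(nsq, dtype=bool)
    pat_b = np.zeros(nsq, dtype=bool)
    dark = np.zeros(nsq, dtype=bool)
    last_active = T - sched.cooldown_steps
    jit = sched.sync_jitter_cycles

    def render_tm(traj, widths):
        raster.fill(False)
        tm_buf = np.zeros(26, dtype=np.int64)
        radii = np.where(widths > 0, widths / 2.0 + res / 2.0, -1.0)
        _kernels.stamp_polylines(traj, radii, res, res, raster, labels, tm_buf)
        return tm_buf[1:].copy()

    for step in range(1, T + 1):
        t = step - 1
        patterns["A"][t] = pat_a
        patterns["B"][t] = pat_b

        traj, widths = advance_cycle_euglena(pop_a, pat_a, layout, config.behavior,
                                             sched.dt, sched.subticks, rng_a)
        tm_a = render_tm(traj, widths)
        traj, widths = advance_cycle_chlamy(pop_b, pat_b, layout, config.behavior,
                                            sched.dt, sched.subticks, rng_b)
        tm_b = render_tm(traj, widths)

        tms["A"][t] = tm_a
        tms["B"][t] = tm_b
        for dish, tm in (("A", tm_a), ("B", tm_b)):
            try:
                ratios[dish][t] = tm_ratio(tm, layout)
            except UndefinedRatioError:
                pass

        # decide the patterns applied at the next step
        nxt = step + 1
        if sched.warmup_steps < nxt <= last_active:
            if config.algorithm == "oscillation" and state.lit_group["A"] is None:
                # rule (1): begin the interlink with group I in both dishes
                state.lit_group["A"] = state.lit_group["B"] = GROUP_I
                pat_a = group_pattern(GROUP_I, layout)
                pat_b = group_pattern(GROUP_I, layout)
                flips.append(FlipEvent(nxt, "A", GROUP_I))
                flips.append(FlipEvent(nxt, "B", GROUP_I))
            else:
                if jit:
                    # delayed exchange: use the TM dataset from 0 or 1
                    # cycles back, independently per direction
                    da, db = rng_j.integers(0, jit + 1, size=2)
                    ex_a = tms["A"][max(t - da, 0)]
                    ex_b = tms["B"][max(t - db, 0)]
                else:
                    ex_a, ex_b = tm_a, tm_b
                pat_a, pat_b, state, new = interlink_step(
                    ex_a, ex_b, state, config.algorithm, layout)
                flips.extend(FlipEvent(nxt, dish, grp) for dish, grp in new)
        else:
            pat_a = dark
            pat_b = dark

    # the initial group-I assignment is the feedback switching on, not a flip
    flips = [f for f in flips if f.step > sched.warmup_steps + 1]
    return ExperimentLog(cycle_s=sched.cycle_s, warmup_steps=sched.warmup_steps,
                         cooldown_steps=sched.cooldown_steps, patterns=patterns,
                         tm=tms, ratio=ratios, flips=flips,
                         algorithm=config.algorithm,
                         meta={"seed": config.seed,
                               "threshold": config.threshold,
                               "n_euglena": config.n_euglena,
                               "n_chlamy": config.n_chlamy})
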