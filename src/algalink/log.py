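"""Per-step experiment log shared by the simulator and the analysis.

The log records, for every time step and both dishes, the applied
illumination pattern, the 25-element TM vector, the group imbalance
ratio (NaN where undefined or not applicable), and illumination flip
events.  It round-trips through a long-format CSV with one row per
(step, dish):

    step, time_s, dish, lit_mask, tm_1..tm_25, ratio, flip_event

where ``lit_mask`` is a 25-character 0/1 string ordered by square index
and ``flip_event`` is the newly lit group ("I"/"II") on the step where a
dish's illumination flipped, else empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

DISHES = ("A", "B")


@dataclass
class FlipEvent:
    step: int
    dish: str
    group: str  # newly lit group, "I" or "II"

    @property
    def time_s(self) -> float:
        raise AttributeError("use ExperimentLog.flip_times for times")


@dataclass
class ExperimentLog:
    """Complete closed-loop run record for both dishes."""

    cycle_s: float
    warmup_steps: int
    cooldown_steps: int
    patterns: dict[str, np.ndarray]   # dish -> bool (T, 25)
    tm: dict[str, np.ndarray]         # dish -> int64 (T, 25)
    ratio: dict[str, np.ndarray]      # dish -> float (T,), NaN if undefined
    flips: list[FlipEvent] = field(default_factory=list)
    algorithm: str = "oscillation"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {d: self.patterns[d].shape for d in DISHES}
        if any(s != (self.total_steps, 25) for s in shapes.values()):
            raise ConfigurationError(f"inconsistent pattern shapes {shapes}")

    # ------------------------------------------------------------------
    @property
    def total_steps(self) -> int:
        return self.patterns["A"].shape[0]

    @property
    def feedback_steps(self) -> np.ndarray:
        """1-based step indices of the feedback-active window."""
        return np.arange(self.warmup_steps + 1,
                         self.total_steps - self.cooldown_steps + 1)

    def is_active(self, step: int) -> bool:
        return self.warmup_steps < step <= self.total_steps - self.cooldown_steps

    def time_of(self, step) -> np.ndarray:
        """Time in seconds at the end of a 1-based step."""
        return np.asarray(step) * self.cycle_s

    def dish_flips(self, dish: str, group: str | None = None) -> list[FlipEvent]:
        return [f for f in self.flips
                if f.dish == dish and (group is None or f.group == group)]

    def flip_times(self, dish: str, group: str | None = None) -> np.ndarray:
        """Flip times in seconds."""
        return np.array([self.time_of(f.step) for f in self.dish_flips(dish, group)])

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        flip_map = {(f.step, f.dish): f.group for f in self.flips}
        for dish in DISHES:
            pat = self.patterns[dish]
            tm = self.tm[dish]
            ratio = self.ratio[dish]
            for t in range(self.total_steps):
                step = t + 1
                row = {"step": step, "time_s": step * self.cycle_s, "dish": dish,
                       "lit_mask": "".join("1" if b else "0" for b in pat[t])}
                row |= {f"tm_{i + 1}": int(tm[t, i]) for i in range(25)}
                row["ratio"] = ratio[t]
                row["flip_event"] = flip_map.get((step, dish), "")
                rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values(["step", "dish"], kind="stable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cycle_s: float | None = None,
                   warmup_steps: int = 500, cooldown_steps: int = 500,
                   algorithm: str = "oscillation") -> "ExperimentLog":
        steps = np.sort(df["step"].unique())
        total = int(steps.max())
        if cycle_s is None:
            one = df[df["step"] == steps[0]].iloc[0]
            cycle_s = float(one["time_s"]) / float(one["step"])
        patterns, tm, ratio = {}, {}, {}
        flips: list[FlipEvent] = []
        tm_cols = [f"tm_{i + 1}" for i in range(25)]
        for dish in DISHES:
            sub = df[df["dish"] == dish].sort_values("step")
            if len(sub) != total:
                raise ConfigurationError(f"log misses steps for dish {dish}")
            patterns[dish] = np.array(
                [[ch == "1" for ch in m] for m in sub["lit_mask"]], dtype=bool)
            tm[dish] = sub[tm_cols].to_numpy(dtype=np.int64)
            ratio[dish] = sub["ratio"].to_numpy(dtype=float)
            ev = sub["flip_event"].fillna("")
            for step, group in zip(sub["step"], ev):
                if group:
                    flips.append(FlipEvent(int(step), dish, str(group)))
        flips.sort(key=lambda f: (f.step, f.dish))
        return cls(cycle_s=cycle_s, warmup_steps=warmup_steps,
                   cooldown_steps=cooldown_steps, patterns=patterns, tm=tm,
                   ratio=ratio, flips=flips, algorithm=algorithm)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ExperimentLog":
        df = pd.read_csv(path, dtype={"lit_mask": str})
        return cls.from_frame(df, **kwargs)
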