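"""Headline metrics extracted from experiment logs.

Oscillation runs are summarised by the full oscillation period (time
between consecutive dish-B flips back to group I; one full cycle is two
alternating flips) and the phase delay (lag from each dish-B flip to the
following dish-A flip).  Separation runs are summarised by the
illumination coincidence between the dishes, per-square duty ratios,
connected-domain counts of the lit/unlit squares, and the frequency
ranking of high-coincidence patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InsufficientOscillationError, UnmatchedFlipsError
from .geometry import GROUP_I, GridLayout
from .log import ExperimentLog

#: 4-connectivity structuring element on the 5x5 square grid
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class OscillationSummary:
    """Mean/SD of the oscillation period and phase delay, in minutes."""

    period_mean: float = float("nan")
    period_sd: float = float("nan")
    phase_delay_mean: float = float("nan")
    phase_delay_sd: float = float("nan")
    n_cycles: int = 0


def oscillation_period(log: ExperimentLog, dish: str = "B") -> OscillationSummary:
    """Full oscillation period from a dish's flips back to group I.

    The SD is the population SD over the measured cycles (0 for a single
    cycle or perfectly regular flipping).
    """
    times = log.flip_times(dish, GROUP_I)
    if times.size < 2:
        raise InsufficientOscillationError(
            f"need >= 2 dish-{dish} flips to group I, found {times.size}")
    periods_min = np.diff(times) / 60.0
    return OscillationSummary(period_mean=float(periods_min.mean()),
                              period_sd=float(periods_min.std()),
                              n_cycles=periods_min.size)


def phase_delay(log: ExperimentLog, lead: str = "B", follow: str = "A"
                ) -> OscillationSummary:
    """Mean lag from each lead-dish flip to the next follow-dish flip.

    A lead flip with no follow flip before the *next* lead flip is an
    orphan and raises :class:`UnmatchedFlipsError`; a trailing lead flip
    with no subsequent follow flip (feedback ended) is dropped.
    """
    t_lead = log.flip_times(lead)
    t_follow = log.flip_times(follow)
    if t_lead.size == 0 or t_follow.size == 0:
        raise UnmatchedFlipsError("no flips to pair", orphans=list(t_lead))
    delays = []
    orphans = []
    for i, tb in enumerate(t_lead):
        nxt_lead = t_lead[i + 1] if i + 1 < t_lead.size else np.inf
        after = t_follow[(t_follow >= tb) & (t_follow < nxt_lead)]
        if after.size == 0:
            if np.isinf(nxt_lead):
                continue  # trailing flip; the loop ended before the response
            orphans.append(tb)
        else:
            delays.append(after[0] - tb)
    if orphans:
        raise UnmatchedFlipsError(
            f"{len(orphans)} dish-{lead} flips without a dish-{follow} response",
            orphans=orphans)
    if not delays:
        raise UnmatchedFlipsError("no pairable flips", orphans=[])
    delays_min = np.asarray(delays) / 60.0
    return OscillationSummary(phase_delay_mean=float(delays_min.mean()),
                              phase_delay_sd=float(delays_min.std()),
                              n_cycles=delays_min.size)


# ----------------------------------------------------------------------
# coincidence

def coincidence(pattern_a, pattern_b) -> int:
    """Number of squares with the same on/off status in both dishes."""
    a = np.asarray(pattern_a, dtype=bool)
    b = np.asarray(pattern_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("patterns must share a layout")
    return int((a == b).sum())


def coincidence_series(log: ExperimentLog, half_width: int = 10) -> pd.DataFrame:
    """Per-step coincidence with a centred +-half_width moving average.

    The averaging window is truncated at the edges (no padding).
    """
    raw = (log.patterns["A"] == log.patterns["B"]).sum(axis=1)
    s = pd.Series(raw)
    avg = s.rolling(window=2 * half_width + 1, center=True, min_periods=1).mean()
    return pd.DataFrame({"step": np.arange(1, log.total_steps + 1),
                         "coincidence": raw,
                         "moving_average": avg.to_numpy()})


def mean_coincidence(log: ExperimentLog, skip_transient: int = 0) -> float:
    """Mean coincidence over the feedback-active window.

    ``skip_transient`` drops that many initial active steps (the rapid
    rise after feedback onset) before averaging.
    """
    steps = log.feedback_steps[skip_transient:]
    raw = (log.patterns["A"][steps - 1] == log.patterns["B"][steps - 1]).sum(axis=1)
    return float(raw.mean())


# ----------------------------------------------------------------------
# spatial pattern metrics

def duty_ratio(log: ExperimentLog, dish: str) -> np.ndarray:
    """Per-square fraction of feedback-active steps spent illuminated."""
    steps = log.feedback_steps
    if steps.size == 0:
        raise InsufficientOscillationError("feedback window is empty")
    return log.patterns[dish][steps - 1].mean(axis=0)


def _as_grid(pattern, layout: GridLayout | None = None) -> np.ndarray:
    p = np.asarray(pattern, dtype=bool)
    rows = cols = int(round(np.sqrt(p.size)))
    return p.reshape(rows, cols)


def cluster_count(pattern, status: str = "unlit",
                  layout: GridLayout | None = None) -> int:
    """Number of 4-connected domains of lit (or unlit) squares.

    Diagonal contact does not join domains: passages exist only on
    shared walls.
    """
    grid = _as_grid(pattern, layout)
    if status == "unlit":
        grid = ~grid
    elif status != "lit":
        raise ValueError(f"status must be 'lit' or 'unlit', got {status!r}")
    _, n = ndimage.label(grid, structure=_FOUR_CONN)
    return int(n)


def boundary_count(pattern, layout: GridLayout | None = None) -> int:
    """Number of 4-adjacent square pairs with differing on/off status."""
    grid = _as_grid(pattern, layout)
    horiz = grid[:, :-1] != grid[:, 1:]
    vert = grid[:-1, :] != grid[1:, :]
    return int(horiz.sum() + vert.sum())


def pattern_histogram(log: ExperimentLog, dish: str = "A",
                      coincidence_range: tuple[int, int] = (21, 25)
                      ) -> list[tuple[np.ndarray, int]]:
    """Frequency ranking of high-coincidence illumination patterns.

    Over feedback-active steps whose coincidence lies in
    ``coincidence_range`` (inclusive), identical 25-bit lit masks of the
    chosen dish are counted.  Patterns are returned sorted by count
    descending, ties broken by first occurrence.
    """
    lo, hi = coincidence_range
    steps = log.feedback_steps
    pa = log.patterns["A"][steps - 1]
    pb = log.patterns["B"][steps - 1]
    coin = (pa == pb).sum(axis=1)
    qualifying = (coin >= lo) & (coin <= hi)
    masks = log.patterns[dish][steps - 1][qualifying]
    counts: dict[bytes, int] = {}
    first: dict[bytes, int] = {}
    for i, m in enumerate(masks):
        key = np.packbits(m).tobytes()
        counts[key] = counts.get(key, 0) + 1
        first.setdefault(key, i)
    ranked = sorted(counts, key=lambda k: (-counts[k], first[k]))
    out = []
    for key in ranked:
        bits = np.unpackbits(np.frombuffer(key, dtype=np.uint8))[:25].astype(bool)
        out.append((bits, counts[key]))
    return out


# ----------------------------------------------------------------------
# plotting (optional; used by the CLI)

def plot_ratio_traces(log: ExperimentLog, path=None):
    """Group-imbalance ratio of both dishes against time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    t_min = log.time_of(np.arange(1, log.total_steps + 1)) / 60.0
    for ax, dish in zip(axes, ("A", "B")):
        ax.plot(t_min, log.ratio[dish], lw=0.6)
        ax.axhline(0.0, color="k", lw=0.4)
        ax.set_ylabel(f"ratio dish {dish}")
        ax.set_ylim(-1, 1)
    axes[1].set_xlabel("time (min)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_coincidence(log: ExperimentLog, path=None, half_width: int = 10):
    """Coincidence series with its moving average."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = coincidence_series(log, half_width)
    fig, ax = plt.subplots(figsize=(8, 3))
    t_min = log.time_of(df["step"].to_numpy()) / 60.0
    ax.plot(t_min, df["coincidence"], lw=0.4, alpha=0.5, label="coincidence")
    ax.plot(t_min, df["moving_average"], color="r", lw=1.0,
            label=f"moving average (+-{half_width})")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("coincidence (squares)")
    ax.set_ylim(0, 25)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
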