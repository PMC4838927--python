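"""Configuration files, run manifests, and synthetic fixture logs.

The experiment configuration is a flat plain-text ``key = value`` file
(``#`` starts a comment).  Keys carry their units in the name to
prevent unit drift; unknown keys are rejected.  An empty file yields the
full default configuration (the published experimental conditions with
the shipped calibrated behavioural parameters).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .agents import BehaviorParams
from .errors import ConfigurationError
from .feedback import ExperimentConfig, ScheduleConfig, group_pattern
from .geometry import GROUP_I, GROUP_II, build_layout
from .log import ExperimentLog, FlipEvent


def _parse_bool(s: str) -> bool:
    v = s.strip().lower()
    if v in ("true", "yes", "1", "on"):
        return True
    if v in ("false", "no", "0", "off"):
        return False
    raise ConfigurationError(f"cannot parse boolean from {s!r}")


def _positive(x):
    if x <= 0:
        raise ConfigurationError(f"value must be positive, got {x}")
    return x


def _non_negative(x):
    if x < 0:
        raise ConfigurationError(f"value must be non-negative, got {x}")
    return x


def _unit_interval(x):
    if not 0.0 <= x <= 1.0:
        raise ConfigurationError(f"value must lie in [0, 1], got {x}")
    return x


def _open_unit_interval(x):
    if not 0.0 < x < 1.0:
        raise ConfigurationError(f"value must lie in (0, 1), got {x}")
    return x


def _choice(*options):
    def check(x):
        if x not in options:
            raise ConfigurationError(f"value must be one of {options}, got {x!r}")
        return x
    return check


#: key -> (parser, validator, target section, field name)
_SCHEMA = {
    # geometry, um
    "square_width_um": (float, _positive, "layout", "square_width"),
    "passage_width_um": (float, _positive, "layout", "passage_width"),
    "passage_length_um": (float, _positive, "layout", "passage_length"),
    "depth_um": (float, _positive, "layout", "depth"),
    # populations
    "n_euglena": (int, _positive, "top", "n_euglena"),
    "n_chlamy": (int, _positive, "top", "n_chlamy"),
    # feedback
    "algorithm": (str, _choice("oscillation", "ranking"), "top", "algorithm"),
    "threshold": (float, _open_unit_interval, "top", "threshold"),
    # schedule
    "total_steps": (int, _positive, "schedule", "total_steps"),
    "warmup_steps": (int, _non_negative, "schedule", "warmup_steps"),
    "cooldown_steps": (int, _non_negative, "schedule", "cooldown_steps"),
    "cycle_s": (float, _positive, "schedule", "cycle_s"),
    "subticks": (int, _positive, "schedule", "subticks"),
    "sync_jitter_cycles": (int, _non_negative, "schedule", "sync_jitter_cycles"),
    # imaging
    "resolution_um_px": (float, _positive, "top", "resolution"),
    # seeding
    "seed": (int, _non_negative, "top", "seed"),
    # behaviour
    "euglena_tumble_D_um2_s": (float, _non_negative, "behavior", "euglena_tumble_D"),
    "euglena_border_turn_prob": (float, _unit_interval, "behavior", "euglena_border_turn_prob"),
    "euglena_heading_noise_rad_rts": (float, _non_negative, "behavior", "euglena_heading_noise"),
    "euglena_tumble_stroke_frac": (float, _non_negative, "behavior", "euglena_tumble_stroke_frac"),
    "chlamy_k_act_per_s": (float, _non_negative, "behavior", "chlamy_k_act"),
    "chlamy_k_rest_per_s": (float, _non_negative, "behavior", "chlamy_k_rest"),
    "chlamy_exit_damping": (float, _unit_interval, "behavior", "chlamy_exit_damping"),
    "chlamy_heading_noise_rad_rts": (float, _non_negative, "behavior", "chlamy_heading_noise"),
    "wall_turn_jitter_rad": (float, _non_negative, "behavior", "wall_turn_jitter"),
    "include_resting_footprint": (_parse_bool, lambda x: x, "behavior", "include_resting_footprint"),
    "chlamy_resting_fraction_init": (float, _unit_interval, "behavior", "chlamy_resting_fraction_init"),
}


def parse_config_text(text: str) -> ExperimentConfig:
    """Parse ``key = value`` lines into a validated ExperimentConfig."""
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _SCHEMA:
            raise ConfigurationError(f"line {lineno}: unknown key {key!r}")
        parser, validator, *_ = _SCHEMA[key]
        try:
            values[key] = validator(parser(val.strip()))
        except ConfigurationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"line {lineno}: bad value for {key}: {exc}") from exc

    sections = {"top": {}, "layout": {}, "schedule": {}, "behavior": {}}
    for key, val in values.items():
        _, _, section, field = _SCHEMA[key]
        sections[section][field] = val
    config = ExperimentConfig(
        layout=build_layout(**sections["layout"]),
        schedule=ScheduleConfig(**sections["schedule"]),
        behavior=BehaviorParams(**sections["behavior"]),
        **sections["top"],
    )
    return config.validate()


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment configuration file."""
    p = Path(path)
    if not p.is_file():
        raise ConfigurationError(f"configuration file not found: {p}")
    return parse_config_text(p.read_text())


def config_to_text(config: ExperimentConfig) -> str:
    """Serialise a configuration back to the plain-text key-value form."""
    out = []
    for key, (_, _, section, field) in _SCHEMA.items():
        src = {"top": config, "layout": config.layout,
               "schedule": config.schedule, "behavior": config.behavior}[section]
        val = getattr(src, field)
        if isinstance(val, bool):
            val = "true" if val else "false"
        elif isinstance(val, float):
            val = f"{val:g}"
        out.append(f"{key} = {val}")
    return "\n".join(out) + "\n"


# ----------------------------------------------------------------------
# run manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir, config: ExperimentConfig, outputs) -> Path:
    """Record everything needed to re-run the experiment bit-identically."""
    from . import __version__

    run_dir = Path(run_dir)
    manifest = {
        "version": __version__,
        "master_seed": config.seed,
        "config": config_to_text(config),
        "outputs": {Path(p).name: _sha256(Path(p)) for p in outputs},
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_manifest(run_dir) -> dict:
    return json.loads((Path(run_dir) / "manifest.json").read_text())


# ----------------------------------------------------------------------
# synthetic fixture logs (analysis-module test scaffolding; synthetic,
# not produced by the simulator)

def make_fixture_log(scenario: str, seed: int = 0, *,
                     total_steps: int = 4000, warmup_steps: int = 500,
                     cooldown_steps: int = 500, cycle_s: float = 1.47,
                     half_period_steps: int = 133, delay_steps: int = 18,
                     pattern=None) -> ExperimentLog:
    """Construct a synthetic log with known ground-truth metrics.

    Scenarios
    ---------
    perfect_oscillation
        Dish B's lit group alternates exactly every ``half_period_steps``
        during the feedback window and dish A follows ``delay_steps``
        later.  The true period/delay in minutes are stored in
        ``log.meta`` (keys ``true_period_min``, ``true_delay_min``).
    fixed_pattern
        One constant 12-lit pattern in both dishes for every active step.
    random_patterns
        Independent uniformly random 12-lit patterns per step and dish.
    """
    layout = build_layout()
    rng = np.random.default_rng(seed)
    T = total_steps
    nsq = layout.n_squares
    patterns = {d: np.zeros((T, nsq), dtype=bool) for d in ("A", "B")}
    tms = {d: np.zeros((T, nsq), dtype=np.int64) for d in ("A", "B")}
    ratios = {d: np.full(T, np.nan) for d in ("A", "B")}
    flips: list[FlipEvent] = []
    active = np.arange(warmup_steps + 1, T - cooldown_steps + 1)
    meta: dict = {"scenario": scenario}

    if scenario == "perfect_oscillation":
        pat = {GROUP_I: group_pattern(GROUP_I, layout),
               GROUP_II: group_pattern(GROUP_II, layout)}
        flip_steps_b = list(range(int(active[0]) + half_period_steps,
                                  int(active[-1]) + 1, half_period_steps))
        g = GROUP_I
        nxt = iter(flip_steps_b)
        upcoming = next(nxt, None)
        for step in active:
            if upcoming is not None and step == upcoming:
                g = GROUP_II if g == GROUP_I else GROUP_I
                flips.append(FlipEvent(int(step), "B", g))
                upcoming = next(nxt, None)
            patterns["B"][step - 1] = pat[g]
        # dish A follows with a fixed delay
        for f in [f for f in flips if f.dish == "B"]:
            step_a = f.step + delay_steps
            if step_a <= active[-1]:
                flips.append(FlipEvent(step_a, "A", f.group))
        a_flips = sorted((f for f in flips if f.dish == "A"), key=lambda f: f.step)
        g = GROUP_I
        i = 0
        for step in active:
            while i < len(a_flips) and a_flips[i].step == step:
                g = a_flips[i].group
                i += 1
            patterns["A"][step - 1] = pat[g]
        # consistent-looking TM vectors and ratios
        for d in ("A", "B"):
            tms[d][active - 1] = 100
            lit = patterns[d][active - 1]
            tms[d][active - 1] += 80 * lit * (1 if d == "B" else 0)
            tms[d][active - 1] -= 60 * lit * (1 if d == "A" else 0)
        meta["true_period_min"] = 2 * half_period_steps * cycle_s / 60.0
        meta["true_delay_min"] = delay_steps * cycle_s / 60.0
        flips.sort(key=lambda f: (f.step, f.dish))
    elif scenario == "fixed_pattern":
        chosen = pattern if pattern is not None else group_pattern(GROUP_I, layout)
        for d in ("A", "B"):
            patterns[d][active - 1] = np.asarray(chosen, dtype=bool)
        meta["pattern"] = np.asarray(chosen, dtype=bool)
    elif scenario == "random_patterns":
        for d in ("A", "B"):
            for step in active:
                lit = rng.choice(nsq, size=12, replace=False)
                patterns[d][step - 1, lit] = True
    else:
        raise ConfigurationError(f"unknown fixture scenario {scenario!r}")

    return ExperimentLog(cycle_s=cycle_s, warmup_steps=warmup_steps,
                         cooldown_steps=cooldown_steps, patterns=patterns,
                         tm=tms, ratio=ratios, flips=flips,
                         algorithm="fixture", meta=meta)
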