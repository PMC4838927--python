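"""Stochastic per-cell behavioural models for the two microalgae.

Dish A holds *Euglena gracilis*-like agents: persistent swimmers
(30-90 um/s, body 20-100 um) that respond photophobically to blue light
by switching to on-site tumbling — modelled as isotropic Brownian drift
with randomised heading — and that tend to turn back at the border of an
illuminated square.  Dish B holds *Chlamydomonas reinhardtii*-like
agents (20-100 um/s, body 10-30 um) that rest in darkness and are
photo-activated: resting cells resume swimming under blue light at rate
``k_act`` and active cells settle back to rest in darkness at rate
``k_rest``.  Because the stimulus light enters from below, activated
cells rarely find the passages out of an illuminated square; this is
collapsed into a 2-D exit-damping probability.

Populations are stored as structure-of-arrays and advanced with
vectorised sub-ticks (default 0.147 s, ten per 1.47 s feedback cycle; a
90 um/s cell then moves at most ~13 um per tick, well below the square
and passage scales).  Per-cell speeds and body sizes are drawn once at
initialisation: cell-to-cell variability is a feature of the system, not
noise to be averaged away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .geometry import GridLayout, region_code, _SQ_HI, _HP_BASE, _VP_BASE

# printed trait ranges, um and um/s
EUGLENA_SPEED_RANGE = (30.0, 90.0)
EUGLENA_LENGTH_RANGE = (20.0, 100.0)
CHLAMY_SPEED_RANGE = (20.0, 100.0)
CHLAMY_DIAMETER_RANGE = (10.0, 30.0)

#: Euglena body width as a fraction of body length (slender spindle shape)
EUGLENA_ASPECT = 0.2


@dataclass
class BehaviorParams:
    """Free behavioural parameters of both species.

    The Euglena escape parameters (``euglena_tumble_D``,
    ``euglena_border_turn_prob``) and the Chlamydomonas switching rates
    (``chlamy_k_act``, ``chlamy_k_rest``) are calibration targets; the
    shipped defaults were fitted so that the closed-loop simulation
    reproduces the printed oscillation periods and phase delay (see
    calibration module and docs/methods.md).
    """

    #: effective translational diffusivity while tumbling, um^2/s
    euglena_tumble_D: float = 950.0
    #: probability of turning back per attempted entry into a lit square
    euglena_border_turn_prob: float = 0.4
    #: heading noise of a swimming Euglena, rad/sqrt(s)
    euglena_heading_noise: float = 0.3
    #: tumbling stroke width as a fraction of body width (a tumbling cell
    #: pivots nearly on-site, so its trace is narrower than a full run)
    euglena_tumble_stroke_frac: float = 0.7
    #: light-driven resting -> active rate, 1/s
    chlamy_k_act: float = 0.055
    #: dark active -> resting rate, 1/s
    chlamy_k_rest: float = 0.055
    #: success probability of a passage-crossing attempt out of a lit square
    chlamy_exit_damping: float = 0.1
    #: heading noise of an active Chlamydomonas, rad/sqrt(s)
    chlamy_heading_noise: float = 1.5
    #: heading jitter added on wall reflection, rad (uniform +-)
    wall_turn_jitter: float = 0.3
    #: whether resting Chlamydomonas mark their static body footprint
    include_resting_footprint: bool = True
    #: fraction of Chlamydomonas initialised resting
    chlamy_resting_fraction_init: float = 0.5

    def validate(self) -> "BehaviorParams":
        for name in ("euglena_tumble_D", "euglena_heading_noise",
                     "chlamy_k_act", "chlamy_k_rest", "chlamy_heading_noise",
                     "wall_turn_jitter", "euglena_tumble_stroke_frac"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("euglena_border_turn_prob", "chlamy_exit_damping",
                     "chlamy_resting_fraction_init"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        return self


@dataclass
class EuglenaPopulation:
    """Structure-of-arrays state of the dish-A population."""

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray        # um/s, per-cell constant
    body_length: np.ndarray  # um
    body_width: np.ndarray   # um
    tumbling: np.ndarray     # bool; False = swimming

    @property
    def n(self) -> int:
        return self.x.size

    def copy(self) -> "EuglenaPopulation":
        return EuglenaPopulation(*(getattr(self, f).copy() for f in
                                   ("x", "y", "heading", "speed",
                                    "body_length", "body_width", "tumbling")))


@dataclass
class ChlamyPopulation:
    """Structure-of-arrays state of the dish-B population."""

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray     # um/s, per-cell constant
    diameter: np.ndarray  # um
    active: np.ndarray    # bool; False = resting

    @property
    def n(self) -> int:
        return self.x.size

    def copy(self) -> "ChlamyPopulation":
        return ChlamyPopulation(*(getattr(self, f).copy() for f in
                                  ("x", "y", "heading", "speed", "diameter", "active")))


def _uniform_square_positions(n: int, layout: GridLayout, rng: np.random.Generator):
    """Positions uniform over the union of square interiors."""
    sq = rng.integers(0, layout.n_squares, size=n)
    row, col = sq // layout.cols, sq % layout.cols
    x = col * layout.pitch + rng.uniform(0.0, layout.square_width, size=n)
    y = row * layout.pitch + rng.uniform(0.0, layout.square_width, size=n)
    return x, y


def init_population(species: str, n: int, layout: GridLayout,
                    rng: np.random.Generator,
                    params: BehaviorParams | None = None):
    """Draw an initial population with uniform positions and trait ranges."""
    if n <= 0:
        raise ConfigurationError(f"population size must be positive, got {n}")
    params = params or BehaviorParams()
    x, y = _uniform_square_positions(n, layout, rng)
    heading = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if species == "euglena":
        speed = rng.uniform(*EUGLENA_SPEED_RANGE, size=n)
        length = rng.uniform(*EUGLENA_LENGTH_RANGE, size=n)
        return EuglenaPopulation(x, y, heading, speed, length,
                                 EUGLENA_ASPECT * length,
                                 np.zeros(n, dtype=bool))
    if species == "chlamy":
        speed = rng.uniform(*CHLAMY_SPEED_RANGE, size=n)
        diameter = rng.uniform(*CHLAMY_DIAMETER_RANGE, size=n)
        active = rng.random(n) >= params.chlamy_resting_fraction_init
        return ChlamyPopulation(x, y, heading, speed, diameter, active)
    raise ConfigurationError(f"unknown species {species!r}")


# ----------------------------------------------------------------------
# wall handling

def _wall_bounds(code: np.ndarray, layout: GridLayout):
    """Axis-aligned wall planes of each point's current region.

    Open sides (passage mouths along the passage axis) are +-inf.
    """
    P = layout.pitch
    W = layout.square_width
    a0, a1 = layout.passage_lo, layout.passage_hi
    n = code.size
    xlo = np.full(n, -np.inf)
    xhi = np.full(n, np.inf)
    ylo = np.full(n, -np.inf)
    yhi = np.full(n, np.inf)

    sq = (code >= 1) & (code <= _SQ_HI)
    if sq.any():
        idx = code[sq] - 1
        r, c = idx // layout.cols, idx % layout.cols
        xlo[sq] = c * P
        xhi[sq] = c * P + W
        ylo[sq] = r * P
        yhi[sq] = r * P + W
    hp = (code >= _HP_BASE) & (code < _VP_BASE)
    if hp.any():
        k = code[hp] - _HP_BASE
        r = k // (layout.cols - 1)
        ylo[hp] = r * P + a0
        yhi[hp] = r * P + a1
    vp = code >= _VP_BASE
    if vp.any():
        k = code[vp] - _VP_BASE
        c = k % layout.cols
        xlo[vp] = c * P + a0
        xhi[vp] = c * P + a1
    return xlo, xhi, ylo, yhi


def enforce_walls(cur_x, cur_y, prop_x, prop_y, heading, layout: GridLayout,
                  rng: np.random.Generator, jitter: float = 0.3):
    """Resolve proposed moves against the chamber walls.

    Moves ending inside a square or passage are accepted; moves through
    a wall are specularly reflected about the crossed wall plane with a
    uniform heading jitter of +-``jitter`` rad.  If the reflected point
    is still outside the interior (corner cuts), the agent stays put and
    reverses.  The function is total: the returned positions are always
    inside the interior provided the current positions were.

    Returns ``(x, y, heading, reflected_mask)`` (new arrays).
    """
    prop_x = np.asarray(prop_x, dtype=np.float64).copy()
    prop_y = np.asarray(prop_y, dtype=np.float64).copy()
    heading = np.asarray(heading, dtype=np.float64).copy()
    code_p = region_code(prop_x, prop_y, layout)
    bad = code_p <= 0
    if not bad.any():
        return prop_x, prop_y, heading, bad
    b = np.flatnonzero(bad)
    cx, cy = np.asarray(cur_x)[b], np.asarray(cur_y)[b]
    px, py = prop_x[b], prop_y[b]
    ccode = region_code(cx, cy, layout)
    xlo, xhi, ylo, yhi = _wall_bounds(ccode, layout)
    x_violates = region_code(px, cy, layout) <= 0
    y_violates = region_code(cx, py, layout) <= 0
    nx, ny = px.copy(), py.copy()
    over = x_violates & (px >= xhi)
    nx[over] = 2.0 * xhi[over] - px[over]
    under = x_violates & (px < xlo)
    nx[under] = 2.0 * xlo[under] - px[under]
    over = y_violates & (py >= yhi)
    ny[over] = 2.0 * yhi[over] - py[over]
    under = y_violates & (py < ylo)
    ny[under] = 2.0 * ylo[under] - py[under]
    # corner cut (diagonal through a convex corner): no single wall plane
    corner = ~x_violates & ~y_violates
    nx[corner], ny[corner] = cx[corner], cy[corner]
    # verify; freeze anything still outside
    still = region_code(nx, ny, layout) <= 0
    nx[still], ny[still] = cx[still], cy[still]
    # heading: negate the reflected component(s); reversal for freezes
    vx = np.cos(heading[b])
    vy = np.sin(heading[b])
    flip_x = x_violates | corner | still
    flip_y = y_violates | corner | still
    vx[flip_x] *= -1.0
    vy[flip_y] *= -1.0
    heading[b] = np.arctan2(vy, vx) + rng.uniform(-jitter, jitter, size=b.size)
    prop_x[b], prop_y[b] = nx, ny
    return prop_x, prop_y, heading, bad


# ----------------------------------------------------------------------
# species steps (vectorised over the population; one sub-tick)

def _lit_at(code: np.ndarray, lit: np.ndarray) -> np.ndarray:
    """Lit flag of each point's square (passages/walls are never lit)."""
    sq = (code >= 1) & (code <= _SQ_HI)
    out = np.zeros(code.shape, dtype=bool)
    out[sq] = lit[code[sq] - 1]
    return out


def step_euglena(pop: EuglenaPopulation, lit: np.ndarray, layout: GridLayout,
                 params: BehaviorParams, dt: float, rng: np.random.Generator
                 ) -> EuglenaPopulation:
    """Advance the Euglena population by one sub-tick (in place).

    Cells in illuminated squares tumble: heading randomised, position
    perturbed by isotropic Brownian drift with <|dx|^2> = 4*D*dt.  Cells
    in darkness swim ballistically with weak heading noise; a swimmer
    whose step would enter an illuminated square turns back at the
    illumination border with probability ``euglena_border_turn_prob``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    n = pop.n
    code = region_code(pop.x, pop.y, layout)
    lit_here = _lit_at(code, lit)
    pop.tumbling = lit_here.copy()
    swim = ~lit_here

    heading = pop.heading.copy()
    heading[swim] += rng.normal(0.0, params.euglena_heading_noise * np.sqrt(dt),
                                size=int(swim.sum()))
    heading[lit_here] = rng.uniform(0.0, 2.0 * np.pi, size=int(lit_here.sum()))

    prop_x = pop.x.copy()
    prop_y = pop.y.copy()
    step = pop.speed[swim] * dt
    prop_x[swim] += step * np.cos(heading[swim])
    prop_y[swim] += step * np.sin(heading[swim])
    sigma = np.sqrt(2.0 * params.euglena_tumble_D * dt)
    k = int(lit_here.sum())
    if k:
        prop_x[lit_here] += rng.normal(0.0, sigma, size=k)
        prop_y[lit_here] += rng.normal(0.0, sigma, size=k)

    # photophobic border turning (swimmers entering a lit square)
    dest = region_code(prop_x, prop_y, layout)
    dest_sq = (dest >= 1) & (dest <= _SQ_HI)
    entering_lit = swim & dest_sq & _lit_at(dest, lit) & (dest != code)
    if entering_lit.any():
        turn = entering_lit & (rng.random(n) < params.euglena_border_turn_prob)
        if turn.any():
            prop_x[turn] = pop.x[turn]
            prop_y[turn] = pop.y[turn]
            # reflect heading off the border; crossings happen through
            # passages, so the border normal follows the passage axis
            ccode = code[turn]
            hpass = (ccode >= _HP_BASE) & (ccode < _VP_BASE)
            vx = np.cos(heading[turn])
            vy = np.sin(heading[turn])
            vx[hpass] *= -1.0           # vertical border of an h-passage
            vy[~hpass] *= -1.0          # horizontal border otherwise
            heading[turn] = (np.arctan2(vy, vx)
                             + rng.uniform(-params.wall_turn_jitter,
                                           params.wall_turn_jitter,
                                           size=int(turn.sum())))

    x, y, heading, _ = enforce_walls(pop.x, pop.y, prop_x, prop_y, heading,
                                     layout, rng, jitter=params.wall_turn_jitter)
    pop.x, pop.y, pop.heading = x, y, heading
    return pop


def step_chlamy(pop: ChlamyPopulation, lit: np.ndarray, layout: GridLayout,
                params: BehaviorParams, dt: float, rng: np.random.Generator
                ) -> ChlamyPopulation:
    """Advance the Chlamydomonas population by one sub-tick (in place).

    Resting cells in illuminated squares wake at rate ``k_act``; active
    cells in darkness rest at rate ``k_rest``.  Active cells random-walk
    (heading noise + wall reflection); while their square is lit,
    passage-crossing attempts succeed only with probability
    ``chlamy_exit_damping``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    n = pop.n
    code = region_code(pop.x, pop.y, layout)
    lit_here = _lit_at(code, lit)

    u = rng.random(n)
    wake = (~pop.active) & lit_here & (u < -np.expm1(-params.chlamy_k_act * dt))
    sleep = pop.active & (~lit_here) & (u < -np.expm1(-params.chlamy_k_rest * dt))
    active = (pop.active | wake) & ~sleep
    pop.active = active

    heading = pop.heading.copy()
    heading[wake] = rng.uniform(0.0, 2.0 * np.pi, size=int(wake.sum()))
    heading[active] += rng.normal(0.0, params.chlamy_heading_noise * np.sqrt(dt),
                                  size=int(active.sum()))

    prop_x = pop.x.copy()
    prop_y = pop.y.copy()
    step = pop.speed[active] * dt
    prop_x[active] += step * np.cos(heading[active])
    prop_y[active] += step * np.sin(heading[active])

    # photo-activated cells fail to find the exits of a lit square
    dest = region_code(prop_x, prop_y, layout)
    attempt = active & lit_here & (dest != code)
    if attempt.any():
        blocked = attempt & (rng.random(n) >= params.chlamy_exit_damping)
        if blocked.any():
            prop_x[blocked] = pop.x[blocked]
            prop_y[blocked] = pop.y[blocked]
            heading[blocked] = (heading[blocked] + np.pi
                                + rng.uniform(-params.wall_turn_jitter,
                                              params.wall_turn_jitter,
                                              size=int(blocked.sum())))

    x, y, heading, _ = enforce_walls(pop.x, pop.y, prop_x, prop_y, heading,
                                     layout, rng, jitter=params.wall_turn_jitter)
    pop.x, pop.y, pop.heading = x, y, heading
    return pop


# ----------------------------------------------------------------------
# cycle advancement with trajectory recording

def advance_cycle_euglena(pop: EuglenaPopulation, lit: np.ndarray,
                          layout: GridLayout, params: BehaviorParams,
                          dt: float, n_ticks: int, rng: np.random.Generator):
    """Advance one feedback cycle; return (polylines, per-segment stroke widths)."""
    traj = np.empty((pop.n, n_ticks + 1, 2), dtype=np.float64)
    widths = np.empty((pop.n, n_ticks), dtype=np.float64)
    traj[:, 0, 0] = pop.x
    traj[:, 0, 1] = pop.y
    tumble_w = params.euglena_tumble_stroke_frac * pop.body_width
    for t in range(n_ticks):
        step_euglena(pop, lit, layout, params, dt, rng)
        traj[:, t + 1, 0] = pop.x
        traj[:, t + 1, 1] = pop.y
        widths[:, t] = np.where(pop.tumbling, tumble_w, pop.body_width)
    return traj, widths


def advance_cycle_chlamy(pop: ChlamyPopulation, lit: np.ndarray,
                         layout: GridLayout, params: BehaviorParams,
                         dt: float, n_ticks: int, rng: np.random.Generator):
    """Advance one feedback cycle; return (polylines, per-segment stroke widths).

    Resting cells keep their position; their zero-length segments ink
    only the static body footprint (or nothing if the resting footprint
    is disabled).
    """
    traj = np.empty((pop.n, n_ticks + 1, 2), dtype=np.float64)
    widths = np.empty((pop.n, n_ticks), dtype=np.float64)
    traj[:, 0, 0] = pop.x
    traj[:, 0, 1] = pop.y
    rest_w = pop.diameter if params.include_resting_footprint else np.full(pop.n, -1.0)
    for t in range(n_ticks):
        step_chlamy(pop, lit, layout, params, dt, rng)
        traj[:, t + 1, 0] = pop.x
        traj[:, t + 1, 1] = pop.y
        widths[:, t] = np.where(pop.active, pop.diameter, rest_w)
    return traj, widths


def population_to_frame(pop):
    """Dump a population to a DataFrame (debugging/inspection)."""
    import pandas as pd

    base = {"id": np.arange(pop.n), "x_um": pop.x, "y_um": pop.y,
            "heading_rad": pop.heading, "speed_um_s": pop.speed}
    if isinstance(pop, EuglenaPopulation):
        base |= {"body_length_um": pop.body_length,
                 "body_width_um": pop.body_width,
                 "mode": np.where(pop.tumbling, "tumbling", "swimming")}
    else:
        base |= {"diameter_um": pop.diameter,
                 "mode": np.where(pop.active, "active", "resting")}
    return pd.DataFrame(base)
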