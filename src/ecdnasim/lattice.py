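"""On-lattice stochastic engine for ecDNA-driven tumor growth.

The model: tumor cells occupy sites of a 2D square lattice. A cell divides at
rate 1 if it carries no ecDNA and at rate 1+s if it carries one or more copies
(constant selection: fitness depends on presence, not copy number), and dies at
rate d. Events are drawn by rejection-free kinetic Monte Carlo (Bortz--
Kalos--Lebowitz style): each drawn event is executed and advances time by an
exponential increment with mean 1/(total rate). At division the mother's
ecDNA copies duplicate and partition binomially between the daughters; to make
room, the mother may push the contiguous run of neighbors along one of the 8
lattice rays, provided an empty site lies within q steps (q=1 is strict
boundary growth, q=inf removes the spatial constraint). A division with no
eligible ray is consumed without a birth.

`run_to_size` drives a compiled kernel; the finer-grained operations
(`init_tumor`, `select_event`, `apply_event`, ...) expose the same rules
step-by-step on a `TumorState` for inspection and testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np

from . import _kernels
from ._kernels import (
    STATUS_BOUNDARY,
    STATUS_EXTINCT,
    STATUS_MAX_EVENTS,
    STATUS_REACHED,
    _DX,
    _DY,
)

__all__ = [
    "ConfigurationError",
    "LatticeBoundaryError",
    "SimulationConfig",
    "TumorState",
    "Event",
    "Placement",
    "init_tumor",
    "cell_division_rate",
    "select_event",
    "find_division_site",
    "segregate_ecdna",
    "apply_event",
    "run_to_size",
]

INFINITE_Q = math.inf

_STATUS_NAMES = {
    STATUS_REACHED: "reached",
    STATUS_EXTINCT: "extinct",
    STATUS_BOUNDARY: "boundary",
    STATUS_MAX_EVENTS: "max_events",
}


class ConfigurationError(ValueError):
    """Invalid simulation parameterization."""


class LatticeBoundaryError(RuntimeError):
    """The tumor reached the lattice boundary; enlarge ``lattice_span``."""


def _normalize_q(q) -> float:
    if isinstance(q, str):
        if q.lower() in ("inf", "infinite", "infinity"):
            return INFINITE_Q
        q = float(q)
    if q == INFINITE_Q:
        return INFINITE_Q
    qi = int(q)
    if qi != q or qi < 1:
        raise ConfigurationError(f"q must be a positive integer or 'inf', got {q!r}")
    return qi


def default_span(n_final: int) -> int:
    """Half-width comfortably holding a compact tumor of n_final cells."""
    return int(math.ceil(2.0 * math.sqrt(n_final / math.pi))) + 16


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one tumor run.

    k : ecDNA copies in the founder cell.
    s : selection coefficient; ecDNA-positive cells divide at rate 1+s (> -1).
    q : pushing range in lattice units (>=1), or inf for no spatial constraint.
    d : death rate per cell (0 <= d < 1, below the base division rate).
    n_final : target population size.
    seed : RNG seed; a run is reproducible from (config, seed).
    lattice_span : half-width of the square lattice (auto-sized by default).
    """

    k: int
    s: float = 0.0
    q: Union[int, float, str] = INFINITE_Q
    d: float = 0.0
    n_final: int = 10_000
    seed: int = 0
    lattice_span: Optional[int] = None

    def __post_init__(self):
        if int(self.k) != self.k or self.k < 0:
            raise ConfigurationError(f"k must be a non-negative integer, got {self.k!r}")
        if self.s <= -1:
            raise ConfigurationError(f"s must exceed -1, got {self.s!r}")
        object.__setattr__(self, "q", _normalize_q(self.q))
        if not 0 <= self.d < 1:
            raise ConfigurationError(f"d must satisfy 0 <= d < 1, got {self.d!r}")
        if int(self.n_final) != self.n_final or self.n_final < 1:
            raise ConfigurationError(f"n_final must be a positive integer, got {self.n_final!r}")
        if self.lattice_span is not None:
            span = int(self.lattice_span)
            if span < 1:
                raise ConfigurationError("lattice_span must be positive")
            if (2 * span + 1) ** 2 < self.n_final:
                raise ConfigurationError(
                    f"lattice_span={span} cannot hold n_final={self.n_final} cells"
                )

    @property
    def span(self) -> int:
        return int(self.lattice_span) if self.lattice_span is not None else default_span(self.n_final)

    def q_steps(self) -> int:
        """Pushing range as a finite step count on this lattice."""
        L = 2 * self.span + 1
        return L if self.q == INFINITE_Q else min(int(self.q), L)

    def max_events(self) -> int:
        return 400 * int(self.n_final) + 100_000

    def to_dict(self) -> dict:
        q = "inf" if self.q == INFINITE_Q else int(self.q)
        return {"k": int(self.k), "s": float(self.s), "q": q, "d": float(self.d),
                "n_final": int(self.n_final), "seed": int(self.seed),
                "lattice_span": self.span}


@dataclass
class Event:
    """One drawn kinetic Monte Carlo event."""

    kind: str  # "division" | "death"
    cell: int
    dt: float


@dataclass
class Placement:
    """An eligible daughter placement: ray direction, distance to the empty
    site, and the contiguous run of cell indices shifted one step outward."""

    direction: Tuple[int, int]
    distance: int
    run: list


class TumorState:
    """Lattice occupancy plus per-cell ecDNA copy counts.

    Coordinates are integer offsets from the founder at (0, 0). ``copies`` is
    (n,) for single-species runs and (n, 2) for two-type runs.
    """

    def __init__(self, x, y, copies, *, span=None, time=0.0, status="reached",
                 config=None, seed=None, rng=None, capacity=None, info=None):
        x = np.asarray(x, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        copies = np.asarray(copies, dtype=np.int64)
        n = len(x)
        if len(y) != n or len(copies) != n:
            raise ValueError("coordinate and copy arrays must have equal length")
        if copies.ndim == 1:
            if np.any(copies < 0):
                raise ValueError("copy counts must be non-negative")
        cap = max(capacity or 0, n)
        self._x = np.zeros(cap, dtype=np.int64)
        self._y = np.zeros(cap, dtype=np.int64)
        shape = (cap,) if copies.ndim == 1 else (cap, copies.shape[1])
        self._copies = np.zeros(shape, dtype=np.int64)
        self._x[:n] = x
        self._y[:n] = y
        self._copies[:n] = copies
        self._n = n
        if span is None:
            span = int(max(np.max(np.abs(x), initial=0), np.max(np.abs(y), initial=0))) + 4
        self.span = int(span)
        self.time = float(time)
        self.status = status
        self.config = config
        self.seed = seed
        self.info = dict(info or {})
        self._rng = rng
        self._grid = None

    # -- views ------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self._n

    @property
    def xs(self) -> np.ndarray:
        return self._x[: self._n]

    @property
    def ys(self) -> np.ndarray:
        return self._y[: self._n]

    @property
    def copies(self) -> np.ndarray:
        return self._copies[: self._n]

    @property
    def founder_site(self) -> Tuple[int, int]:
        return (0, 0)

    @property
    def two_species(self) -> bool:
        return self._copies.ndim == 2

    def total_per_cell(self) -> np.ndarray:
        c = self.copies
        return c.sum(axis=1) if c.ndim == 2 else c

    @property
    def total_copies(self) -> int:
        return int(self.copies.sum())

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.total_per_cell() > 0))

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)
        return self._rng

    # -- occupancy grid ----------------------------------------------------
    def grid(self) -> np.ndarray:
        """int32 occupancy grid; entry = cell index or -1. Built lazily."""
        if self._grid is None:
            L = 2 * self.span + 1
            g = np.full((L, L), -1, dtype=np.int32)
            gx = self.xs + self.span
            gy = self.ys + self.span
            if np.any(gx < 0) or np.any(gx >= L) or np.any(gy < 0) or np.any(gy >= L):
                raise LatticeBoundaryError("cells outside the lattice span")
            g[gx, gy] = np.arange(self._n, dtype=np.int32)
            self._grid = g
        return self._grid

    def occupancy(self) -> dict:
        """Mapping (x, y) -> cell index (founder-origin coordinates)."""
        return {(int(x), int(y)): i for i, (x, y) in enumerate(zip(self.xs, self.ys))}

    def validate(self) -> None:
        """Check occupancy integrity: one live cell per occupied site."""
        occ = self.occupancy()
        assert len(occ) == self._n, "duplicate coordinates"
        g = self.grid()
        assert int((g >= 0).sum()) == self._n
        assert np.all(self.total_per_cell() >= 0)

    # -- internal mutation (op path) ---------------------------------------
    def _remove_cell(self, i: int) -> None:
        g = self.grid()
        g[self._x[i] + self.span, self._y[i] + self.span] = -1
        last = self._n - 1
        if i != last:
            self._x[i] = self._x[last]
            self._y[i] = self._y[last]
            self._copies[i] = self._copies[last]
            g[self._x[i] + self.span, self._y[i] + self.span] = i
        self._n = last

    def _add_cell(self, x: int, y: int, copies) -> int:
        if self._n >= len(self._x):
            grow = max(64, len(self._x))
            self._x = np.concatenate([self._x, np.zeros(grow, np.int64)])
            self._y = np.concatenate([self._y, np.zeros(grow, np.int64)])
            pad_shape = (grow,) if self._copies.ndim == 1 else (grow, self._copies.shape[1])
            self._copies = np.concatenate([self._copies, np.zeros(pad_shape, np.int64)])
        i = self._n
        self._x[i] = x
        self._y[i] = y
        self._copies[i] = copies
        self.grid()[x + self.span, y + self.span] = i
        self._n += 1
        return i


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def init_tumor(config: SimulationConfig) -> TumorState:
    """A single founder cell with k copies at the lattice origin, time 0."""
    state = TumorState(
        [0], [0], [config.k], span=config.span, time=0.0, status="growing",
        config=config, seed=config.seed, rng=np.random.default_rng(config.seed),
        capacity=config.n_final + 1,
    )
    state.grid()
    return state


def cell_division_rate(copy_counts, s: float) -> float:
    """Constant-selection division rate: 1 for ecDNA-free cells, 1+s otherwise.

    ``copy_counts`` may be a single count or one count per species; only the
    total's positivity matters (copy-number independence).
    """
    if s <= -1:
        raise ConfigurationError(f"s must exceed -1, got {s!r}")
    if isinstance(copy_counts, Iterable) and not isinstance(copy_counts, (str, bytes)):
        total = int(np.sum(np.asarray(list(copy_counts))))
    else:
        total = int(copy_counts)
    if total < 0:
        raise ValueError("copy counts must be non-negative")
    return 1.0 if total == 0 else 1.0 + float(s)


def _division_rates(state: TumorState, config: SimulationConfig) -> np.ndarray:
    pos = state.total_per_cell() > 0
    return np.where(pos, 1.0 + config.s, 1.0)


def select_event(state: TumorState, config: SimulationConfig) -> Event:
    """Draw the next event proportional to per-cell rates, with exponential dt."""
    n = state.n_cells
    if n < 1:
        raise RuntimeError("cannot select an event in an empty population")
    rates = _division_rates(state, config)
    r_div = float(rates.sum())
    r_death = config.d * n
    r_tot = r_div + r_death
    if r_tot <= 0:
        raise RuntimeError("total event rate is non-positive")
    rng = state.rng
    dt = float(rng.exponential(1.0 / r_tot))
    if rng.random() * r_tot < r_death:
        return Event("death", int(rng.integers(n)), dt)
    cell = int(rng.choice(n, p=rates / r_div))
    return Event("division", cell, dt)


def find_division_site(state: TumorState, mother: int, q) -> Optional[Placement]:
    """Uniformly choose an eligible Moore ray for the daughter, or None.

    A ray is eligible if its nearest empty site lies within q steps; the
    returned placement carries the contiguous run of cells to shift one step
    outward (empty for an adjacent empty site).
    """
    if not 0 <= mother < state.n_cells:
        raise IndexError("mother cell is not live")
    q = _normalize_q(q)
    g = state.grid()
    L = g.shape[0]
    qe = L if q == INFINITE_Q else min(int(q), L)
    gx = int(state.xs[mother]) + state.span
    gy = int(state.ys[mother]) + state.span
    dist = _kernels.eligible_directions(g, gx, gy, qe)
    eligible = np.flatnonzero(dist > 0)
    if len(eligible) == 0:
        return None
    d = int(state.rng.choice(eligible))
    t = int(dist[d])
    run = [int(g[gx + j * _DX[d], gy + j * _DY[d]]) for j in range(1, t)]
    return Placement(direction=(int(_DX[d]), int(_DY[d])), distance=t, run=run)


def segregate_ecdna(copies: int, rng: Optional[np.random.Generator] = None):
    """Binomial partitioning: duplicate to 2*copies, split Binomial(2c, 1/2)."""
    copies = int(copies)
    if copies < 0:
        raise ValueError(f"copy count must be non-negative, got {copies}")
    if copies == 0:
        return 0, 0
    rng = rng or np.random.default_rng()
    total = 2 * copies
    a = int(rng.binomial(total, 0.5))
    return a, total - a


def apply_event(state: TumorState, event: Event, config: SimulationConfig) -> TumorState:
    """Execute an event in place: death frees the site; division pushes, places
    the daughter, and binomially partitions the mother's duplicated copies.
    Time advances by event.dt in every case, including blocked divisions."""
    if not 0 <= event.cell < state.n_cells:
        raise RuntimeError(f"event refers to dead cell {event.cell}")
    state.time += event.dt
    if event.kind == "death":
        state._remove_cell(event.cell)
        return state
    if event.kind != "division":
        raise ValueError(f"unknown event kind {event.kind!r}")
    placement = find_division_site(state, event.cell, config.q)
    if placement is None:
        return state  # blocked: event consumed with no birth
    dx, dy = placement.direction
    g = state.grid()
    gx = int(state.xs[event.cell]) + state.span
    gy = int(state.ys[event.cell]) + state.span
    L = g.shape[0]
    fx = gx + placement.distance * dx
    fy = gy + placement.distance * dy
    if fx <= 0 or fx >= L - 1 or fy <= 0 or fy >= L - 1:
        raise LatticeBoundaryError("push reached the lattice boundary")
    # shift the occupied run one step outward, far end first
    for j in range(placement.distance - 1, 0, -1):
        ci = placement.run[j - 1]
        g[gx + (j + 1) * dx, gy + (j + 1) * dy] = ci
        g[gx + j * dx, gy + j * dy] = -1
        state._x[ci] += dx
        state._y[ci] += dy
    a, b = segregate_ecdna(int(state.copies[event.cell]), state.rng)
    state._copies[event.cell] = a
    state._add_cell(int(state.xs[event.cell]) + dx, int(state.ys[event.cell]) + dy, b)
    return state


def run_to_size(config: SimulationConfig) -> TumorState:
    """Grow a tumor from one founder to n_final cells (kernel-accelerated).

    Extinction (possible when d > 0) is returned as a state with
    ``status == 'extinct'``, not raised.
    """
    status, n, xs, ys, copies, t, events = _kernels.run_single(
        int(config.k), float(config.s), config.q_steps(), float(config.d),
        int(config.n_final), config.span, int(config.seed), config.max_events(),
    )
    if status == STATUS_BOUNDARY:
        raise LatticeBoundaryError(
            f"tumor reached the lattice boundary (span={config.span}); increase lattice_span"
        )
    if status == STATUS_MAX_EVENTS:
        raise RuntimeError("event budget exhausted before reaching n_final")
    return TumorState(
        xs - config.span, ys - config.span, copies, span=config.span, time=t,
        status=_STATUS_NAMES[status], config=config, seed=config.seed,
        info={"events": int(events)},
    )
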