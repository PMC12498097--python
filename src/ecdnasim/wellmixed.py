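"""Non-spatial (well-mixed) Gillespie growth with binomial ecDNA segregation.

Identical division, death and segregation rules to the lattice engine, with no
spatial constraint — every division succeeds. This is the q -> infinity limit
of the spatial model and doubles as an independent oracle for it. An optional
fixed-passage mode subsamples the population back to a set size whenever it
reaches a trigger size, emulating serial cell-culture passaging (under which,
unlike pure growth, a neutral ecDNA can be lost from the population entirely).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .lattice import ConfigurationError

__all__ = [
    "WellMixedPopulation",
    "run_well_mixed",
    "run_well_mixed_two_type",
    "positive_fraction_trajectory",
]


@dataclass
class WellMixedPopulation:
    """Final population plus (optionally) its recorded trajectory.

    ``copies`` is (n,) for single-species runs, (n, 2) for two-type runs.
    ``history`` has columns time, n_cells, positive_fraction, mean_copies
    (and heteroplasmy for two-type runs), one row per recorded event.
    """

    copies: np.ndarray
    time: float
    status: str
    seed: Optional[int] = None
    history: Optional[pd.DataFrame] = None
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.copies)

    def total_per_cell(self) -> np.ndarray:
        c = self.copies
        return c.sum(axis=1) if c.ndim == 2 else c

    @property
    def positive_fraction(self) -> float:
        if self.n_cells == 0:
            return 0.0
        return float(np.mean(self.total_per_cell() > 0))

    @property
    def mean_copies(self) -> float:
        if self.n_cells == 0:
            return 0.0
        return float(self.total_per_cell().mean())


def _validate(k, s, n_final, d):
    if int(k) != k or k < 0:
        raise ConfigurationError(f"k must be a non-negative integer, got {k!r}")
    if s <= -1:
        raise ConfigurationError(f"s must exceed -1, got {s!r}")
    if int(n_final) != n_final or n_final < 1:
        raise ConfigurationError(f"n_final must be a positive integer, got {n_final!r}")
    if not 0 <= d < 1:
        raise ConfigurationError(f"d must satisfy 0 <= d < 1, got {d!r}")


def run_well_mixed(
    k: int,
    s: float = 0.0,
    n_final: int = 1000,
    *,
    d: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    record_history: bool = True,
    passage_trigger: Optional[int] = None,
    passage_to: Optional[int] = None,
    n_passages: Optional[int] = None,
    max_events: Optional[int] = None,
) -> WellMixedPopulation:
    """Grow a well-mixed population from one founder with k copies to n_final.

    Division at rate 1 (ecDNA-free) or 1+s; optional death at rate d; binomial
    segregation of duplicated copies at each division. If ``passage_trigger``
    is set, the population is uniformly subsampled to ``passage_to`` cells
    whenever it reaches the trigger size (under which, unlike pure growth,
    the last ecDNA copy can be lost); ``n_passages`` stops the run after that
    many passages with status 'passaged'. Extinction is returned as a
    population with status 'extinct'.
    """
    _validate(k, s, n_final, d)
    if (passage_trigger is None) != (passage_to is None):
        raise ConfigurationError("passage_trigger and passage_to must be set together")
    if passage_trigger is not None and not 0 < passage_to < passage_trigger:
        raise ConfigurationError("need 0 < passage_to < passage_trigger")
    if rng is None:
        rng = np.random.default_rng(seed)
    cap = max(n_final, passage_trigger or 0) + 1
    copies = np.zeros(cap, dtype=np.int64)
    copies[0] = k
    n = 1
    t = 0.0
    hist = [] if record_history else None
    if record_history:
        hist.append((0.0, 1, float(k > 0), float(k)))
    budget = max_events if max_events is not None else 400 * n_final + 100_000
    events = 0
    passages = 0
    status = "max_events"
    while events < budget:
        if n >= n_final:
            status = "reached"
            break
        if n <= 0:
            status = "extinct"
            break
        n_pos = int(np.count_nonzero(copies[:n]))
        r_div = n + s * n_pos
        r_tot = r_div + d * n
        t += rng.exponential(1.0 / r_tot)
        events += 1
        if rng.random() * r_tot < d * n:
            i = int(rng.integers(n))
            copies[i] = copies[n - 1]
            n -= 1
        else:
            rmax = 1.0 + max(s, 0.0)
            while True:
                i = int(rng.integers(n))
                ri = 1.0 + s if copies[i] > 0 else 1.0
                if rng.random() * rmax < ri:
                    break
            total = 2 * copies[i]
            a = rng.binomial(total, 0.5) if total > 0 else 0
            copies[i] = a
            copies[n] = total - a
            n += 1
            if passage_trigger is not None and n >= passage_trigger:
                keep = rng.choice(n, size=passage_to, replace=False)
                copies[:passage_to] = copies[keep]
                n = passage_to
                passages += 1
                if n_passages is not None and passages >= n_passages:
                    status = "passaged"
                    break
        if record_history:
            live = copies[:n]
            hist.append((t, n, float(np.mean(live > 0)), float(live.mean())))
    history = None
    if record_history:
        history = pd.DataFrame(hist, columns=["time", "n_cells", "positive_fraction", "mean_copies"])
    return WellMixedPopulation(
        copies=copies[:n].copy(), time=t, status=status, seed=seed, history=history,
        params={"k": k, "s": s, "n_final": n_final, "d": d},
    )


def run_well_mixed_two_type(
    k1: int,
    k2: int,
    s1: float = 0.0,
    s2: float = 0.0,
    *,
    rate_mode: str = "variant",
    rho: float = 0.0,
    n_final: int = 1000,
    d: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    record_history: bool = False,
) -> WellMixedPopulation:
    """Two-type well-mixed growth (wild-type/variant or two species).

    rate_mode 'variant': rate 1+s2 with any type-2 copy, 1+s1 if type-1 only,
    1 if ecDNA-free. rate_mode 'mixed': 1+s2 with both types present, 1+s1
    with exactly one, 1 if free. rho couples segregation of the two types as
    in the spatial engine (0 = independent binomial splits).
    """
    from ._kernels import cosegregate_split, seed_rng

    _validate(k1, 0.0, n_final, d)
    _validate(k2, 0.0, n_final, d)
    if s1 <= -1 or s2 <= -1:
        raise ConfigurationError("selection coefficients must exceed -1")
    if not 0 <= rho <= 1:
        raise ConfigurationError(f"rho must lie in [0, 1], got {rho!r}")
    if rate_mode not in ("variant", "mixed"):
        raise ConfigurationError(f"unknown rate_mode {rate_mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    # cosegregate_split uses the kernel RNG; seed it from this run's stream
    seed_rng(int(rng.integers(2**31 - 1)))

    def cls(a, b):
        if rate_mode == "variant":
            return 2 if b > 0 else (1 if a > 0 else 0)
        if a > 0 and b > 0:
            return 2
        return 1 if (a > 0 or b > 0) else 0

    rates = np.array([1.0, 1.0 + s1, 1.0 + s2])
    rmax = rates.max()
    cap = n_final + 1
    c = np.zeros((cap, 2), dtype=np.int64)
    c[0] = (k1, k2)
    n = 1
    t = 0.0
    hist = [] if record_history else None
    budget = 400 * n_final + 100_000
    events = 0
    status = "max_events"
    while events < budget:
        if n >= n_final:
            status = "reached"
            break
        if n <= 0:
            status = "extinct"
            break
        live = c[:n]
        cl = np.where(live[:, 1] > 0, 2, np.where(live[:, 0] > 0, 1, 0)) \
            if rate_mode == "variant" else \
            np.where((live[:, 0] > 0) & (live[:, 1] > 0), 2,
                     np.where((live[:, 0] > 0) | (live[:, 1] > 0), 1, 0))
        r_div = float(rates[cl].sum())
        r_tot = r_div + d * n
        t += rng.exponential(1.0 / r_tot)
        events += 1
        if rng.random() * r_tot < d * n:
            i = int(rng.integers(n))
            c[i] = c[n - 1]
            n -= 1
        else:
            while True:
                i = int(rng.integers(n))
                if rng.random() * rmax < rates[cls(c[i, 0], c[i, 1])]:
                    break
            a1, b1, a2, b2 = cosegregate_split(int(c[i, 0]), int(c[i, 1]), float(rho))
            c[i] = (a1, a2)
            c[n] = (b1, b2)
            n += 1
        if record_history:
            live = c[:n]
            tot = live.sum(axis=1)
            wt = live[:, 0].sum()
            allc = tot.sum()
            hist.append((t, n, float(np.mean(tot > 0)), float(tot.mean()),
                         100.0 * wt / allc if allc > 0 else np.nan))
    history = None
    if record_history:
        history = pd.DataFrame(
            hist, columns=["time", "n_cells", "positive_fraction", "mean_copies", "heteroplasmy"]
        )
    return WellMixedPopulation(
        copies=c[:n].copy(), time=t, status=status, seed=seed, history=history,
        params={"k1": k1, "k2": k2, "s1": s1, "s2": s2, "rho": rho, "rate_mode": rate_mode},
    )


def positive_fraction_trajectory(pop: WellMixedPopulation) -> pd.DataFrame:
    """(time, positive_fraction) pairs from a recorded run."""
    if pop.history is None or len(pop.history) == 0:
        raise ValueError("population has no recorded history; rerun with record_history=True")
    return pop.history[["time", "positive_fraction"]].copy()
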