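"""Two cosegregating / coselected ecDNA species in one tumor.

Some tumors carry two structurally distinct ecDNA species (different
oncogenes on different circles). Two mechanisms can couple their dynamics:

* cosegregation — correlated co-inheritance at division. After duplication to
  2*c1 and 2*c2 copies, ``round(rho * min(2c1, 2c2))`` cross-species pairs are
  formed and each pair follows a single fair coin into one daughter; unpaired
  copies segregate independently. rho=0 recovers independent binomial
  segregation, rho=1 forces equal per-species splits whenever c1 = c2.
* coselection — a fitness premium for mixed cells: division rate 1 for
  ecDNA-free cells, 1+s_p for "pure" cells (exactly one species present),
  1+s_m for "mixed" cells (both present).

Joint inference reuses the rejection-ABC machinery with one Wasserstein term
per species marginal per region, plus the mixed-cell fraction as an extra
acceptance gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import (
    ConfigurationError,
    SimulationConfig,
    TumorState,
    _STATUS_NAMES,
)
from .abc import ABCResults, ABCSettings, region_distance, wasserstein1d
from .sampling import RegionSample, core_sample, margin_samples

__all__ = [
    "TwoSpeciesConfig",
    "cosegregate",
    "two_species_rate",
    "run_two_species",
    "mixed_fraction",
    "TwoSpeciesObservedData",
    "TwoSpeciesPriorGrid",
    "TwoSpeciesABCRejection",
]


@dataclass(frozen=True)
class TwoSpeciesConfig:
    """Founder copies k1/k2, pure/mixed selection s_p/s_m, cosegregation rho."""

    k1: int
    k2: int
    s_p: float = 1.0
    s_m: float = 1.0
    rho: float = 0.0

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ConfigurationError("founder copy numbers must be non-negative")
        if self.s_p <= -1 or self.s_m <= -1:
            raise ConfigurationError("selection coefficients must exceed -1")
        if not 0 <= self.rho <= 1:
            raise ConfigurationError(f"rho must lie in [0, 1], got {self.rho!r}")


def cosegregate(c1: int, c2: int, rho: float,
                rng: Optional[np.random.Generator] = None):
    """One correlated division split: returns ((a1, a2), (b1, b2)) with
    a1+b1 = 2*c1 and a2+b2 = 2*c2 (per-species conservation)."""
    if c1 < 0 or c2 < 0:
        raise ValueError("copy counts must be non-negative")
    if not 0 <= rho <= 1:
        raise ValueError(f"rho must lie in [0, 1], got {rho!r}")
    if rng is None:
        rng = np.random.default_rng()
    # numba kernel shares this law; reseed its RNG from the caller's stream
    _kernels.seed_rng(int(rng.integers(2**31 - 1)))
    a1, b1, a2, b2 = _kernels.cosegregate_split(int(c1), int(c2), float(rho))
    return (int(a1), int(a2)), (int(b1), int(b2))


def two_species_rate(copies1: int, copies2: int, s_p: float, s_m: float) -> float:
    """1 if both species absent, 1+s_p if exactly one present, 1+s_m if both."""
    if copies1 < 0 or copies2 < 0:
        raise ValueError("copy counts must be non-negative")
    if copies1 > 0 and copies2 > 0:
        return 1.0 + float(s_m)
    if copies1 > 0 or copies2 > 0:
        return 1.0 + float(s_p)
    return 1.0


def run_two_species(tsc: TwoSpeciesConfig, config: SimulationConfig) -> TumorState:
    """Spatial run with cosegregating inheritance and pure/mixed fitness."""
    (status, n, xs, ys, c1, c2, t, events, _, _) = _kernels.run_two_type(
        int(tsc.k1), int(tsc.k2), float(tsc.s_p), float(tsc.s_m),
        1, float(tsc.rho), 0, config.q_steps(), float(config.d),
        int(config.n_final), config.span, int(config.seed), config.max_events(),
    )
    if status == _kernels.STATUS_BOUNDARY:
        raise RuntimeError("tumor reached the lattice boundary; increase lattice_span")
    if status == _kernels.STATUS_MAX_EVENTS:
        raise RuntimeError("event budget exhausted before reaching n_final")
    copies = np.stack([c1, c2], axis=1)
    return TumorState(
        xs - config.span, ys - config.span, copies, span=config.span, time=t,
        status=_STATUS_NAMES[status], config=config, seed=config.seed,
        info={"events": int(events)},
    )


def mixed_fraction(sample) -> float:
    """Fraction of cells carrying at least one copy of each species."""
    counts = sample.counts if isinstance(sample, RegionSample) else sample
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("mixed_fraction needs two-species counts of shape (n, 2)")
    if len(counts) == 0:
        raise ValueError("empty sample")
    return float(np.mean((counts[:, 0] > 0) & (counts[:, 1] > 0)))


# ---------------------------------------------------------------------------
# joint ABC
# ---------------------------------------------------------------------------

@dataclass
class TwoSpeciesObservedData:
    """Per-region (n, 2) copy-count arrays for one two-species tumor."""

    core: np.ndarray
    margins: List[np.ndarray]
    tumor_id: str = "tumor"

    def __post_init__(self):
        self.core = np.asarray(self.core, dtype=np.int64)
        self.margins = [np.asarray(m, dtype=np.int64) for m in self.margins]
        for r in [self.core, *self.margins]:
            if r.ndim != 2 or r.shape[1] != 2 or len(r) < 1:
                raise ValueError("regions must be non-empty (n, 2) arrays")
            if np.any(r < 0):
                raise ValueError("copy counts must be non-negative")
        if not self.margins:
            raise ValueError("at least one margin region is required")


@dataclass
class TwoSpeciesPriorGrid:
    """Uniform prior over (k1, k2, s, q); s is shared by pure and mixed cells
    (the desk-scale joint fit holds rho fixed and does not split s_p/s_m)."""

    k1: np.ndarray = field(default_factory=lambda: np.arange(1, 151))
    k2: np.ndarray = field(default_factory=lambda: np.arange(1, 151))
    s: np.ndarray = field(default_factory=lambda: np.arange(0.0, 4.01, 0.25))
    q: np.ndarray = field(default_factory=lambda: np.array([1, 2, 5, 10, 50, 1000]))

    def sample(self, rng: np.random.Generator):
        return (int(rng.choice(self.k1)), int(rng.choice(self.k2)),
                float(rng.choice(self.s)), int(rng.choice(self.q)))


def _two_species_region_distance(sim: np.ndarray, obs: np.ndarray, min_copy_filter: int):
    """Marginal Wasserstein distances (filtered on total copies) plus
    mixed-fraction gap (unfiltered)."""
    if len(sim) != len(obs):
        raise ValueError("size mismatch between simulated and observed region")
    gap = abs(mixed_fraction(sim) - mixed_fraction(obs))
    sim_f = sim[sim.sum(axis=1) >= min_copy_filter]
    obs_f = obs[obs.sum(axis=1) >= min_copy_filter]
    if len(sim_f) == 0 or len(obs_f) == 0:
        return float("inf"), float("inf"), gap
    w1 = wasserstein1d(sim_f[:, 0], obs_f[:, 0])
    w2 = wasserstein1d(sim_f[:, 1], obs_f[:, 1])
    return w1, w2, gap


class TwoSpeciesABCRejection:
    """Joint rejection-ABC for (k1, k2, s, q) from two-species regional data."""

    def __init__(self, observed: TwoSpeciesObservedData,
                 prior: Optional[TwoSpeciesPriorGrid] = None,
                 settings: Optional[ABCSettings] = None,
                 rho: float = 0.0):
        self.observed = observed
        self.prior = prior or TwoSpeciesPriorGrid()
        self.settings = settings or ABCSettings()
        self.rho = float(rho)

    def fit(self, seed: int = 0) -> ABCResults:
        st = self.settings
        obs = self.observed
        rng = np.random.default_rng(seed)
        rows = []
        n_failed = 0
        for b in range(st.budget):
            k1, k2, s, q = self.prior.sample(rng)
            sim_seed = int(rng.integers(1, 2**31 - 1))
            cfg = SimulationConfig(k=0, s=0.0, q=q, n_final=st.n_final, seed=sim_seed)
            tsc = TwoSpeciesConfig(k1=k1, k2=k2, s_p=s, s_m=s, rho=self.rho)
            state = run_two_species(tsc, cfg)
            if state.status != "reached":
                n_failed += 1
                continue
            srng = np.random.default_rng(int(rng.integers(1, 2**31 - 1)))
            core = core_sample(state, len(obs.core), rng=srng)
            wc1, wc2, gc = _two_species_region_distance(core.counts, obs.core,
                                                        st.min_copy_filter)
            for m in range(st.margins_per_sim):
                obs_m = obs.margins[m % len(obs.margins)]
                sim_m = margin_samples(state, len(obs_m), count=1,
                                       fraction=st.margin_fraction, rng=srng)[0]
                wm1, wm2, gm = _two_species_region_distance(
                    sim_m.counts, obs_m, st.min_copy_filter)
                rows.append(dict(
                    k=k1, k2=k2, s=s, q=q, sim_index=b, sim_seed=sim_seed,
                    pair_index=m,
                    w_core=max(wc1, wc2), w_margin=max(wm1, wm2),
                    gap_core=gc, gap_margin=gm,
                    sigma=wc1 + wc2 + wm1 + wm2,
                ))
        model = _TwoSpeciesModelView(self)
        return ABCResults(model, pd.DataFrame(rows), seed=seed, n_failed=n_failed)


class _TwoSpeciesModelView:
    """Adapter giving ABCResults the attributes it expects of a model."""

    def __init__(self, src: TwoSpeciesABCRejection):
        self.settings = src.settings
        self.prior = src.prior
        self.observed = src.observed
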