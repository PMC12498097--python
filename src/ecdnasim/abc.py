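"""Rejection-sampling approximate Bayesian computation for (k, s, q).

The observable is the per-cell ecDNA copy-number distribution in spatially
distinct tumor regions (core, infiltrating margin, optionally leading edge),
as measured by DNA FISH foci counts per nucleus. For each parameter draw from
the prior grid, a tumor is simulated to n_final cells, one core sample and
``margins_per_sim`` margin samples are taken size-matched to the observed
regions, and each of the resulting core--margin pairs is accepted when every
region individually satisfies both gates:

* first Wasserstein distance between the (>= min-copy filtered) simulated and
  observed copy-number distributions <= eps_region, and
* absolute difference of the unfiltered ecDNA-positive cell fractions
  <= delta_fraction.

The fit quality of an accepted pair is summarized by sigma, the summed
Wasserstein distances over its regions. The numeric thresholds are not
published for the source procedure; the defaults (eps_region=5,
delta_fraction=0.1) make an accepted core+margin pair satisfy sigma < 10.

Organized statsmodels-style: ``ABCRejection`` is the model object bound to
observed data, its ``fit`` returns an ``ABCResults`` carrying the accepted
posterior, diagnostics, a ``summary()`` table and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .lattice import SimulationConfig, run_to_size
from .sampling import (
    MARGIN_FRACTION,
    MIN_COPY_THRESHOLD,
    core_sample,
    leading_edge_sample,
    margin_samples,
)

__all__ = [
    "ObservedPatientData",
    "PriorGrid",
    "ABCSettings",
    "ABCRejection",
    "ABCResults",
    "wasserstein1d",
    "region_distance",
    "posterior_summary",
]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def wasserstein1d(a: Sequence[float], b: Sequence[float]) -> float:
    """First Wasserstein distance between two empirical 1D distributions.

    Equals the integral of the absolute ECDF difference; zero iff the two
    multisets define the same distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wasserstein1d requires non-empty samples")
    return float(wasserstein_distance(a, b))


def _positive_fraction(counts: np.ndarray) -> float:
    counts = np.asarray(counts)
    total = counts.sum(axis=1) if counts.ndim == 2 else counts
    return float(np.mean(total > 0))


def region_distance(sim_counts, obs_counts, min_copy_filter: int = MIN_COPY_THRESHOLD):
    """(Wasserstein distance on filtered counts, positive-fraction gap).

    ``sim_counts`` must be size-matched to ``obs_counts`` (the sampling step
    guarantees this in the ABC loop). Both sides are filtered at
    ``min_copy_filter`` for the Wasserstein term; the positive-fraction gap is
    computed on the unfiltered counts. A region whose filtered side is empty
    gets an infinite distance (it cannot be compared, hence never accepted).
    """
    sim = np.asarray(sim_counts, dtype=np.int64)
    obs = np.asarray(obs_counts, dtype=np.int64)
    if len(sim) != len(obs):
        raise ValueError(f"size mismatch: sim has {len(sim)} cells, observed {len(obs)}")
    gap = abs(_positive_fraction(sim) - _positive_fraction(obs))
    sim_f = sim[sim >= min_copy_filter]
    obs_f = obs[obs >= min_copy_filter]
    if sim_f.size == 0 or obs_f.size == 0:
        return float("inf"), gap
    return wasserstein1d(sim_f, obs_f), gap


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class ObservedPatientData:
    """Per-region single-cell copy-number lists for one tumor."""

    core: np.ndarray
    margins: List[np.ndarray]
    leading_edge: Optional[np.ndarray] = None
    tumor_id: str = "tumor"

    def __post_init__(self):
        self.core = np.asarray(self.core, dtype=np.int64)
        self.margins = [np.asarray(m, dtype=np.int64) for m in self.margins]
        if self.leading_edge is not None:
            self.leading_edge = np.asarray(self.leading_edge, dtype=np.int64)
        regions = [self.core, *self.margins]
        if self.leading_edge is not None:
            regions.append(self.leading_edge)
        for r in regions:
            if r.size < 1:
                raise ValueError("every observed region needs at least one cell")
            if np.any(r < 0):
                raise ValueError("copy counts must be non-negative")
        if not self.margins:
            raise ValueError("at least one margin region is required")

    @classmethod
    def from_copy_table(cls, table: pd.DataFrame, tumor_id: Optional[str] = None):
        """Build from a long-format copy table (see ``ecdnasim.io``)."""
        df = table
        if tumor_id is None:
            ids = df["tumor_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"table holds {len(ids)} tumors; pass tumor_id")
            tumor_id = ids[0]
        df = df[df["tumor_id"] == tumor_id]
        if df.empty:
            raise ValueError(f"no rows for tumor {tumor_id!r}")
        core = df.loc[df["region"] == "core", "copies"].to_numpy()
        margins = [
            g["copies"].to_numpy()
            for _, g in df[df["region"] == "margin"].groupby("replicate", sort=True)
        ]
        edge_rows = df.loc[df["region"] == "leading_edge", "copies"]
        edge = edge_rows.to_numpy() if len(edge_rows) else None
        return cls(core=core, margins=margins, leading_edge=edge, tumor_id=str(tumor_id))


@dataclass
class PriorGrid:
    """Uniform prior over a grid of (k, s, q) candidates."""

    k: np.ndarray = field(default_factory=lambda: np.arange(1, 151))
    s: np.ndarray = field(default_factory=lambda: np.arange(0.0, 4.01, 0.25))
    q: np.ndarray = field(default_factory=lambda: np.array([1, 2, 5, 10, 50, 1000]))

    def __post_init__(self):
        self.k = np.asarray(self.k)
        self.s = np.asarray(self.s, dtype=float)
        self.q = np.asarray(self.q)
        if self.k.size == 0 or self.s.size == 0 or self.q.size == 0:
            raise ValueError("prior grids must be non-empty")

    def sample(self, rng: np.random.Generator):
        return (
            int(rng.choice(self.k)),
            float(rng.choice(self.s)),
            int(rng.choice(self.q)),
        )


@dataclass
class ABCSettings:
    """Tuning of the rejection sampler (desk-scale defaults)."""

    budget: int = 2000
    eps_region: float = 5.0
    delta_fraction: float = 0.1
    margins_per_sim: int = 10
    margin_fraction: float = MARGIN_FRACTION
    min_copy_filter: int = MIN_COPY_THRESHOLD
    n_final: int = 10_000
    accept_mode: str = "threshold"  # or "quantile"
    accept_quantile: float = 0.02

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.eps_region <= 0:
            raise ValueError("eps_region must be positive")
        if not 0 <= self.delta_fraction <= 1:
            raise ValueError("delta_fraction must lie in [0, 1]")
        if self.accept_mode not in ("threshold", "quantile"):
            raise ValueError(f"unknown accept_mode {self.accept_mode!r}")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ABCRejection:
    """Rejection-ABC model for one tumor's regional copy-number data.

    Parameters
    ----------
    observed : ObservedPatientData
    prior : PriorGrid, optional (defaults to the standard grid)
    settings : ABCSettings, optional
    """

    def __init__(self, observed: ObservedPatientData,
                 prior: Optional[PriorGrid] = None,
                 settings: Optional[ABCSettings] = None):
        self.observed = observed
        self.prior = prior or PriorGrid()
        self.settings = settings or ABCSettings()

    @classmethod
    def from_copy_table(cls, table: pd.DataFrame, tumor_id: Optional[str] = None,
                        prior=None, settings=None):
        return cls(ObservedPatientData.from_copy_table(table, tumor_id),
                   prior=prior, settings=settings)

    # -- one simulated tumor -> rows for every core--margin pair -----------
    def _simulate_rows(self, k, s, q, sim_index, sim_seed, sample_seed):
        st = self.settings
        obs = self.observed
        cfg = SimulationConfig(k=k, s=s, q=(np.inf if q >= 10**6 else q),
                               n_final=st.n_final, seed=sim_seed)
        state = run_to_size(cfg)
        if state.status != "reached":
            return [], state.status
        srng = np.random.default_rng(sample_seed)
        core = core_sample(state, len(obs.core), rng=srng)
        w_core, g_core = region_distance(core.counts, obs.core, st.min_copy_filter)
        edge = None
        w_edge = g_edge = None
        if obs.leading_edge is not None:
            edge = leading_edge_sample(state, len(obs.leading_edge), rng=srng)
            w_edge, g_edge = region_distance(edge.counts, obs.leading_edge, st.min_copy_filter)
        rows = []
        for m in range(st.margins_per_sim):
            obs_m = obs.margins[m % len(obs.margins)]
            sim_m = margin_samples(state, len(obs_m), count=1,
                                   fraction=st.margin_fraction, rng=srng)[0]
            w_m, g_m = region_distance(sim_m.counts, obs_m, st.min_copy_filter)
            sigma = w_core + w_m + (w_edge or 0.0)
            row = dict(k=k, s=s, q=q, sim_index=sim_index, sim_seed=sim_seed,
                       pair_index=m, w_core=w_core, w_margin=w_m,
                       gap_core=g_core, gap_margin=g_m, sigma=sigma)
            if w_edge is not None:
                row["w_edge"] = w_edge
                row["gap_edge"] = g_edge
            rows.append(row)
        return rows, "reached"

    def fit(self, seed: int = 0, progress: bool = False) -> "ABCResults":
        """Run the rejection sampler and collect the posterior."""
        st = self.settings
        rng = np.random.default_rng(seed)
        all_rows = []
        n_failed = 0
        for b in range(st.budget):
            k, s, q = self.prior.sample(rng)
            sim_seed = int(rng.integers(1, 2**31 - 1))
            sample_seed = int(rng.integers(1, 2**31 - 1))
            rows, status = self._simulate_rows(k, s, q, b, sim_seed, sample_seed)
            if status != "reached":
                n_failed += 1
                continue
            all_rows.extend(rows)
            if progress and (b + 1) % 100 == 0:
                print(f"  ABC draw {b + 1}/{st.budget}")
        pairs = pd.DataFrame(all_rows)
        return ABCResults(self, pairs, seed=seed, n_failed=n_failed)


def _accept_mask(pairs: pd.DataFrame, settings: ABCSettings) -> np.ndarray:
    if pairs.empty:
        return np.zeros(0, dtype=bool)
    w_cols = [c for c in ("w_core", "w_margin", "w_edge") if c in pairs]
    g_cols = [c for c in ("gap_core", "gap_margin", "gap_edge") if c in pairs]
    if settings.accept_mode == "quantile":
        n_accept = max(1, int(round(settings.accept_quantile * len(pairs))))
        order = np.argsort(pairs["sigma"].to_numpy(), kind="stable")
        mask = np.zeros(len(pairs), dtype=bool)
        mask[order[:n_accept]] = True
        return mask
    mask = np.ones(len(pairs), dtype=bool)
    for c in w_cols:
        mask &= pairs[c].to_numpy() <= settings.eps_region
    for c in g_cols:
        mask &= pairs[c].to_numpy() <= settings.delta_fraction
    return mask


def posterior_summary(posterior: pd.DataFrame,
                      params: Sequence[str] = ("k", "s", "q")) -> pd.DataFrame:
    """Per-parameter mode with asymmetric 68% interval, reported mode-lo+hi.

    The point estimate is the most frequent accepted value (ties broken by
    proximity to the accepted median); lo/hi span the central 68% of accepted
    values, mirroring the asymmetric-interval convention used for
    patient-style reports such as k = 131-16+16.
    """
    if posterior is None or len(posterior) == 0:
        raise ValueError("empty posterior: no accepted parameter draws")
    rows = []
    for p in params:
        vals = posterior[p].to_numpy()
        uniq, counts = np.unique(vals, return_counts=True)
        med = float(np.median(vals))
        best = counts.max()
        cands = uniq[counts == best]
        mode = float(cands[np.argmin(np.abs(cands - med))])
        lo = float(np.quantile(vals, 0.16))
        hi = float(np.quantile(vals, 0.84))
        rows.append(dict(param=p, mode=mode, minus=mode - lo, plus=hi - mode,
                         median=med, n=len(vals)))
    return pd.DataFrame(rows).set_index("param")


class ABCResults:
    """Accepted posterior and diagnostics from an ``ABCRejection.fit``."""

    def __init__(self, model: ABCRejection, pairs: pd.DataFrame, seed: int,
                 n_failed: int = 0):
        self.model = model
        self.pairs = pairs
        self.seed = seed
        self.n_failed = n_failed
        mask = _accept_mask(pairs, model.settings)
        self.posterior = pairs.loc[mask].reset_index(drop=True) if len(pairs) else pairs

    @property
    def n_accepted(self) -> int:
        return len(self.posterior)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / len(self.pairs) if len(self.pairs) else 0.0

    def param_estimate(self, param: str, point: str = "mode") -> float:
        """Posterior point estimate ('mode' or 'median') for one parameter."""
        if self.n_accepted == 0:
            raise ValueError("empty posterior: no accepted parameter draws")
        if point == "median":
            return float(np.median(self.posterior[param]))
        return float(posterior_summary(self.posterior, [param]).loc[param, "mode"])

    def summary(self, params: Sequence[str] = ("k", "s", "q")):
        """Per-parameter mode-lo+hi table (raises if nothing was accepted)."""
        return posterior_summary(self.posterior, params)

    def diagnostics(self) -> dict:
        """Distance quantiles over all evaluated pairs (useful when the
        posterior is empty and thresholds need loosening)."""
        out = {"n_pairs": len(self.pairs), "n_accepted": self.n_accepted,
               "n_failed_sims": self.n_failed,
               "acceptance_rate": self.acceptance_rate}
        if len(self.pairs):
            for c in ("w_core", "w_margin", "w_edge", "gap_core", "gap_margin", "sigma"):
                if c in self.pairs:
                    out[f"{c}_quantiles"] = {
                        q: float(np.quantile(self.pairs[c], q)) for q in (0.05, 0.25, 0.5)
                    }
        return out

    def plot_posterior(self, params: Sequence[str] = ("k", "s", "q"), axes=None):
        """Histogram of the accepted marginal for each parameter."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3))
        axes = np.atleast_1d(axes)
        for ax, p in zip(axes, params):
            ax.hist(self.posterior[p], bins=30, color="#40618f")
            ax.set_xlabel(p)
            ax.set_ylabel("accepted pairs")
        return axes
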