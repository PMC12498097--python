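"""Circular multiregion sampling of simulated tumors.

Mimics multiregion DNA-FISH sampling of a resected tumor: a core sample
centered on the founder cell's coordinates, infiltrating-margin samples
centered on occupied cells at 75% of the tumor radius at random angles, and
leading-edge samples further out (95% by default; the margin fraction is the
measured convention, the leading-edge fraction is this package's choice).
Each sample grows a circle until it encloses at least the requested number of
cells, then subsamples exactly that many uniformly without replacement.
`filter_min_copies` applies the <3-copy exclusion used to keep stromal
(ecDNA-free or low-signal) nuclei out of both simulated and measured samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "RegionSample",
    "tumor_radius",
    "sample_circular",
    "core_sample",
    "margin_samples",
    "leading_edge_sample",
    "filter_min_copies",
    "MARGIN_FRACTION",
    "LEADING_EDGE_FRACTION",
    "MIN_COPY_THRESHOLD",
]

MARGIN_FRACTION = 0.75
LEADING_EDGE_FRACTION = 0.95
MIN_COPY_THRESHOLD = 3


@dataclass
class RegionSample:
    """A labeled circular sample of per-cell ecDNA copy counts.

    counts is (n,) for single-species tumors, (n, 2) for two-type tumors.
    """

    label: str
    center: Tuple[float, float]
    n_requested: int
    counts: np.ndarray
    filtered: bool = False
    threshold: Optional[int] = None
    angle: Optional[float] = None
    shortfall: bool = False
    center_distance: Optional[float] = None
    radius: Optional[float] = None

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    def total_per_cell(self) -> np.ndarray:
        c = np.asarray(self.counts)
        return c.sum(axis=1) if c.ndim == 2 else c

    @property
    def positive_fraction(self) -> float:
        if self.n_cells == 0:
            return 0.0
        return float(np.mean(self.total_per_cell() > 0))


def _rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def tumor_radius(state) -> float:
    """Maximum Euclidean distance of any cell from the founder site."""
    if state.n_cells < 1:
        raise ValueError("empty tumor has no radius")
    x = np.asarray(state.xs, dtype=float)
    y = np.asarray(state.ys, dtype=float)
    return float(np.sqrt(x * x + y * y).max())


def sample_circular(state, center, n, seed=None, rng=None, *, label="core",
                    angle=None) -> RegionSample:
    """Smallest circle around ``center`` holding >= n cells, subsampled to n.

    If the whole tumor holds fewer than n cells, all cells are returned and
    the sample is flagged with ``shortfall=True``.
    """
    if n < 1:
        raise ValueError("requested sample size must be >= 1")
    gen = _rng(seed, rng)
    cx, cy = center
    x = np.asarray(state.xs, dtype=float)
    y = np.asarray(state.ys, dtype=float)
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    m = state.n_cells
    cdist = float(np.sqrt((cx**2 + cy**2)))
    if n >= m:
        chosen = np.arange(m)
        radius = float(np.sqrt(d2.max()))
        shortfall = n > m
    else:
        part = np.argpartition(d2, n - 1)
        r2 = d2[part[n - 1]]
        inside = np.flatnonzero(d2 <= r2)  # >= n cells, ties included
        chosen = gen.choice(inside, size=n, replace=False)
        radius = float(np.sqrt(r2))
        shortfall = False
    counts = np.array(state.copies[chosen], dtype=np.int64)
    return RegionSample(
        label=label, center=(float(cx), float(cy)), n_requested=int(n),
        counts=counts, angle=angle, shortfall=shortfall,
        center_distance=cdist, radius=radius,
    )


def core_sample(state, n, seed=None, rng=None) -> RegionSample:
    """Circular sample centered on the coordinates of the first tumor cell."""
    return sample_circular(state, state.founder_site, n, seed=seed, rng=rng, label="core")


def _radial_sample(state, n, fraction, label, gen, tolerance, max_retries):
    radius = tumor_radius(state)
    x = np.asarray(state.xs, dtype=float)
    y = np.asarray(state.ys, dtype=float)
    tol = tolerance if tolerance is not None else max(2.0, 0.05 * radius)
    best = None  # (err, angle, cell index)
    for _ in range(max_retries):
        theta = float(gen.uniform(0.0, 2.0 * np.pi))
        tx = fraction * radius * np.cos(theta)
        ty = fraction * radius * np.sin(theta)
        j = int(np.argmin((x - tx) ** 2 + (y - ty) ** 2))
        err = float(np.hypot(x[j] - tx, y[j] - ty))
        if best is None or err < best[0]:
            best = (err, theta, j)
        if err <= tol:
            break
    _, theta, j = best
    return sample_circular(state, (x[j], y[j]), n, rng=gen, label=label, angle=theta)


def margin_samples(state, n, count=10, fraction=MARGIN_FRACTION, seed=None,
                   rng=None, tolerance=None, max_retries=20) -> List[RegionSample]:
    """``count`` circular samples centered on occupied cells at
    ``fraction`` x tumor radius, each at an independent random angle."""
    if count < 1:
        raise ValueError("count must be >= 1")
    gen = _rng(seed, rng)
    return [
        _radial_sample(state, n, fraction, "margin", gen, tolerance, max_retries)
        for _ in range(count)
    ]


def leading_edge_sample(state, n, fraction=LEADING_EDGE_FRACTION, seed=None,
                        rng=None, tolerance=None, max_retries=20) -> RegionSample:
    """A margin-style sample at the tumor periphery (default 95% of radius)."""
    gen = _rng(seed, rng)
    return _radial_sample(state, n, fraction, "leading_edge", gen, tolerance, max_retries)


def filter_min_copies(sample: RegionSample, threshold: int = MIN_COPY_THRESHOLD) -> RegionSample:
    """Drop cells whose total copy count is below ``threshold`` (idempotent)."""
    total = sample.total_per_cell()
    keep = total >= threshold
    return dataclasses.replace(
        sample, counts=np.asarray(sample.counts)[keep].copy(), filtered=True,
        threshold=int(threshold),
    )
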