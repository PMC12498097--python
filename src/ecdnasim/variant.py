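"""Wild-type plus variant ecDNA within one tumor (heteroplasmy dynamics).

Models an oncogene variant (e.g. a constitutively active structural variant)
carried on ecDNA alongside the wild-type ecDNA it arose from. Both types
segregate binomially and independently at division; cell fitness is dominated
by the variant: rate 1+s_var with any variant copy, 1+s_wt with wild-type
only, 1 when ecDNA-free. The variant is either present in the founder
(``vvar = 0`` with ``kvar`` copies) or arises post-expansion: when the
population first reaches ``vvar`` cells, one wild-type copy — each copy
equally likely — mutates into a variant copy (conversion, so copy number is
conserved at the event).

`heteroplasmy` is the percentage of ecDNA copies in a sample that are
wild-type. `mutation_origin_distribution` addresses the precancerous phase:
under a per-copy replication mutation probability mu, in how many wild-type
copies does the cell that acquires the first mutation sit?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .lattice import (
    ConfigurationError,
    SimulationConfig,
    TumorState,
    _STATUS_NAMES,
)
from .sampling import RegionSample, core_sample, margin_samples

__all__ = [
    "VariantConfig",
    "run_variant_sim",
    "heteroplasmy",
    "covariegation_probability",
    "mutation_origin_distribution",
]


@dataclass(frozen=True)
class VariantConfig:
    """Wild-type/variant parameterization.

    kwt, kvar : founder wild-type / variant copy numbers.
    vvar : population size at which one wt copy mutates to a variant
           (0 = variant present at initiation).
    s_wt, s_var : selection for wt-only cells and variant-carrying cells.
    mu : per-copy per-replication mutation probability (mutation-origin runs).
    """

    kwt: int
    kvar: int = 0
    vvar: int = 0
    s_wt: float = 1.0
    s_var: float = 2.0
    mu: float = 0.0

    def __post_init__(self):
        if self.kwt < 0 or self.kvar < 0:
            raise ConfigurationError("founder copy numbers must be non-negative")
        if self.vvar < 0:
            raise ConfigurationError("vvar must be non-negative")
        if self.s_wt <= -1 or self.s_var <= -1:
            raise ConfigurationError("selection coefficients must exceed -1")
        if not 0 <= self.mu <= 1:
            raise ConfigurationError("mu must lie in [0, 1]")


def run_variant_sim(vc: VariantConfig, config: SimulationConfig) -> TumorState:
    """Spatial two-type run; per-cell copies come back as an (n, 2) array
    with columns (wild-type, variant). ``state.info`` records the population
    size at the mutation trigger and whether a variant copy was created."""
    if vc.vvar > config.n_final:
        raise ConfigurationError(
            f"vvar={vc.vvar} exceeds n_final={config.n_final}: mutation time unreachable"
        )
    (status, n, xs, ys, c1, c2, t, events, trig_n, var_created) = _kernels.run_two_type(
        int(vc.kwt), int(vc.kvar), float(vc.s_wt), float(vc.s_var),
        0, 0.0, int(vc.vvar), config.q_steps(), float(config.d),
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
        info={"events": int(events), "trigger_n": int(trig_n),
              "variant_created": bool(var_created)},
    )


def heteroplasmy(sample) -> float:
    """Percentage of ecDNA copies in the sample that are wild-type (type 1)."""
    counts = sample.counts if isinstance(sample, RegionSample) else sample
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("heteroplasmy needs two-type counts of shape (n, 2)")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total ecDNA copies: heteroplasmy undefined")
    return 100.0 * float(counts[:, 0].sum()) / float(total)


def covariegation_probability(
    vc: VariantConfig,
    config: SimulationConfig,
    n_sample: int,
    replicates: int = 200,
    seed: int = 0,
) -> float:
    """Probability that both a core and one random margin sample contain the
    variant, estimated over replicate tumors.

    Per replicate: simulate a tumor, draw a core sample and one margin sample
    of ``n_sample`` cells each; success iff at least one sampled cell in each
    region carries >= 1 variant copy.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    for _ in range(replicates):
        rep_cfg = SimulationConfig(
            k=0, s=0.0, q=config.q, d=config.d, n_final=config.n_final,
            seed=int(rng.integers(1, 2**31 - 1)), lattice_span=config.lattice_span,
        )
        state = run_variant_sim(vc, rep_cfg)
        if state.status != "reached":
            continue
        srng = np.random.default_rng(int(rng.integers(1, 2**31 - 1)))
        core = core_sample(state, n_sample, rng=srng)
        margin = margin_samples(state, n_sample, count=1, rng=srng)[0]
        if (core.counts[:, 1] > 0).any() and (margin.counts[:, 1] > 0).any():
            hits += 1
        done += 1
    if done == 0:
        raise RuntimeError("all replicate tumors went extinct")
    return hits / done


def mutation_origin_distribution(
    k: int,
    s: float,
    mu: float,
    n_final: int = 1000,
    replicates: int = 200,
    seed: int = 0,
) -> Tuple[np.ndarray, int]:
    """Wild-type abundance in the first-mutating cell, across replicates.

    Well-mixed wild-type-only growth from ``k`` copies under selection ``s``;
    at every division a cell's copies replicate (c -> 2c) and each of the c
    newly replicated copies mutates with probability ``mu``. The founder's k
    copies count as one replication round, so a mutation at initiation is
    recorded as k-1 wild-type copies; a mutation at a division of a cell with
    c copies is recorded as 2c-1 (copies at the moment of mutation, minus the
    new variant). Each replicate stops at its first mutation or at n_final.

    Returns (recorded abundances, number of replicates with no mutation).
    """
    if not 0 <= mu <= 1:
        raise ConfigurationError("mu must lie in [0, 1]")
    if k < 0 or s <= -1:
        raise ConfigurationError("invalid k or s")
    rng = np.random.default_rng(seed)
    values = []
    n_none = 0
    for _ in range(replicates):
        rep = np.random.default_rng(int(rng.integers(1, 2**31 - 1)))
        # initiation: the founder's k copies are one replication round
        if k > 0 and mu > 0 and rep.random() < 1.0 - (1.0 - mu) ** k:
            values.append(k - 1)
            continue
        copies = np.zeros(n_final + 1, dtype=np.int64)
        copies[0] = k
        n = 1
        mutated = False
        rmax = 1.0 + max(s, 0.0)
        while n < n_final:
            while True:
                i = int(rep.integers(n))
                ri = 1.0 + s if copies[i] > 0 else 1.0
                if rep.random() * rmax < ri:
                    break
            c = int(copies[i])
            if c > 0 and mu > 0 and rep.random() < 1.0 - (1.0 - mu) ** c:
                values.append(2 * c - 1)
                mutated = True
                break
            total = 2 * c
            a = rep.binomial(total, 0.5) if total > 0 else 0
            copies[i] = a
            copies[n] = total - a
            n += 1
        if not mutated:
            n_none += 1
    return np.asarray(values, dtype=np.int64), n_none
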