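"""Allele-count-level simulation of pooled whole-genome sequencing.

Each phenotype pool is sequenced in silico at every parental variant
site.  Read depth per site is Poisson around a mean (or fixed, for exact
tests); the number of reads matching the invasive-parent allele is
binomial around the pool's true allele frequency, perturbed by a
symmetric two-allele error model.  Reads matching neither parental
allele are assumed discarded upstream, so depth is conserved between the
two allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .synthetic_cross import (
    RngLike,
    SporeGenotype,
    VariantSite,
    as_rng,
    pool_allele_frequencies,
)

__all__ = ["SequencingSpec", "PoolReadCounts", "sequence_pool"]


@dataclass(frozen=True)
class SequencingSpec:
    """Pooled-sequencing noise model.

    mean_depth:
        Expected reads per site per pool.  The default 120 keeps the mean
        comfortably above 100-fold coverage.
    error_rate:
        Probability that a read reports the wrong parental allele
        (symmetric flip).  Default 0.002.
    fixed_depth:
        If true, every site gets exactly ``round(mean_depth)`` reads
        instead of a Poisson draw — useful for exact distributional tests.
    seed:
        Optional default seed; an explicit seed/Generator passed to
        :func:`sequence_pool` takes precedence.
    """

    mean_depth: float = 120.0
    error_rate: float = 0.002
    fixed_depth: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class PoolReadCounts:
    """Observed read counts for one site in one pool.

    ``reads_b`` counts reads matching the invasive-parent (B) allele,
    ``reads_a`` the other parent's allele; they sum to ``depth``.
    """

    site: VariantSite
    pool: str
    depth: int
    reads_b: int

    def __post_init__(self):
        if self.depth < 0 or not (0 <= self.reads_b <= self.depth):
            raise ValueError("require 0 <= reads_b <= depth")

    @property
    def reads_a(self) -> int:
        return self.depth - self.reads_b


def sequence_pool(
    pool: Sequence[SporeGenotype],
    sites: Sequence[VariantSite],
    spec: SequencingSpec = SequencingSpec(),
    seed: RngLike = None,
    pool_label: str = "pool",
) -> list:
    """Simulate pooled sequencing of one phenotype pool.

    For each site with true invasive-allele frequency ``q`` in the pool,
    ``depth ~ Poisson(mean_depth)`` and
    ``reads_b ~ Binomial(depth, q(1-e) + (1-q)e)`` with error rate ``e``.
    Deterministic given the seed.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    if len(sites) == 0:
        return []
    rng = as_rng(seed if seed is not None else spec.seed)
    q = pool_allele_frequencies(pool)
    if len(q) != len(sites):
        raise ValueError("site list does not match spore genotype length")
    e = spec.error_rate
    p_obs = q * (1.0 - e) + (1.0 - q) * e
    if spec.fixed_depth:
        depth = np.full(len(sites), int(round(spec.mean_depth)), dtype=np.int64)
    else:
        depth = rng.poisson(spec.mean_depth, size=len(sites))
    reads_b = rng.binomial(depth, p_obs)
    return [
        PoolReadCounts(site=s, pool=pool_label, depth=int(d), reads_b=int(rb))
        for s, d, rb in zip(sites, depth, reads_b)
    ]
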