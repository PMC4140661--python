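"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from poolseg import (
    GenomeSpec,
    SporeGenotype,
    generate_complete_tetrads,
    make_parents,
)
from poolseg.pipeline import CrossConfig, simulate_cross
from poolseg.linkage import build_linkage_records
from poolseg.pooled_sequencing import SequencingSpec, sequence_pool


@pytest.fixture(scope="session")
def toy_spec() -> GenomeSpec:
    return GenomeSpec(chromosomes=(("chrI", 400_000), ("chrII", 300_000)))


@pytest.fixture(scope="session")
def toy_sites(toy_spec):
    return make_parents(toy_spec, 0.003, seed=11)


def two_site_spec(d_cm: float, length: int = 100_000) -> GenomeSpec:
    """One chromosome whose ends are d_cm apart on the genetic map."""
    rate = d_cm / ((length - 1) / 1000)  # cM per kb
    return GenomeSpec(chromosomes=(("chr1", length),), genetic_rate=rate)


def recombination_fraction(d_cm: float, n_tetrads: int, seed: int):
    """Monte-Carlo recombination fraction between two terminal markers.

    Returns (r_hat, standard error) with the SE taken over per-tetrad
    recombinant fractions, since spores within a tetrad are correlated.
    """
    spec = two_site_spec(d_cm)
    length = spec.chromosomes[0][1]
    sites = make_parents_at(spec, [("chr1", 1), ("chr1", length)])
    tetrads = generate_complete_tetrads(
        n_tetrads, sites, spec, viability=1.0, seed=seed
    )
    fracs = []
    for t in tetrads:
        rec = sum(1 for s in t.spores if s.origin[0] != s.origin[1])
        fracs.append(rec / 4)
    fracs = np.asarray(fracs)
    return float(fracs.mean()), float(fracs.std(ddof=1) / np.sqrt(len(fracs)))


def make_parents_at(spec: GenomeSpec, positions):
    """Fixed variant sites at given (chrom, pos) pairs."""
    from poolseg import VariantSite

    return [
        VariantSite(chrom=c, pos=p, ref_allele="A", alt_allele="G", parent_of_ref="A")
        for c, p in positions
    ]


def haldane_r(d_cm: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def fixed_pool(n: int, origin: int, n_sites: int = 1):
    """A pool of n spores all carrying one parental allele at every site."""
    return [
        SporeGenotype(origin=np.full(n_sites, origin, dtype=np.uint8), mat="a")
        for _ in range(n)
    ]


def linked_site_lod(n_inv: int, n_non: int, seed: int, error_rate: float = 0.002):
    """Simulate sequencing of a completely linked site and score its LOD."""
    from poolseg.linkage import estimate_counts, lod_score

    rng = np.random.default_rng(seed)
    spec = SequencingSpec(mean_depth=120.0, error_rate=error_rate)
    inv = sequence_pool(fixed_pool(n_inv, 1), make_parents_at(
        GenomeSpec(chromosomes=(("chr1", 1000),)), [("chr1", 500)]
    ), spec, rng, pool_label="invasive")[0]
    non = sequence_pool(fixed_pool(n_non, 0), make_parents_at(
        GenomeSpec(chromosomes=(("chr1", 1000),)), [("chr1", 500)]
    ), spec, rng, pool_label="non_invasive")[0]
    f_inv, f_non, _, _ = estimate_counts(inv, non, n_inv, n_non)
    return lod_score(f_inv, f_non, n_inv, n_non)


def recovery_config() -> CrossConfig:
    """Gate-locus cross with the classic 37/63 pools."""
    return CrossConfig(n_tetrads=40, pool_targets=(37, 63))


def gate_recovered(seed: int, window: int = 50_000) -> bool:
    """Does the argmax-LOD variant fall inside the causal linkage block?"""
    sim = simulate_cross(recovery_config(), seed)
    records = build_linkage_records(
        sim.inv_counts, sim.non_counts, sim.pools.n_inv, sim.pools.n_non
    )
    best = max((r for r in records if not r.no_call), key=lambda r: r.lod)
    causal = sim.causal_site
    return best.site.chrom == causal.chrom and abs(best.site.pos - causal.pos) <= window
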