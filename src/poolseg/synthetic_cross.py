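"""Simulation of a haploid-by-haploid yeast cross for pooled segregant analysis.

This module generates the upstream side of a bulk segregant experiment:
two parental genomes that differ at a configurable density of biallelic
SNV sites, meiosis under a four-strand chiasma model (no crossover
interference, so pairwise recombination fractions follow the Haldane map
function), tetrad completeness checks (four viable spores, mating types
segregating 2:2), a liability-threshold phenotype model with an optional
epistatic gate locus, and phenotype-sorted segregant pools.

Conventions
-----------
* Coordinates are 1-based, fully closed (GFF3/VCF style).
* Parental labels: ``A`` is the non-invasive parent (a BY4741-like
  laboratory strain), ``B`` the invasive parent.  Spore genotypes are
  stored as uint8 vectors over the variant sites, 0 = A, 1 = B.
* All randomness flows from a single integer seed: public entry points
  accept either a seed or a ``numpy.random.Generator``; composite
  operations split their stream with ``numpy.random.SeedSequence.spawn``
  so that stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "GenomeSpec",
    "VariantSite",
    "CausalModel",
    "SporeGenotype",
    "Tetrad",
    "SegregantPools",
    "make_parents",
    "simulate_tetrad",
    "generate_complete_tetrads",
    "assign_phenotype",
    "assign_phenotypes",
    "build_pools",
    "pool_allele_frequencies",
]

PARENT_A = 0  # non-invasive parent
PARENT_B = 1  # invasive parent

#: default genome-wide genetic rate, cM per kb (approximate S. cerevisiae
#: genome average; ~4400 cM over ~12 Mb).
DEFAULT_GENETIC_RATE = 0.35

RngLike = Union[int, np.random.Generator, None]

_BASES = np.array(["A", "C", "G", "T"])


def as_rng(seed: RngLike) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Karyotype of the toy genome.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.  The order given here defines
        chromosome sort order throughout the pipeline.
    genetic_rate:
        Map-distance rate in cM per kb, either a scalar applied to every
        chromosome or a per-chromosome mapping.
    mat_locus:
        ``(chromosome, position)`` of the mating-type marker.  Defaults to
        the midpoint of the first chromosome.
    """

    chromosomes: tuple
    genetic_rate: Union[float, Mapping[str, float]] = DEFAULT_GENETIC_RATE
    mat_locus: Optional[tuple] = None

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        object.__setattr__(
            self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes)
        )
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        rates = (
            self.genetic_rate.values()
            if isinstance(self.genetic_rate, Mapping)
            else [self.genetic_rate]
        )
        if any(r < 0 for r in rates):
            raise ValueError("genetic_rate must be >= 0")
        mat = self.mat_locus
        if mat is None:
            name, length = self.chromosomes[0]
            mat = (name, max(1, length // 2))
        mat = (str(mat[0]), int(mat[1]))
        lengths = dict(self.chromosomes)
        if mat[0] not in lengths or not (1 <= mat[1] <= lengths[mat[0]]):
            raise ValueError("mat_locus must lie within a declared chromosome")
        object.__setattr__(self, "mat_locus", mat)

    @property
    def names(self) -> tuple:
        return tuple(n for n, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def rate_for(self, chrom: str) -> float:
        if isinstance(self.genetic_rate, Mapping):
            return float(self.genetic_rate.get(chrom, DEFAULT_GENETIC_RATE))
        return float(self.genetic_rate)

    def morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans."""
        return self.rate_for(chrom) * (self.length_of(chrom) / 1000.0) / 100.0


@dataclass(frozen=True)
class VariantSite:
    """One biallelic difference between the two parents."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    parent_of_ref: str = "A"  # which parent carries the REF base

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt")
        if self.parent_of_ref not in ("A", "B"):
            raise ValueError("parent_of_ref must be 'A' or 'B'")

    def allele_of(self, parent: str) -> str:
        """Base carried by parent ``'A'`` or ``'B'`` at this site."""
        if parent == self.parent_of_ref:
            return self.ref_allele
        return self.alt_allele


@dataclass(frozen=True)
class CausalModel:
    """Liability-threshold phenotype model with an optional epistatic gate.

    ``effect_sites`` holds ``(site_index, beta)`` pairs; a spore's liability
    is ``sum(beta_i * x_i) + eps`` where ``x_i`` is 1 if the spore carries
    the invasive-parent (B) allele at effect site *i* and
    ``eps ~ Normal(0, noise_sd)``.  If ``gate_site`` is set and the spore
    carries the parent-A allele there, the phenotype is non-invasive
    regardless of liability — modelled on a loss-of-function allele (a
    FLO8-pseudogene analog) that abolishes filamentation epistatically.
    """

    effect_sites: tuple = ()
    gate_site: Optional[int] = None
    noise_sd: float = 0.35
    tau_lo: float = 0.35
    tau_hi: float = 0.65

    def __post_init__(self):
        object.__setattr__(
            self,
            "effect_sites",
            tuple((int(i), float(b)) for i, b in self.effect_sites),
        )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tau_lo > self.tau_hi:
            raise ValueError("tau_lo must be <= tau_hi")


@dataclass
class SporeGenotype:
    """One haploid meiotic product."""

    origin: np.ndarray  # uint8 per variant site: 0 = parent A, 1 = parent B
    mat: str  # "alpha" or "a"
    viable: bool = True
    liability: float = float("nan")
    phenotype: Optional[str] = None  # invasive / intermediate / non_invasive

    def carries_b(self, index: int) -> bool:
        return bool(self.origin[index] == PARENT_B)


@dataclass
class Tetrad:
    """The four products of one meiosis.

    ``complete`` is true when all four spores are viable and the mating
    types segregate 2:2.  Under faithful 2:2 marker segregation the mating
    check can only pass, but it is enforced as a guard.
    """

    spores: tuple
    complete: bool = False

    def __post_init__(self):
        if len(self.spores) != 4:
            raise ValueError("a tetrad has exactly 4 spores")


@dataclass
class SegregantPools:
    invasive: list
    non_invasive: list

    @property
    def n_inv(self) -> int:
        return len(self.invasive)

    @property
    def n_non(self) -> int:
        return len(self.non_invasive)


# ---------------------------------------------------------------------------
# parental genomes
# ---------------------------------------------------------------------------

def make_parents(
    spec: GenomeSpec, divergence: float, seed: RngLike = None
) -> list:
    """Draw the biallelic sites at which the two parents differ.

    The number of variant sites per chromosome is Binomial(length,
    divergence); positions are uniform without replacement.  Ref/alt bases
    are drawn uniformly (alt from the three non-ref bases) and the parent
    carrying the reference base is chosen at random per site, so neither
    parent is systematically the reference.

    Returns the sites sorted by (chromosome order, position).
    """
    if not (0 < divergence < 1):
        raise ValueError("divergence must be in (0, 1)")
    rng = as_rng(seed)
    sites: list = []
    for chrom, length in spec.chromosomes:
        n = int(rng.binomial(length, divergence))
        n = min(n, length)
        positions = np.sort(rng.choice(length, size=n, replace=False) + 1)
        refs = rng.integers(0, 4, size=n)
        # alt drawn uniformly among the 3 non-ref bases
        alts = (refs + rng.integers(1, 4, size=n)) % 4
        ref_parent = rng.random(n) < 0.5
        for pos, r, a, is_a in zip(positions, refs, alts, ref_parent):
            sites.append(
                VariantSite(
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele=str(_BASES[r]),
                    alt_allele=str(_BASES[a]),
                    parent_of_ref="A" if is_a else "B",
                )
            )
    return sites


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

class _ChromIndex:
    """Per-chromosome site index, precomputed once for repeated meioses."""

    def __init__(self, sites: Sequence[VariantSite], spec: GenomeSpec):
        self.spec = spec
        self.n_sites = len(sites)
        pos_by_chrom: dict = {name: [] for name in spec.names}
        idx_by_chrom: dict = {name: [] for name in spec.names}
        last = None
        for i, s in enumerate(sites):
            if s.chrom not in pos_by_chrom:
                raise ValueError(f"site on undeclared chromosome {s.chrom}")
            key = (spec.names.index(s.chrom), s.pos)
            if last is not None and key <= last:
                raise ValueError("sites must be sorted by (chrom, pos) and unique")
            last = key
            pos_by_chrom[s.chrom].append(s.pos)
            idx_by_chrom[s.chrom].append(i)
        self.positions = {c: np.asarray(p) for c, p in pos_by_chrom.items()}
        self.indices = {c: np.asarray(p, dtype=np.intp) for c, p in idx_by_chrom.items()}


def simulate_tetrad(
    sites: Sequence[VariantSite],
    spec: GenomeSpec,
    viability: float = 0.9,
    seed: RngLike = None,
    _index: Optional[_ChromIndex] = None,
) -> Tetrad:
    """Simulate one meiosis under a four-strand, no-interference model.

    Per chromosome the chiasma count is Poisson(2 * genetic length in
    Morgans); each chiasma picks one chromatid from each sister pair
    uniformly and exchanges the material distal to a uniform physical
    position.  Any one chromatid therefore sees a Poisson(d) crossover
    process, giving Haldane recombination fractions r = (1 - exp(-2d))/2
    in expectation.  All four products are returned; every heterozygous
    site segregates exactly 2:2.  Spore viability is independent
    Bernoulli(viability); the mating-type locus rides along as one extra
    2:2 marker.
    """
    if not (0.0 <= viability <= 1.0):
        raise ValueError("viability must be in [0, 1]")
    rng = as_rng(seed)
    index = _index if _index is not None else _ChromIndex(sites, spec)

    origins = np.empty((4, index.n_sites), dtype=np.uint8)
    mat_chrom, mat_pos = spec.mat_locus
    mat_origin = np.array([PARENT_A, PARENT_A, PARENT_B, PARENT_B], dtype=np.uint8)

    for chrom, length in spec.chromosomes:
        pos = index.positions[chrom]
        idx = index.indices[chrom]
        # chromatids 0,1 descend from the parent-A homolog, 2,3 from B
        chrom_orig = np.repeat(
            np.array([PARENT_A, PARENT_B], dtype=np.uint8), 2
        ).reshape(4, 1) * np.ones((1, len(pos)), dtype=np.uint8)
        chrom_mat = mat_origin.copy() if chrom == mat_chrom else None

        n_chiasmata = rng.poisson(2.0 * spec.morgans(chrom))
        if n_chiasmata:
            xpos = np.sort(rng.uniform(0, length, size=n_chiasmata))
            ci = rng.integers(0, 2, size=n_chiasmata)      # chromatid of A pair
            cj = rng.integers(2, 4, size=n_chiasmata)      # chromatid of B pair
            for x, i, j in zip(xpos, ci, cj):
                distal = pos > x
                if distal.any():
                    tmp = chrom_orig[i, distal].copy()
                    chrom_orig[i, distal] = chrom_orig[j, distal]
                    chrom_orig[j, distal] = tmp
                if chrom_mat is not None and mat_pos > x:
                    chrom_mat[i], chrom_mat[j] = chrom_mat[j], chrom_mat[i]

        # independent assortment: random assignment of the four products
        perm = rng.permutation(4)
        origins[:, idx] = chrom_orig[perm]
        if chrom_mat is not None:
            mat_origin = chrom_mat[perm]

    viable = rng.random(4) < viability
    spores = tuple(
        SporeGenotype(
            origin=origins[k],
            mat="alpha" if mat_origin[k] == PARENT_A else "a",
            viable=bool(viable[k]),
        )
        for k in range(4)
    )
    mats = sorted(s.mat for s in spores)
    complete = all(s.viable for s in spores) and mats == ["a", "a", "alpha", "alpha"]
    return Tetrad(spores=spores, complete=complete)


def generate_complete_tetrads(
    n_tetrads: int,
    sites: Sequence[VariantSite],
    spec: GenomeSpec,
    viability: float = 0.9,
    seed: RngLike = None,
    max_attempts: Optional[int] = None,
) -> list:
    """Simulate meioses until ``n_tetrads`` complete tetrads are collected.

    Incomplete meioses (a dead spore or, defensively, a mating-type skew)
    are discarded, as in tetrad dissection.  Raises ``RuntimeError`` if the
    attempt budget — by default 50 times the expected number of attempts —
    is exhausted, which flags an implausibly low viability.
    """
    if n_tetrads <= 0:
        raise ValueError("n_tetrads must be positive")
    rng = as_rng(seed)
    index = _ChromIndex(sites, spec)
    p_complete = viability ** 4
    if max_attempts is None:
        expected = n_tetrads / max(p_complete, 1e-12)
        max_attempts = int(max(1000, 50 * expected))
    tetrads: list = []
    attempts = 0
    while len(tetrads) < n_tetrads:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"gave up after {attempts - 1} meioses with only "
                f"{len(tetrads)}/{n_tetrads} complete tetrads "
                f"(viability={viability}); completion probability "
                f"viability^4 = {p_complete:.3g} is too low"
            )
        t = simulate_tetrad(sites, spec, viability=viability, seed=rng, _index=index)
        if t.complete:
            tetrads.append(t)
    return tetrads


# ---------------------------------------------------------------------------
# phenotype and pools
# ---------------------------------------------------------------------------

def assign_phenotype(
    spore: SporeGenotype, model: CausalModel, seed: RngLike = None
) -> str:
    """Assign the invasive/intermediate/non-invasive class to one spore.

    Mutates ``spore.liability`` and ``spore.phenotype`` and returns the
    class.  See :class:`CausalModel` for the liability model.
    """
    rng = as_rng(seed)
    liability = 0.0
    for i, beta in model.effect_sites:
        if spore.origin[i] == PARENT_B:
            liability += beta
    if model.noise_sd > 0:
        liability += rng.normal(0.0, model.noise_sd)
    spore.liability = float(liability)
    if model.gate_site is not None and spore.origin[model.gate_site] == PARENT_A:
        spore.phenotype = "non_invasive"
    elif liability > model.tau_hi:
        spore.phenotype = "invasive"
    elif liability < model.tau_lo:
        spore.phenotype = "non_invasive"
    else:
        spore.phenotype = "intermediate"
    return spore.phenotype


def assign_phenotypes(
    tetrads: Sequence[Tetrad], model: CausalModel, seed: RngLike = None
) -> None:
    """Assign phenotypes to every spore of every tetrad in place."""
    rng = as_rng(seed)
    for t in tetrads:
        for s in t.spores:
            assign_phenotype(s, model, rng)


def build_pools(
    tetrads: Sequence[Tetrad],
    targets: Optional[tuple] = None,
    seed: RngLike = None,
) -> SegregantPools:
    """Sort phenotyped spores into invasive / non-invasive pools.

    Intermediate spores are excluded.  If ``targets = (n_inv, n_non)`` is
    given, each pool is subsampled without replacement to that size (to
    mimic fixed pool sizes such as 37/63 or 51/24); a target larger than
    the available spores is an error, as is an empty pool.
    """
    rng = as_rng(seed)
    inv = [s for t in tetrads for s in t.spores if s.phenotype == "invasive"]
    non = [s for t in tetrads for s in t.spores if s.phenotype == "non_invasive"]
    if targets is not None:
        n_inv, n_non = targets
        if n_inv > len(inv) or n_non > len(non):
            raise RuntimeError(
                f"cannot subsample pools to {targets}: only "
                f"{len(inv)} invasive / {len(non)} non-invasive spores available"
            )
        inv = [inv[i] for i in rng.choice(len(inv), size=n_inv, replace=False)]
        non = [non[i] for i in rng.choice(len(non), size=n_non, replace=False)]
    if not inv or not non:
        raise RuntimeError(
            f"empty pool: {len(inv)} invasive / {len(non)} non-invasive spores"
        )
    return SegregantPools(invasive=inv, non_invasive=non)


def pool_allele_frequencies(pool: Sequence[SporeGenotype]) -> np.ndarray:
    """True frequency of the invasive-parent (B) allele at every site."""
    if not pool:
        raise ValueError("empty pool")
    mat = np.stack([s.origin for s in pool])
    return mat.mean(axis=0)
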