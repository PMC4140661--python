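"""LOD-score linkage mapping from pooled allele counts.

The core statistic: for each variant site, the fraction of reads in each
phenotype pool matching the invasive-parent allele is converted to an
estimated (real-valued) count of spores carrying that allele, and a LOD
score tests those per-pool allele frequencies against the 1/2 expected
under independent segregation:

    LOD = sum over pools p of
          n_p * [ f_p*log10(f_p) + (1-f_p)*log10(1-f_p) - log10(1/2) ]

with the convention 0*log10(0) = 0.  This is the log10 likelihood ratio
of the per-pool binomial MLE against allele frequency 1/2, evaluated on
the estimated spore counts c_p = n_p * f_p; at complete cosegregation it
reduces to (n_inv + n_non) * log10(2).  Variants whose allele skew points
the same way in both pools reflect segregation distortion rather than
phenotype linkage and are flagged and excluded from linkage calls.

Suprathreshold variants are aggregated to genes (gene LOD = max over its
non-synonymous coding variants) and nearby suprathreshold genes are
merged into linkage blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .pooled_sequencing import PoolReadCounts
from .synthetic_cross import VariantSite

__all__ = [
    "LinkageRecord",
    "GeneLod",
    "LinkageBlock",
    "estimate_counts",
    "lod_score",
    "classify_direction",
    "build_linkage_records",
    "call_linked_variants",
    "aggregate_genes",
    "cluster_blocks",
]

#: direction labels
INV_LINKED = "invasive_parent_linked"
NON_LINKED = "noninvasive_parent_linked"
DISTORTION = "same_direction_distortion"

#: default merge window for block clustering, bp.  Chosen at the scale of
#: the multi-gene linkage blocks seen in yeast BSA scans (tens of kb).
DEFAULT_MERGE_WINDOW = 50_000


@dataclass(frozen=True)
class LinkageRecord:
    """Per-site linkage summary across the two pools."""

    site: VariantSite
    f_inv: Optional[float]  # fraction of invasive-pool reads with the B allele
    f_non: Optional[float]
    c_inv: Optional[float]  # estimated spore counts, real-valued
    c_non: Optional[float]
    lod: Optional[float]
    direction: Optional[str]
    no_call: bool = False  # zero depth in a pool: excluded from LOD


@dataclass(frozen=True)
class GeneLod:
    """Gene-level score: max LOD over the gene's non-synonymous variants.

    ``start``/``end`` span the positions of those variants (1-based,
    closed); a single-variant gene has a zero-width span (start == end).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    lod: float
    n_variants: int


@dataclass(frozen=True)
class LinkageBlock:
    """A run of suprathreshold genes separated by at most merge_window bp."""

    chrom: str
    start: int
    end: int
    genes: tuple
    max_lod: float


def estimate_counts(
    inv: PoolReadCounts, non: PoolReadCounts, n_inv: int, n_non: int
):
    """Estimate per-pool spore counts from read fractions.

    ``f_p`` is the fraction of the pool's reads matching the
    invasive-parent allele, and the estimated count of spores carrying
    that allele is ``c_p = n_p * f_p`` — the pool size multiplied by the
    matching read fraction, kept real-valued (no rounding).  If either
    pool has zero depth the site is a no-call: ``(None, None, None, None)``.
    """
    if n_inv <= 0 or n_non <= 0:
        raise ValueError("pool sizes must be positive")
    if inv.depth == 0 or non.depth == 0:
        return None, None, None, None
    f_inv = inv.reads_b / inv.depth
    f_non = non.reads_b / non.depth
    return f_inv, f_non, n_inv * f_inv, n_non * f_non


def _pool_term(f: float, n: float) -> float:
    # n * [ f log10 f + (1-f) log10(1-f) + log10 2 ], with 0 log 0 = 0
    t = math.log10(2.0)
    if f > 0.0:
        t += f * math.log10(f)
    if f < 1.0:
        t += (1.0 - f) * math.log10(1.0 - f)
    return n * t


def lod_score(f_inv: float, f_non: float, n_inv: int, n_non: int) -> float:
    """LOD of the observed pool allele fractions against 1/2:1/2 segregation.

    Non-negative; zero iff both fractions are exactly 1/2; equal to
    ``(n_inv + n_non) * log10(2)`` at complete, opposite fixation.
    """
    for f in (f_inv, f_non):
        if not (0.0 <= f <= 1.0):
            raise ValueError("allele fractions must lie in [0, 1]")
    if n_inv <= 0 or n_non <= 0:
        raise ValueError("pool sizes must be positive")
    lod = _pool_term(f_inv, n_inv) + _pool_term(f_non, n_non)
    return max(lod, 0.0)  # clamp -0.0 / rounding at the null


def classify_direction(f_inv: float, f_non: float) -> str:
    """Label which parent's allele travels with which pool.

    Opposite skews are linkage signals; same-direction skew (both pools
    favouring one parent) is segregation distortion.
    """
    if f_inv > 0.5 > f_non:
        return INV_LINKED
    if f_inv < 0.5 < f_non:
        return NON_LINKED
    return DISTORTION


def build_linkage_records(
    inv_counts: Sequence[PoolReadCounts],
    non_counts: Sequence[PoolReadCounts],
    n_inv: int,
    n_non: int,
) -> list:
    """Pair the two pools' counts per site and compute LOD records."""
    if len(inv_counts) != len(non_counts):
        raise ValueError("pool count lists differ in length")
    records = []
    for inv, non in zip(inv_counts, non_counts):
        if (inv.site.chrom, inv.site.pos) != (non.site.chrom, non.site.pos):
            raise ValueError(
                f"site mismatch between pools at {inv.site.chrom}:{inv.site.pos}"
            )
        f_inv, f_non, c_inv, c_non = estimate_counts(inv, non, n_inv, n_non)
        if f_inv is None:
            records.append(
                LinkageRecord(inv.site, None, None, None, None, None, None, True)
            )
            continue
        records.append(
            LinkageRecord(
                site=inv.site,
                f_inv=f_inv,
                f_non=f_non,
                c_inv=c_inv,
                c_non=c_non,
                lod=lod_score(f_inv, f_non, n_inv, n_non),
                direction=classify_direction(f_inv, f_non),
            )
        )
    return records


def call_linked_variants(records: Sequence[LinkageRecord], threshold: float) -> list:
    """Variants passing the LOD cutoff (strict ``lod > threshold``).

    No-call and segregation-distortion records never pass; they stay in
    the caller's full record list with their flags.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [
        r
        for r in records
        if not r.no_call and r.direction != DISTORTION and r.lod > threshold
    ]


def aggregate_genes(
    records: Sequence[LinkageRecord],
    gene_of: Mapping,
    chrom_order: Optional[Sequence[str]] = None,
) -> list:
    """Aggregate per-variant LODs to genes.

    ``gene_of`` maps ``(chrom, pos)`` to a gene id for every variant that
    is coding and non-synonymous; variants absent from the mapping (or
    no-called) are skipped.  Gene LOD is the max over member variants,
    the span is the min..max of their positions.  Genes come back sorted
    by (chromosome order, start); order of the input records is
    irrelevant.
    """
    by_gene: dict = {}
    for r in records:
        if r.no_call:
            continue
        gene = gene_of.get((r.site.chrom, r.site.pos))
        if gene is None:
            continue
        entry = by_gene.setdefault(gene, [r.site.chrom, [], []])
        if entry[0] != r.site.chrom:
            raise ValueError(f"gene {gene} spans multiple chromosomes")
        entry[1].append(r.site.pos)
        entry[2].append(r.lod)
    order = {c: i for i, c in enumerate(chrom_order)} if chrom_order else None
    genes = [
        GeneLod(
            gene_id=g,
            chrom=chrom,
            start=min(positions),
            end=max(positions),
            lod=max(lods),
            n_variants=len(positions),
        )
        for g, (chrom, positions, lods) in by_gene.items()
    ]
    genes.sort(
        key=lambda g: (
            order[g.chrom] if order is not None else g.chrom,
            g.start,
            g.gene_id,
        )
    )
    return genes


def cluster_blocks(
    gene_lods: Sequence[GeneLod],
    threshold: float,
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> list:
    """Merge suprathreshold genes into linkage blocks.

    Genes with ``lod > threshold`` on the same chromosome join one block
    when the gap between their spans is at most ``merge_window`` bp.
    Input must be sorted by (chrom, start), as :func:`aggregate_genes`
    returns it.
    """
    blocks: list = []
    current: Optional[list] = None  # [chrom, start, end, genes, max_lod]

    def flush():
        if current is not None:
            blocks.append(
                LinkageBlock(
                    chrom=current[0],
                    start=current[1],
                    end=current[2],
                    genes=tuple(current[3]),
                    max_lod=current[4],
                )
            )

    for g in gene_lods:
        if g.lod <= threshold:
            continue
        if (
            current is not None
            and g.chrom == current[0]
            and g.start - current[2] <= merge_window
        ):
            current[2] = max(current[2], g.end)
            current[3].append(g.gene_id)
            current[4] = max(current[4], g.lod)
        else:
            flush()
            current = [g.chrom, g.start, g.end, [g.gene_id], g.lod]
    flush()
    return blocks
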