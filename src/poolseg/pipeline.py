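"""End-to-end orchestration: simulate a cross, sequence the pools, map linkage.

This ties the stages together the way the CLI exposes them:

    parents -> tetrads -> phenotypes -> pools -> pooled sequencing
            -> annotate -> non-synonymous filter -> LOD -> threshold
            -> gene aggregation -> block clustering

A single integer seed drives every stage through a spawned seed tree, so
one run is reproducible end to end and stages are independently
re-runnable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import GeneModel, NONSYNONYMOUS, annotate_variant
from .io_formats import build_reference, make_gene_models
from .linkage import (
    DISTORTION,
    DEFAULT_MERGE_WINDOW,
    aggregate_genes,
    build_linkage_records,
    call_linked_variants,
    cluster_blocks,
)
from .pooled_sequencing import SequencingSpec, sequence_pool
from .synthetic_cross import (
    CausalModel,
    GenomeSpec,
    SegregantPools,
    VariantSite,
    assign_phenotypes,
    build_pools,
    generate_complete_tetrads,
    make_parents,
)

__all__ = [
    "CrossConfig",
    "SimulatedCross",
    "MappingResult",
    "simulate_cross",
    "annotate_sites",
    "map_linkage",
    "run_pipeline",
    "plot_lod",
]

#: toy karyotype used by default: ~1 Mb over three chromosomes, a scaled
#: stand-in for the 12 Mb yeast genome that keeps simulations fast while
#: leaving room for multiple independent linkage blocks.
DEFAULT_CHROMOSOMES = (("chrI", 400_000), ("chrII", 300_000), ("chrIII", 300_000))


@dataclass
class CrossConfig:
    """All simulator and mapping parameters for one run."""

    chromosomes: tuple = DEFAULT_CHROMOSOMES
    genetic_rate: float = 0.35  # cM/kb
    divergence: float = 0.003  # parental divergence (0.3%, a 99.7%-identity cross)
    n_tetrads: int = 31
    viability: float = 0.9
    pool_targets: Optional[tuple] = None  # e.g. (37, 63); None = use all spores
    # causal architecture: one gated effect locus placed mid-chromosome
    causal_chrom: str = "chrII"
    gate: bool = True
    beta: float = 1.0
    noise_sd: float = 0.4
    tau_lo: float = 0.4
    tau_hi: float = 0.7
    # sequencing
    mean_depth: float = 120.0
    error_rate: float = 0.002
    # mapping
    lod_threshold: float = 3.0
    merge_window: int = DEFAULT_MERGE_WINDOW
    # toy annotation
    gene_length: int = 1200
    gene_spacing: int = 800

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(
            chromosomes=self.chromosomes, genetic_rate=self.genetic_rate
        )

    def sequencing_spec(self) -> SequencingSpec:
        return SequencingSpec(mean_depth=self.mean_depth, error_rate=self.error_rate)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromosomes"] = [list(c) for c in self.chromosomes]
        if self.pool_targets is not None:
            d["pool_targets"] = list(self.pool_targets)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "CrossConfig":
        data = dict(data)
        if "chromosomes" in data:
            data["chromosomes"] = tuple(tuple(c) for c in data["chromosomes"])
        if data.get("pool_targets") is not None:
            data["pool_targets"] = tuple(data["pool_targets"])
        return cls(**data)


@dataclass
class SimulatedCross:
    """Everything the simulation stage produces, in memory."""

    config: CrossConfig
    spec: GenomeSpec
    sites: list
    causal_index: int
    model: CausalModel
    tetrads: list
    pools: SegregantPools
    inv_counts: list
    non_counts: list
    reference: dict
    genes: list

    @property
    def causal_site(self) -> VariantSite:
        return self.sites[self.causal_index]


@dataclass
class MappingResult:
    records: list
    linked: list
    gene_lods: list
    blocks: list
    annotations: dict
    report: dict


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _pick_causal_index(sites: Sequence[VariantSite], chrom: str) -> int:
    """Variant site nearest the midpoint of the causal chromosome."""
    candidates = [(i, s) for i, s in enumerate(sites) if s.chrom == chrom]
    if not candidates:
        raise RuntimeError(f"no variant sites on causal chromosome {chrom}")
    positions = np.array([s.pos for _, s in candidates])
    mid = (positions.min() + positions.max()) / 2
    return candidates[int(np.argmin(np.abs(positions - mid)))][0]


def simulate_cross(config: CrossConfig, seed: int) -> SimulatedCross:
    """Simulate parents, meioses, phenotypes, pools, and pooled sequencing."""
    (
        rng_parents,
        rng_tetrads,
        rng_pheno,
        rng_pools,
        rng_seq_inv,
        rng_seq_non,
        rng_ref,
        rng_genes,
    ) = _spawn(seed, 8)
    spec = config.genome_spec()
    sites = make_parents(spec, config.divergence, rng_parents)
    causal_index = _pick_causal_index(sites, config.causal_chrom)
    model = CausalModel(
        effect_sites=((causal_index, config.beta),),
        gate_site=causal_index if config.gate else None,
        noise_sd=config.noise_sd,
        tau_lo=config.tau_lo,
        tau_hi=config.tau_hi,
    )
    tetrads = generate_complete_tetrads(
        config.n_tetrads, sites, spec, viability=config.viability, seed=rng_tetrads
    )
    assign_phenotypes(tetrads, model, rng_pheno)
    pools = build_pools(tetrads, targets=config.pool_targets, seed=rng_pools)
    seq_spec = config.sequencing_spec()
    inv_counts = sequence_pool(
        pools.invasive, sites, seq_spec, rng_seq_inv, pool_label="invasive"
    )
    non_counts = sequence_pool(
        pools.non_invasive, sites, seq_spec, rng_seq_non, pool_label="non_invasive"
    )
    reference = build_reference(spec, sites, rng_ref)
    genes = make_gene_models(
        spec, rng_genes, gene_length=config.gene_length, spacing=config.gene_spacing
    )
    return SimulatedCross(
        config=config,
        spec=spec,
        sites=sites,
        causal_index=causal_index,
        model=model,
        tetrads=tetrads,
        pools=pools,
        inv_counts=inv_counts,
        non_counts=non_counts,
        reference=reference,
        genes=genes,
    )


def annotate_sites(
    sites: Sequence[VariantSite],
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> dict:
    """Consequence call for every site, keyed by (chrom, pos)."""
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    calls = {}
    for s in sites:
        calls[(s.chrom, s.pos)] = annotate_variant(
            s, by_chrom.get(s.chrom, ()), reference
        )
    return calls


def map_linkage(
    inv_counts,
    non_counts,
    n_inv: int,
    n_non: int,
    annotations: Mapping,
    chrom_order: Sequence[str],
    lod_threshold: float = 3.0,
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> MappingResult:
    """Annotation filter, LOD scan, gene aggregation, block clustering.

    The run report partitions every input variant into exactly one of:
    noncoding_dropped, synonymous_dropped, no_call, below_threshold,
    distortion_flagged (suprathreshold but same-direction skew), linked.
    """
    records = build_linkage_records(inv_counts, non_counts, n_inv, n_non)
    nonsyn_keys = {
        key
        for key, call in annotations.items()
        if call.consequence in NONSYNONYMOUS
    }
    gene_of = {
        key: annotations[key].gene_id for key in nonsyn_keys
    }

    n_noncoding = sum(
        1 for c in annotations.values() if c.consequence == "noncoding"
    )
    n_synonymous = sum(
        1 for c in annotations.values() if c.consequence == "synonymous"
    )
    nonsyn_records = [
        r for r in records if (r.site.chrom, r.site.pos) in nonsyn_keys
    ]
    n_no_call = sum(1 for r in nonsyn_records if r.no_call)
    linked = call_linked_variants(nonsyn_records, lod_threshold)
    n_distortion = sum(
        1
        for r in nonsyn_records
        if not r.no_call and r.direction == DISTORTION and r.lod > lod_threshold
    )
    n_below = len(nonsyn_records) - n_no_call - len(linked) - n_distortion

    gene_lods = aggregate_genes(nonsyn_records, gene_of, chrom_order)
    blocks = cluster_blocks(gene_lods, lod_threshold, merge_window)

    report = {
        "n_variants": len(records),
        "n_noncoding_dropped": n_noncoding,
        "n_synonymous_dropped": n_synonymous,
        "n_no_call": n_no_call,
        "n_below_threshold": n_below,
        "n_distortion_flagged": n_distortion,
        "n_linked": len(linked),
        "n_genes_scored": len(gene_lods),
        "n_blocks": len(blocks),
        "lod_threshold": lod_threshold,
        "merge_window": merge_window,
        "n_inv": n_inv,
        "n_non": n_non,
    }
    return MappingResult(
        records=records,
        linked=linked,
        gene_lods=gene_lods,
        blocks=blocks,
        annotations=dict(annotations),
        report=report,
    )


def run_pipeline(config: CrossConfig, seed: int):
    """One-shot simulate + map; returns (SimulatedCross, MappingResult)."""
    sim = simulate_cross(config, seed)
    annotations = annotate_sites(sim.sites, sim.genes, sim.reference)
    result = map_linkage(
        sim.inv_counts,
        sim.non_counts,
        sim.pools.n_inv,
        sim.pools.n_non,
        annotations,
        chrom_order=sim.spec.names,
        lod_threshold=config.lod_threshold,
        merge_window=config.merge_window,
    )
    result.report["n_tetrads"] = len(sim.tetrads)
    result.report["n_spores"] = 4 * len(sim.tetrads)
    result.report["seed"] = seed
    return sim, result


def plot_lod(
    records,
    path: str,
    chrom_order: Sequence[str],
    threshold: float = 3.0,
) -> None:
    """Per-chromosome LOD scatter with the cutoff drawn as a dashed line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [c for c in chrom_order]
    fig, axes = plt.subplots(
        1, max(len(chroms), 1), figsize=(4 * max(len(chroms), 1), 3), sharey=True
    )
    if len(chroms) == 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        xs = [r.site.pos / 1000 for r in records if r.site.chrom == chrom and not r.no_call]
        ys = [r.lod for r in records if r.site.chrom == chrom and not r.no_call]
        ax.scatter(xs, ys, s=4, color="#444444")
        ax.axhline(threshold, linestyle="--", color="crimson", linewidth=1)
        ax.set_title(chrom)
        ax.set_xlabel("position (kb)")
    axes[0].set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
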