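"""Readers and writers for the formats the pipeline touches.

FASTA (Biopython), GFF3 (gffutils for parsing, a small emitter for
writing), VCF 4.2 (pysam, with AD allelic-depth FORMAT fields for the
pooled samples), flat TSVs (pandas), BED (1-based closed spans converted
to 0-based half-open), and a YAML run manifest.

Chromosome order is taken from the genome spec / manifest, never sorted
lexicographically.  All writers are deterministic: re-running on
identical inputs produces byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import ConsequenceCall, GeneModel
from .linkage import GeneLod, LinkageBlock, LinkageRecord
from .pooled_sequencing import PoolReadCounts
from .synthetic_cross import GenomeSpec, RngLike, VariantSite, as_rng

__all__ = [
    "Manifest",
    "load_manifest",
    "save_manifest",
    "build_reference",
    "write_fasta",
    "read_fasta",
    "make_gene_models",
    "write_gff3",
    "read_gff3",
    "write_parents_vcf",
    "read_parents_vcf",
    "write_pools_vcf",
    "read_vcf_pools",
    "annotations_to_frame",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "records_to_frame",
    "genes_to_frame",
    "write_outputs",
    "read_blocks_bed",
]

INV_POOL = "invasive"
NON_POOL = "non_invasive"


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class Manifest:
    """Paths and parameters for one pipeline run."""

    fasta: Optional[str] = None
    gff3: Optional[str] = None
    parents_vcf: Optional[str] = None
    pools_vcf: Optional[str] = None
    n_inv: int = 37
    n_non: int = 63
    lod_threshold: float = 3.0
    merge_window: int = 50_000
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_inv <= 0 or self.n_non <= 0:
            raise ValueError("pool sizes must be positive")


def load_manifest(path: str) -> Manifest:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    m = Manifest(**data)
    base = os.path.dirname(os.path.abspath(path))
    for attr in ("fasta", "gff3", "parents_vcf", "pools_vcf"):
        p = getattr(m, attr)
        if p is None:
            continue
        if not os.path.isabs(p):
            p = os.path.join(base, p)
            setattr(m, attr, p)
        if not os.path.exists(p):
            raise FileNotFoundError(f"manifest refers to missing {attr}: {p}")
    return m


def save_manifest(m: Manifest, path: str) -> None:
    data = {
        k: v
        for k, v in m.__dict__.items()
        if v is not None and (k != "params" or v)
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# reference FASTA
# ---------------------------------------------------------------------------

def build_reference(
    spec: GenomeSpec, sites: Sequence[VariantSite], seed: RngLike = None
) -> dict:
    """Random reference sequences consistent with the variant REF alleles."""
    rng = as_rng(seed)
    bases = np.array(["A", "C", "G", "T"])
    seqs = {}
    for chrom, length in spec.chromosomes:
        arr = bases[rng.integers(0, 4, size=length)]
        seqs[chrom] = arr
    for s in sites:
        seqs[s.chrom][s.pos - 1] = s.ref_allele
    return {c: "".join(a) for c, a in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# gene models / GFF3
# ---------------------------------------------------------------------------

def make_gene_models(
    spec: GenomeSpec,
    seed: RngLike = None,
    gene_length: int = 1200,
    spacing: int = 800,
) -> list:
    """Tile each chromosome with single-CDS genes of fixed length.

    Gene length must be a multiple of 3; strands alternate pseudo-randomly.
    This yields a gene-dense toy annotation (compact, yeast-like) so a
    realistic share of variant sites lands in coding sequence.
    """
    if gene_length % 3 != 0:
        raise ValueError("gene_length must be a multiple of 3")
    rng = as_rng(seed)
    genes = []
    counter = 0
    for chrom, length in spec.chromosomes:
        start = spacing + 1
        while start + gene_length - 1 <= length - spacing:
            counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"g{counter:04d}",
                    chrom=chrom,
                    strand=strand,
                    cds=((start, start + gene_length - 1),),
                )
            )
            start += gene_length + spacing
    return genes


def _fmt_domains(gene: GeneModel) -> str:
    return ",".join(f"{n}:{a}-{b}" for n, a, b in gene.domains)


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Emit gene + CDS features, phase-aware, with domains as an attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.domains:
                attrs += f";domains={_fmt_domains(g)}"
            fh.write(
                f"{g.chrom}\tpoolseg\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            ivs = g.cds if g.strand == "+" else tuple(reversed(g.cds))
            cum = 0
            for a, b in ivs:
                phase = (3 - cum % 3) % 3
                fh.write(
                    f"{g.chrom}\tpoolseg\tCDS\t{a}\t{b}\t.\t{g.strand}\t{phase}\t"
                    f"ID=cds-{g.gene_id};Parent={g.gene_id}\n"
                )
                cum += b - a + 1


def _parse_domains(value: str) -> tuple:
    doms = []
    for part in value.split(","):
        if not part:
            continue
        name, span = part.split(":")
        a, b = span.split("-")
        doms.append((name, int(a), int(b)))
    return tuple(doms)


def read_gff3(path: str) -> list:
    """Load gene models (CDS features grouped by gene) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds = sorted(
            (c.start, c.end) for c in db.children(g, featuretype="CDS")
        )
        doms = ()
        if "domains" in g.attributes:
            doms = _parse_domains(g.attributes["domains"][0])
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                cds=tuple(cds),
                domains=doms,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(spec_contigs, samples, with_ad: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in spec_contigs:
        header.contigs.add(name, length=length)
    header.info.add(
        "PREF", 1, "String", "Parent carrying the REF allele (A=non-invasive, B=invasive)"
    )
    header.formats.add("GT", 1, "String", "Genotype")
    if with_ad:
        header.formats.add("AD", "R", "Integer", "Allelic depths for ref and alt alleles")
        header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s)
    return header


def write_parents_vcf(
    sites: Sequence[VariantSite], spec: GenomeSpec, path: str
) -> None:
    """Two-sample VCF of parental differences (GT 0/0 vs 1/1)."""
    header = _vcf_header(spec.chromosomes, ["parent_A", "parent_B"], with_ad=False)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for s in sites:
            rec = vcf.new_record(
                contig=s.chrom,
                start=s.pos - 1,
                stop=s.pos,
                alleles=(s.ref_allele, s.alt_allele),
            )
            rec.info["PREF"] = s.parent_of_ref
            ref_gt, alt_gt = (0, 0), (1, 1)
            if s.parent_of_ref == "A":
                rec.samples["parent_A"]["GT"] = ref_gt
                rec.samples["parent_B"]["GT"] = alt_gt
            else:
                rec.samples["parent_A"]["GT"] = alt_gt
                rec.samples["parent_B"]["GT"] = ref_gt
            vcf.write(rec)


def write_pools_vcf(
    inv_counts: Sequence[PoolReadCounts],
    non_counts: Sequence[PoolReadCounts],
    spec: GenomeSpec,
    path: str,
) -> None:
    """One sample column per phenotype pool, with AD allelic depths."""
    header = _vcf_header(spec.chromosomes, [INV_POOL, NON_POOL], with_ad=True)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for inv, non in zip(inv_counts, non_counts):
            s = inv.site
            rec = vcf.new_record(
                contig=s.chrom,
                start=s.pos - 1,
                stop=s.pos,
                alleles=(s.ref_allele, s.alt_allele),
            )
            rec.info["PREF"] = s.parent_of_ref
            for label, counts in ((INV_POOL, inv), (NON_POOL, non)):
                # AD is (ref reads, alt reads); reads_b counts the B-parent allele
                if s.parent_of_ref == "A":
                    ad = (int(counts.reads_a), int(counts.reads_b))
                else:
                    ad = (int(counts.reads_b), int(counts.reads_a))
                rec.samples[label]["AD"] = ad
                rec.samples[label]["DP"] = int(counts.depth)
            vcf.write(rec)


def read_parents_vcf(path: str) -> list:
    """Load parental variant sites (biallelic SNVs) from a two-parent VCF."""
    sites = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if len(rec.alleles) != 2 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            sites.append(
                VariantSite(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    parent_of_ref=rec.info.get("PREF", "A"),
                )
            )
    return sites


def read_vcf_pools(path: str):
    """Read a two-pool VCF back into per-pool read-count lists.

    Returns ``(inv_counts, non_counts, n_skipped)``; multi-allelic or
    non-SNV records are skipped and counted.  Read counts are oriented to
    the invasive parent via the PREF INFO tag (reads_b = depth of the
    parent-B allele).
    """
    inv_counts, non_counts = [], []
    skipped = 0
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError(f"expected exactly 2 pool samples, found {len(samples)}")
        for rec in vcf.fetch() if vcf.index else vcf:
            if (
                len(rec.alleles) != 2
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
            ):
                skipped += 1
                continue
            pref = rec.info.get("PREF", "A")
            site = VariantSite(
                chrom=rec.contig,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                parent_of_ref=pref,
            )
            per_pool = []
            for sample in samples:
                fmt = rec.samples[sample]
                ad = fmt.get("AD")
                if ad is None:
                    raise ValueError(f"missing AD at {rec.contig}:{rec.pos}")
                ref_reads, alt_reads = int(ad[0]), int(ad[1])
                reads_b = alt_reads if pref == "A" else ref_reads
                per_pool.append(
                    PoolReadCounts(
                        site=site,
                        pool=sample,
                        depth=ref_reads + alt_reads,
                        reads_b=reads_b,
                    )
                )
            inv_counts.append(per_pool[0])
            non_counts.append(per_pool[1])
    return inv_counts, non_counts, skipped


# ---------------------------------------------------------------------------
# genotype matrix / pool membership
# ---------------------------------------------------------------------------

def write_genotype_matrix(sites, tetrads, path: str) -> None:
    """Sites x spores matrix of parental origins (A/B), spores as columns."""
    cols = {}
    for ti, t in enumerate(tetrads):
        for si, s in enumerate(t.spores):
            name = f"t{ti + 1:03d}s{si + 1}"
            cols[name] = np.where(s.origin == 1, "B", "A")
    frame = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            **cols,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def _chrom_rank(chrom_order):
    order = {c: i for i, c in enumerate(chrom_order)}
    return lambda c: order.get(c, len(order))


def records_to_frame(
    records: Sequence[LinkageRecord],
    annotations: Optional[Mapping] = None,
    chrom_order: Sequence[str] = (),
) -> pd.DataFrame:
    rows = []
    for r in records:
        ann: Optional[ConsequenceCall] = (
            annotations.get((r.site.chrom, r.site.pos)) if annotations else None
        )
        rows.append(
            {
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "ref": r.site.ref_allele,
                "alt": r.site.alt_allele,
                "parent_of_ref": r.site.parent_of_ref,
                "f_inv": r.f_inv,
                "f_non": r.f_non,
                "c_inv": r.c_inv,
                "c_non": r.c_non,
                "lod": r.lod,
                "direction": r.direction,
                "no_call": r.no_call,
                "gene": ann.gene_id if ann else None,
                "consequence": ann.consequence if ann else None,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        rank = _chrom_rank(chrom_order)
        frame = frame.sort_values(
            by=["chrom", "pos"], key=lambda col: col.map(rank) if col.name == "chrom" else col
        ).reset_index(drop=True)
    return frame


def annotations_to_frame(calls: Sequence[ConsequenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "gene": c.gene_id,
                "codon_index": c.codon_index,
                "ref_aa": c.ref_aa,
                "alt_aa": c.alt_aa,
                "consequence": c.consequence,
            }
            for c in calls
        ],
        columns=["chrom", "pos", "gene", "codon_index", "ref_aa", "alt_aa", "consequence"],
    )


def genes_to_frame(genes: Sequence[GeneLod]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "lod": g.lod,
                "n_variants": g.n_variants,
            }
            for g in genes
        ],
        columns=["gene", "chrom", "start", "end", "lod", "n_variants"],
    )


def write_outputs(
    records: Sequence[LinkageRecord],
    genes: Sequence[GeneLod],
    blocks: Sequence[LinkageBlock],
    outdir: str,
    annotations: Optional[Mapping] = None,
    chrom_order: Sequence[str] = (),
) -> dict:
    """Write variant/gene TSVs and a blocks BED; returns the paths.

    BED spans convert the internal 1-based closed coordinates to BED's
    0-based half-open convention (start-1, end).
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "variants": os.path.join(outdir, "variant_lod.tsv"),
        "genes": os.path.join(outdir, "gene_lod.tsv"),
        "blocks": os.path.join(outdir, "blocks.bed"),
    }
    records_to_frame(records, annotations, chrom_order).to_csv(
        paths["variants"], sep="\t", index=False
    )
    genes_to_frame(genes).to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["blocks"], "w") as fh:
        for i, b in enumerate(blocks, start=1):
            name = f"block_{i}|" + ",".join(b.genes)
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{name}\t{b.max_lod:.4f}\n")
    return paths


def read_blocks_bed(path: str) -> list:
    """Read the BED back into LinkageBlock objects (1-based closed)."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start0, end, name, score = line.rstrip("\n").split("\t")
            genes = tuple(name.split("|", 1)[1].split(",")) if "|" in name else ()
            blocks.append(
                LinkageBlock(
                    chrom=chrom,
                    start=int(start0) + 1,
                    end=int(end),
                    genes=genes,
                    max_lod=float(score),
                )
            )
    return blocks
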