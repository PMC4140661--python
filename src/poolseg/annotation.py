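"""Codon-level consequence annotation of coding variants.

Classifies each SNV against gene models (CDS intervals, phase-aware via
translation order) and the reference sequence: noncoding, synonymous,
missense, stop_gained or stop_lost.  Codon and residue numbering is
1-based from the initiator codon, matching the field's "codon 142 / 409 /
477" usage; minus-strand variants are reverse-complemented before codon
lookup and translation uses the standard nuclear code.  Each variant is
annotated independently — two substitutions falling in one codon are not
combined into a joint codon change.

Also reports, for premature stops, which annotated protein domains are
lost, partially truncated, or left intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .synthetic_cross import VariantSite

__all__ = [
    "GeneModel",
    "ConsequenceCall",
    "TruncationReport",
    "annotate_variant",
    "filter_nonsynonymous",
    "truncation_report",
]

NONSYNONYMOUS = frozenset({"missense", "stop_gained", "stop_lost"})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene.

    ``cds`` holds 1-based closed intervals in genomic (ascending)
    coordinates; translation order is ascending for ``+`` genes and
    descending for ``-`` genes.  ``domains`` are optional protein-domain
    annotations as ``(name, aa_start, aa_end)`` in residue coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: tuple  # ((start, end), ...) ascending, non-overlapping
    domains: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ivs = tuple((int(a), int(b)) for a, b in self.cds)
        if not ivs:
            raise ValueError(f"{self.gene_id}: at least one CDS interval required")
        prev_end = 0
        for a, b in ivs:
            if a > b:
                raise ValueError(f"{self.gene_id}: CDS interval {a}..{b} inverted")
            if a <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or unsorted")
            prev_end = b
        object.__setattr__(self, "cds", ivs)
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        doms = tuple((str(n), int(a), int(b)) for n, a, b in self.domains)
        for name, a, b in doms:
            if not (1 <= a <= b <= self.protein_length):
                raise ValueError(
                    f"{self.gene_id}: domain {name} ({a}-{b}) outside protein "
                    f"of length {self.protein_length}"
                )
        object.__setattr__(self, "domains", doms)

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    def contains(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.cds)

    def cds_offset(self, pos: int) -> int:
        """1-based offset of a genomic position within the spliced,
        strand-oriented CDS."""
        if self.strand == "+":
            off = 0
            for a, b in self.cds:
                if pos > b:
                    off += b - a + 1
                elif pos >= a:
                    return off + (pos - a + 1)
                else:
                    break
        else:
            off = 0
            for a, b in reversed(self.cds):
                if pos < a:
                    off += b - a + 1
                elif pos <= b:
                    return off + (b - pos + 1)
                else:
                    break
        raise ValueError(f"{self.gene_id}: position {pos} not in CDS")

    def spliced_cds(self, ref_seq: str) -> str:
        """Strand-oriented coding sequence extracted from the reference."""
        parts = [ref_seq[a - 1 : b] for a, b in self.cds]
        seq = "".join(parts).upper()
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(frozen=True)
class ConsequenceCall:
    site: VariantSite
    gene_id: Optional[str]
    codon_index: Optional[int]  # 1-based residue number
    ref_codon: Optional[str]
    alt_codon: Optional[str]
    ref_aa: Optional[str]  # single-letter, '*' for stop
    alt_aa: Optional[str]
    consequence: str  # synonymous | missense | stop_gained | stop_lost | noncoding


@dataclass(frozen=True)
class TruncationReport:
    """Fate of annotated domains downstream of a premature stop."""

    lost: tuple  # domains entirely after the stop codon
    partial: tuple  # domains the stop falls inside
    intact: tuple  # domains entirely before the stop


def _classify(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense"


def annotate_variant(
    site: VariantSite,
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> ConsequenceCall:
    """Annotate one SNV against gene models and the reference sequence.

    The reference base at ``site.pos`` must equal ``site.ref_allele``
    (mismatch is a data error naming the offending position).  Variants
    outside every CDS are ``noncoding``.
    """
    ref_seq = str(reference[site.chrom])
    ref_base = ref_seq[site.pos - 1].upper()
    if ref_base != site.ref_allele.upper():
        raise ValueError(
            f"reference mismatch at {site.chrom}:{site.pos}: "
            f"FASTA has {ref_base}, variant says {site.ref_allele}"
        )
    gene = next(
        (g for g in gene_models if g.chrom == site.chrom and g.contains(site.pos)),
        None,
    )
    if gene is None:
        return ConsequenceCall(site, None, None, None, None, None, None, "noncoding")

    offset = gene.cds_offset(site.pos)  # 1-based within spliced CDS
    codon_index = (offset - 1) // 3 + 1
    within = (offset - 1) % 3
    cds = gene.spliced_cds(ref_seq)
    ref_codon = cds[(codon_index - 1) * 3 : codon_index * 3]

    alt_base = site.alt_allele.upper()
    if gene.strand == "-":
        alt_base = _COMPLEMENT[alt_base]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    ref_aa = str(Seq(ref_codon).translate())  # standard nuclear code
    alt_aa = str(Seq(alt_codon).translate())
    return ConsequenceCall(
        site=site,
        gene_id=gene.gene_id,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=_classify(ref_aa, alt_aa),
    )


def filter_nonsynonymous(calls: Sequence[ConsequenceCall]) -> list:
    """Keep only protein-changing calls (missense, stop_gained, stop_lost).

    Synonymous and noncoding calls are dropped; order is preserved.
    """
    return [c for c in calls if c.consequence in NONSYNONYMOUS]


def truncation_report(call: ConsequenceCall, gene: GeneModel) -> TruncationReport:
    """Classify annotated domains relative to a premature stop.

    A domain is *lost* iff it starts strictly after the stop codon,
    *partial* if the stop falls within it, *intact* if it ends before
    the stop.
    """
    if call.consequence != "stop_gained":
        raise ValueError("truncation_report applies to stop_gained calls only")
    stop = call.codon_index
    lost, partial, intact = [], [], []
    for dom in gene.domains:
        _, aa_start, aa_end = dom
        if aa_start > stop:
            lost.append(dom)
        elif aa_end < stop:
            intact.append(dom)
        else:
            partial.append(dom)
    return TruncationReport(lost=tuple(lost), partial=tuple(partial), intact=tuple(intact))
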