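# Methods

This note documents the models behind `poolseg`, the defaults and why
they were chosen, and what the synthetic data does and does not emulate.

## Cross simulation

**Parental genomes.** The two haploids differ at biallelic SNVs only.
Per chromosome the site count is Binomial(length, divergence) and
positions are uniform without replacement; ref/alt bases are uniform and
the parent carrying the reference base is random per site, so neither
parent is systematically the reference strain. The default divergence is
0.003 (99.7% identity, the scale of a laboratory-by-Σ1278b-like cross;
an SK1-like cross would be ~0.005).

**Meiosis.** A four-strand chiasma model without crossover interference:
per chromosome the chiasma count is Poisson(2d), d the genetic length in
Morgans; each chiasma picks one chromatid from each sister pair uniformly
and exchanges material distal to a uniform physical position; the four
products are assigned to spores with independent assortment across
chromosomes. Consequences used as test oracles: every heterozygous site
segregates exactly 2:2 within a tetrad, and the pairwise recombination
fraction converges to the Haldane value r = ½(1 − e^(−2d)). Interference
is deliberately omitted: it changes tetrad-type proportions but not the
2:2 bookkeeping or the pooled allele-frequency logic this package is
about, and Haldane gives a closed-form oracle. The default genetic rate
is 0.35 cM/kb, the approximate genome-wide *S. cerevisiae* average,
configurable per chromosome.

**Completeness.** The mating-type locus rides along as one extra 2:2
marker (default: midpoint of the first chromosome), so with four viable
spores the 2:2 mating-type condition holds automatically; it is still
checked as a guard. Spore viability is independent Bernoulli(0.9) by
default, so a meiosis completes with probability 0.9⁴ ≈ 0.66;
`generate_complete_tetrads` discards incomplete meioses, as tetrad
dissection does, and aborts with a diagnostic if the attempt budget
(50× the expected number) is exhausted.

**Phenotype.** A liability-threshold model: liability = Σ βᵢxᵢ + ε with
xᵢ = 1 if the spore carries the invasive-parent allele at effect site i
and ε ~ N(0, noise_sd). Spores above τ_hi are invasive, below τ_lo
non-invasive, otherwise intermediate; intermediates are excluded from
pooling. An optional epistatic gate locus — modelled on a
loss-of-function transcription-factor allele that abolishes filamentation
outright — forces non-invasion whenever the spore carries the
non-invasive parent's allele there, regardless of liability. Defaults
(β = 1, noise_sd = 0.4, τ = 0.4/0.7) put roughly 8% of spores (with the
gate; ~15% without) in the intermediate class, in the spirit of the
screening regime where a modest minority of spores is ambiguous, without
matching any particular screen. Pools can be subsampled without
replacement to fixed target sizes (e.g. 37/63 or 51/24) to mimic
fixed-size pool designs; by default all non-intermediate spores are
pooled.

**Randomness.** Every public operation accepts an integer seed or a
numpy Generator; composite stages split one seed via
`numpy.random.SeedSequence.spawn`, so a single integer reproduces a full
run and stages remain independently replayable.

## Pooled sequencing

Sequencing is simulated at the allele-count level: per site, depth is
Poisson(mean_depth) (a fixed-depth mode exists for exact distributional
tests) and the invasive-allele read count is Binomial(depth, q(1−e) +
(1−q)e), where q is the pool's true allele frequency and e a symmetric
allele-flip error. Reads matching neither parental allele are assumed
discarded upstream, so the two allele counts conserve depth exactly.
Defaults: mean_depth = 120, so ">100-fold per pool" holds with margin;
e = 0.002, the scale of a post-filtering short-read miscall rate. Library
geometry, mapping bias, duplicates and indels are not modelled — they act
upstream of the allele counts this model starts from.

## Linkage statistics

`c_p = n_p · f_p` converts the matching-read fraction of each pool into a
real-valued estimated spore count; no rounding, since rounding discards
information. The LOD is the per-pool binomial likelihood ratio of the
MLE against allele frequency ½ evaluated on those counts (see README for
the formula); it is non-negative, zero only at ½/½, symmetric under
relabelling the parents, and equals (n_inv+n_non)·log10 2 at complete
opposite fixation. A brute-force log-pmf oracle pins the implementation
in the tests. Sites with zero depth in either pool are no-calls, not
imputed. Same-direction skew in both pools is transmission distortion,
not phenotype linkage; such records are flagged and never pass the
linkage call, but remain in the output.

Thresholding is strict (`lod > cutoff`; default 3, with 4 the
conventional choice for more divergent crosses producing unwieldy
candidate lists). Gene scores take the **max** over a gene's
non-synonymous variants rather than the sum — co-inherited variants in
one gene share linkage, so summing would inflate with variant count —
and the gene span is the min..max of those variant positions
(zero-width for a single variant). Suprathreshold genes on one
chromosome merge into a linkage block when the gap between spans is at
most `merge_window` (default 50 kb, anchored to the tens-of-kb scale of
multi-gene blocks in yeast BSA scans; the rule is parameterised because
published block counts rarely state one).

Null calibration: with no causal locus the fraction of variants
exceeding LOD 3 is small, and it *falls* as the pools exhaust a larger
share of a fixed spore supply, because pooling nearly all spores pins
the within-pool allele frequency near ½ (hypergeometric shrinkage).
At fixed read depth the read-noise contribution to the LOD grows like
n_pool/depth, so exceedance would not fall with pool size if spores were
unlimited; the test suite therefore fixes the tetrad count and compares
small against near-exhaustive pools.

## Variant annotation

Gene models are CDS interval lists (1-based closed, ascending), with
translation order derived from strand; multi-exon and minus-strand genes
are supported, and CDS length must be a codon multiple. For a SNV, the
1-based offset within the spliced strand-oriented CDS gives
codon_index = ⌈offset/3⌉; minus-strand alleles are complemented before
codon substitution, and translation uses the standard nuclear code
(Biopython). Classes: noncoding, synonymous, missense, stop_gained,
stop_lost. Each variant is annotated independently — two substitutions
in one codon are not merged into a joint codon change, matching how BSA
variant lists report SNVs separately. The non-synonymous filter retains
missense/stop_gained/stop_lost. For premature stops, annotated protein
domains are reported as lost (domain starts after the stop), partial
(stop inside the domain) or intact.

## Synthetic defaults and scale

The default toy genome is ~1 Mb over three chromosomes (400/300/300 kb),
a scaled stand-in for the 12 Mb yeast genome chosen so that a full
simulate-and-map run takes about a second while still holding ~3,000
variant sites, several hundred genes (1.2 kb single-CDS genes tiled at
0.8 kb spacing — gene-dense, as yeast is) and room for independent
linkage blocks. The default cross simulates 31 complete tetrads (124
spores). The statistical tests state their own problem sizes (e.g.
2,000–5,000 tetrads for map-function checks, 100 replicates for
recovery and cosegregation-LOD bounds).

What passing tests on this generator do **not** show: robustness to
alignment/mapping artefacts, reference bias, coverage heterogeneity
along real chromosomes, aneuploidy, gene conversion, de novo mutation,
or mis-phenotyped spores — none of which the generator emulates.

## Known limitations

* No crossover or chromatid interference; tetrad-type frequencies are
  those of the no-interference model.
* Single-locus liability with one optional gate; no multi-locus QTL
  model, interval mapping, or confidence intervals on block boundaries —
  the scan reports raw LOD only.
* Indels, multi-allelic sites and joint codon changes are out of scope;
  such records are skipped (with counts) at VCF ingestion.
* The LOD treats estimated spore counts as binomial observations; it
  inherits the read-fraction noise of the pools rather than modelling
  read depth explicitly.
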