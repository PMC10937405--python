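# Methods

`svdosage` implements a desk-scale version of a pan-genome analysis in
which structural variants (SVs) act as bidirectional dosage regulators of
gene expression in *Brassica oleracea*: a panel of 27 assembled genomes
defines a nonredundant SV catalog, a ~700-accession population is
genotyped for those SVs, and each SV is classified as *suppressing* or
*promoting* the expression of its nearest gene. This note records the
models, thresholds and design choices behind every stage.

## SV catalog

Per-genome SV calls are collapsed into a nonredundant catalog per SV
class. Spanned variants (deletions, CNVs, inversions, translocations)
merge when their reference intervals overlap or are bookended
(`end == start`, read literally as "continuous"); the merged record's
source-genome set is the union of its members. Insertions have no
reference extent, so they cluster by breakpoint proximity (≤ 10 bp) and
alternate-allele length similarity (≤ 10% relative difference). This is
a coordinate proxy for sequence-identity clustering (the field's usual
CD-HIT at 95% identity): it needs no allele sequences and is exact on
synthetic data where planted insertions never collide. Merging is
idempotent and invariant to input order; both properties are tested, and
the result is checked against an independent pairwise-connectivity
oracle.

Genomic-context labels use the fixed precedence
exon > intron > upstream > downstream > intergenic when an SV touches
several features; upstream/downstream are strand-aware 3-kb windows.
The precedence is a design choice (coding impact outranks regulatory
proximity); no published rule exists for the ambiguous cases. Density
profiles rescale gene bodies to 50 relative bins (the body
normalization is not specified anywhere; 50 bins resolves the flank
gradient without overfitting short genes) and use absolute 100-bp bins
over 5-kb flanks.

Pan-SV saturation is modeled as P(n) = A − B·exp(−n/C) fitted by least
squares over random genome orderings; the predicted total SV count is
the mean asymptote A and its uncertainty the standard deviation of A
across orderings. The exponential form is a documented choice — the
modeling reference behind the original analysis does not pin down the
functional form — and the fit recovers noiseless curves to well under
1%. Constant (already saturated) curves short-circuit to A = the
constant. LTR insertion ages use the molecular clock T = K/(2µ) with
µ = 1.3 × 10⁻⁸ substitutions per site per year.

## Pan gene families

A syntenic family is present in a genome when its copy count there is
≥ 1. With n panel genomes: core = present in all n; softcore = present
in ≥ ⌈0.9·n⌉ but not all (25–26 of 27); private = exactly one;
dispensable = everything between. Loss analyses read ">50% retained"
strictly (14 of 27 qualifies, 13 does not), and a morphotype claims a
family's loss only when it holds strictly more than 70% of the losing
genomes — at most one morphotype can ever qualify. Homoeolog-retention
analysis treats triplets with all three subgenome copies (LF/MF1/MF2)
in the reference genome as ancestral three-copy genes; a triplet enters
the analysis when all three copies survive in strictly more than half
of the genomes and at least one genome lost a copy. Family-level loss
uses presence (≥ 1 copy); triplet eligibility requires exactly the
three ancestral copies — the two Methods-level rules are genuinely
different and are implemented separately.

## Dosage classification

Each SV links to its closest gene by edge-to-edge gap within a 10-kb
radius; adjacency counts as gap 0; ties break deterministically on gene
id. Genes with more than one SV inside the radius are excluded, keeping
the genotype–expression attribution unambiguous. Distance bins are
{CDS, intron, 0–1.5 kb, 1.5–3 kb, 3–5 kb, 5–10 kb}; only the endpoints
(CDS, 5–10 kb) are externally fixed, the interior boundaries are the
package's choice and configurable. Upstream and downstream flanks pool
by |distance|; the signed, strand-aware distance is retained in every
link.

Genotypes are orientation-free: whichever allele carries more sequence
is "presence", so carriers of a deletion are the *absence* group and
the labels survive re-referencing to a different genome. Heterozygous
calls count as carrying the alternate allele (accession-level
binarization: the counting unit throughout is the accession, not the
allele). Missing calls are excluded, never imputed.

A gene qualifies as expressed in panel mode when TPM ≥ 1 in strictly
more than 60% of samples, in population mode when TPM ≥ 5 in strictly
more than 30%. The panel rule is evaluated per genotype group and the
gene passes if either group passes: a gene fully silenced by a strong
suppressor would otherwise be discarded exactly when the effect is most
interesting. Direction comes from group mean TPMs (means, not medians)
with an inclusive 1.5-fold rule: presence ≥ 1.5 × absence ⇒ promoting,
absence ≥ 1.5 × presence ⇒ suppressing. A zero denominator with a
positive numerator counts as an infinite ratio and qualifies; two zero
means give "none" — no pseudo-counts, so calls are deterministic and
label-antisymmetric. Panel eligibility requires ≥ 4 genomes in the
minority genotype group. Population mode additionally requires ≥ 60
genotyped accessions, ≥ 10 per group, and a two-sided Mann–Whitney U
test below α = 0.05 before any direction is assigned; the U test is
exact for tie-free groups of ≤ 8, otherwise the tie-corrected normal
approximation. The suppression/promotion imbalance is tested with an
exact two-sided binomial test at null probability ½.

## Regulatory signatures

The weighted methylation level of an interval is Σ methylated reads /
Σ total reads over CpG sites covered by ≥ 3 reads — a reads-weighted
mean, so pooling disjoint intervals equals the reads-weighted
combination of their levels (property-tested). CpG islands follow the
classical criteria (length ≥ 200 bp, GC ≥ 0.50, observed/expected
CpG ≥ 0.60) over 200-bp windows at step 1; overlapping qualifying
windows merge, and a merged span is kept only if it still satisfies the
criteria when recomputed whole. The island definition and the "highly
methylated" cutoff (weighted level ≥ 0.80) are package choices — the
source analysis names the concepts but defines neither — and both are
configurable.

TF-binding sites are matched as IUPAC consensus strings on both strands
(reverse strand via the reverse-complemented motif; palindromes count
once per strand; overlapping offsets all count). Consensus matching
replaces database position-weight scoring as a reproducible desk-scale
proxy. Enrichment between promoting and suppressing SV sets uses a
label-permutation test on per-kb hit densities (1,000 permutations by
default); all permutation p-values use the add-one estimator
p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + N), bounded below by 1/(N+1).
Only CpG-context methylation is modeled; CHG/CHH are out of scope.

## Association

Case–control SV-GWAS tests each SV with a two-tailed Fisher exact test
on the 2×2 accession table (case/control × presence/absence), missing
calls dropped per SV, Bonferroni correction over the SVs actually
tested. Two-tailed means summing all hypergeometric outcomes whose
point probability does not exceed the observed table's; the
implementation is verified against exhaustive enumeration for all
tables with N ≤ 40. Accession-count tables reproduce the published
example p-values to printed precision, which settles the
accession-vs-allele counting question in favor of accessions. Signal
selection reports both the Bonferroni-significant set and the smallest-p
top-5% set with ties at the cut included. Two-SV haplotype groups are
hap1 = neither, hap2 = SV2 only, hap3 = SV1 only, hap4 = both, with
two-sided Student's t comparisons of expression between non-empty
groups. LD is the squared Pearson correlation of presence/absence
dosages with SNP dosages, missing pairs dropped pairwise. Expression
association signals below p = 10⁻¹⁰ are labeled cis when the SV lies
within 20 kb of the gene span on the same chromosome, trans otherwise
(interchromosomal is always trans).

## Synthetic data

The generator defines the study conditions; it is not tuned per test.
Defaults: 27 panel genomes, 704 accessions with the study's morphotype
composition (36 wild, 310 cabbage, 153 cauliflower, 63 broccoli, 46
kohlrabi, 21 curly kale, 18 ornamental kale, 24 Chinese kale, 20
brussels sprouts, 7 Tronchuda kale, 6 collard greens), 2,000 genes, 600
SVs, effect folds log-uniform on [1.5, 10], multiplicative log-normal
TPM noise with CV 0.3 (strictly positive TPMs with realistic spread),
5% missing genotype calls. 35% of SVs are planted suppressing and 30%
promoting — the slight suppression excess mirrors the reported
imbalance.

Genes sit one per 26-kb slot on three chromosomes, so each planted SV's
nearest gene is its target by construction and no gene ever has two SVs
within the linking radius. SV effects are mechanically simple and
invertible: the carrier-group's expected TPM is multiplied (promoting)
or divided (suppressing) by the planted fold. Suppressing SV sequences
embed a ≥ 200-bp CpG-rich segment whose CpG sites draw methylation
levels around 0.90 (background sites around 0.10, read depth Poisson
with mean 30); promoting SV sequences embed instantiated copies of the
listed TF motifs; null SVs get CpG-depleted background. One effect SV
is made exclusive to ornamental kale (present in all 18 accessions of
that morphotype, absent elsewhere), emulating the strongest reported
morphotype association; a handful of other effect SVs get a planted
0.8 case/control frequency gap. Genotypes are generated directly at
accession level as presence/absence/missing (the analysis counts
accessions, so a diploid layer would add nothing), and all randomness
flows from one integer seed through per-stage child generators, making
bundles byte-identical across runs.

Population expression is generated for every accession rather than a
223-sample subset: with an 18-carrier exclusive SV, a proportional
subset would leave the carrier group below the 10-sample eligibility
minimum and silence exactly the planted signal the population pipeline
is meant to recover.

What the generator does not emulate: linkage between SVs, population
structure and kinship, read-level noise, covariate effects on
expression, CHG/CHH methylation, and realistic chromosome-scale
sequence evolution. Passing recovery tests therefore shows that the
statistical machinery is correct under the stated noise model, not that
the thresholds are optimal for real data.

## Numerical choices and degenerate inputs

Fold ratios with zero denominators are ±∞/0 as described above, never
pseudo-counted. Constant expression rows z-score to all zeros. The
rank-sum test between private-SV counts is exact for groups of ≤ 12
without ties and the normal approximation above. The saturation fit
falls back to A = constant for flat curves and rejects inputs with
fewer than 4 panel sizes or decreasing counts. Groups below two
members make the rank-sum p undefined (flagged, not fabricated). VCF
parsing derives the reference span of spanned symbolic records from
SVLEN (with POS as the first affected base) because htslib's END
handling is convention-dependent when both END and SVLEN are present;
records lacking SVLEN on a symbolic allele are a parse error naming the
record.

## Problem sizes

The test suite and the acceptance script run panel recovery at the full
default scale (27 genomes × 2,000 genes × 600 SVs), population recovery
at 704 accessions × 200 SVs, null calibration at 200 replicates with
999 permutations each, and oracle cross-checks at 1,000 random Fisher
tables, 500 random intervals and 50 random sequences. These sizes give
stable statistics (binomial standard error ≈ 1.5 percentage points on
the calibration rates) while keeping a full run under a minute.

## Known limitations

The insertion-merging proxy can split insertions that sequence-identity
clustering would join (and vice versa) on real call sets. Consensus
motif matching is blunter than position-weight scoring. The eGWAS
association table is an input (mixed-model fitting is out of scope), so
cis/trans labeling inherits whatever multiple-testing behavior produced
it. Fisher GWAS does no population-structure correction by design —
that is the documented property of the case–control strategy it
implements.
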