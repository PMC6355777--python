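# Methods

Formulas and conventions used by each stage. Coordinates are 1-based
inclusive everywhere except BED-style interval tables, which are 0-based
half-open.

## Susceptibility-SNP set (`postgwas.variants`)

Linkage disequilibrium between two loci with phased haplotype vectors
`a`, `b` (alternate allele coded 1):

```
D  = p_AB − p_A·p_B
r² = D² / (p_A(1−p_A)·p_B(1−p_B))
```

`r²` is undefined (raises `MonomorphicError`) when either locus is
monomorphic. LD expansion keeps partners with `r² ≥ 0.8` (inclusive);
summary SNPs are filtered at `P < 5×10⁻⁸` (strict). The merged set is
deduplicated on `(chrom, pos, unordered allele pair)` with source
precedence index > LD > summary; discarded sources are recorded in
`also_in`, and conflicting rsIDs at one site are logged.

## Region and consequence annotation (`postgwas.annotate`)

Each SNP receives exactly one primary region by precedence
`CDS > splicing > UTR5/UTR3 > ncRNA > promoter > intronic > intergenic`,
maximized across overlapping transcripts. Splice sites are the first two
intronic bases on either side of an exon–intron boundary. The promoter is
the strand-aware window `[TSS−1000, TSS−1]` on the coding strand.

Coding consequences are called strand-aware with the standard genetic
code: substitutions are `synonymous`/`missense` by codon translation;
indels with length difference not divisible by 3 are `frameshift`;
anything untranslatable falls back to `unknown`. The damaging consensus
over PROVEAN, SIFT, PolyPhen-2 and CADD counts only explicit `damaging`
calls: `damaging_any` means ≥ 1, `damaging_all` means all four; `missing`
never counts.

MicroRNA seed sites on the mRNA (5'→3') are the Watson–Crick complements
of the miRNA seed: `8mer` = revcomp(positions 2–8) + A, `7mer-m8` =
revcomp(2–8), `7mer-A1` = revcomp(2–7) + A. A 3'UTR SNP `destroys` a site
present with the reference allele and absent with the alternate, and
`creates` one in the reverse case; only sites overlapping the variant
count.

Enhancer membership per tissue is overlap of the SNP position with states
`{6_EnhG, 7_Enh, 12_EnhBiv}` in any cell line of the tissue. The
functional-SNP set per tissue is the union of five categories (splicing,
damaging missense, miRNA-seed 3'UTR, TF-disrupting promoter,
TF-disrupting enhancer); the tally reports the raw category sum, the
overlap removed by deduplication, and the union.

## TF-binding disruption (`postgwas.tfbs`)

PWMs are position probability matrices; scores are log-odds against a
uniform 0.25 background, maximized over both strands and every offset
covering the variant. Binding is disrupted when

```
|score(alt) − score(ref)| ≥ log 2   and   max(score) ≥ 0.8 · max_score(PWM)
```

Per-TF enrichment of disruption in a functional SNP set versus background
uses the one-sided Fisher exact test with BH adjustment across TFs.

## Variant-set enrichment (`postgwas.enrich_hist`)

The associated variant set (AVS) is the disjoint union of LD blocks
(blocks sharing members are merged by union-find). Null sets draw, for
each block, a background SNP whose LD-partner tally falls in the same bin
(0, 1–5, 6–20, > 20), replacing the block with that SNP's LD set. The
statistic is the number of AVS blocks with ≥ 1 member inside ≥ 1 track
interval; the empirical p-value uses add-one smoothing,

```
p = (1 + #{null ≥ observed}) / (n_perm + 1),
```

so it is never zero, with BH adjustment across the
tissue × cell-line × mark grid. Because the statistic is a small integer,
ties make this p-value conservative; the test suite checks validity
(type-I error ≤ nominal) rather than exact uniformity for this family.

## cis-QTL, SMR and HEIDI (`postgwas.qtl_smr`)

Enhancer SNPs pair with every feature whose TSS lies within ±1 Mb
(inclusive); other functional SNPs pair only with their host gene.
Associations are per-pair linear regressions of phenotype on additive
dosage with exact t p-values and BH adjustment per (analysis, tissue).

SMR uses the top cis SNP:

```
b_xy  = b_GWAS / b_eQTL
T_SMR = z_G² z_E² / (z_G² + z_E²)  ~  χ²(1)
```

HEIDI tests heterogeneity of `b_xy` across instruments with eQTL
`p < 1.6×10⁻³`, pruned at `r² > 0.9` with the top SNP, at most 20 used;
with fewer than 3 instruments the p-value is reported absent. The
statistic is `Σ d_i²/Var(d_i)` with `d_i = b_xy(i) − b_xy(top)`; its null
distribution (a sum of correlated 1-df chi-squares under the full
delta-method covariance of the `d_i`) is approximated by a
moment-matched scaled chi-square (Satterthwaite): with
`v = 2·Σ corr(d)²`, the statistic divided by `v/2k` is referred to
`χ²(2k²/v)`, which reduces to `χ²(k)` for independent instruments.
Calibration was verified empirically under a single-shared-causal-variant
null with strong instruments (rejection 0.054 at the 0.05 level over
2000 simulations); with weak instruments near the eligibility threshold
the delta-method approximation inflates, which is why the instrument
p-value threshold matters.

A gene passes SMR when `q_SMR < 0.05`, the top SNP's eQTL `p < 0.05`, and
HEIDI `p > 0.05` (absent HEIDI passes by default; configurable). Per
tissue class, eQTL target genes are the intersection of
eQTL-significant and SMR-passing genes, unioned across classes.

## Evidence integration (`postgwas.integrate`)

Differential expression per study is a two-sample t-test with effect
direction; studies combine by sample-size-weighted Stouffer:

```
z_i = Φ⁻¹(1 − p_i/2) · sign(direction_i)
Z   = Σ √N_i z_i / √(Σ N_i)
```

with two-sided p and BH across genes. Target genes are the union of the
four sources (enriched TF, meQTL, eQTL∩SMR, pQTL); only protein-coding
targets are tallied against three validations — DE `q < 0.05`, mouse
nervous-system phenotype term, direct disease-pathway/known-gene
membership. All three hits prioritize a gene; ≥ 2 hits feed
hypergeometric pathway over-representation (BH across pathways). Genes
without direct disease membership are bridged through one-hop PPI
neighbors (pathway neighbor beats known-gene neighbor), and drugs join on
direct targets or bridged genes. Report percentages use half-up rounding
to two decimals.

## Synthetic-data engine (`postgwas.synthio`)

One chromosome of 50 kb blocks, one strand-alternating gene per block
(two exons, 300 nt CDS `ATG…TAA` with no internal stop, 60/120 nt UTRs),
eight role-assigned SNPs per block. Haplotypes use a copying model: SNP
`j` copies SNP `j−1` with probability `√block_r²`, giving adjacent
correlation `block_r²` in expectation; blocks are independent. GWAS
z-scores are drawn per block from `MVN(λ·R[:,causal], R)` with the
realized haplotype correlation `R` and `λ = 9`, `se = 1/√(2N·maf(1−maf))`
at `N = 50,000`, so LD partners of the causal enhancer SNP inherit
proportional signal. Planted disease genes carry cis-QTL effects
(`β·dosage + N(0, σ²)`), direction-consistent case/control shifts in
three expression studies, motif-breaking promoter/enhancer alleles,
miRNA-seed-breaking 3'UTR alleles and resource-table entries; "partial"
genes carry only DE and mouse hits (two-hit controls), and null genes
carry none. Every generator is a pure function of the configuration via
seeded substreams, so identical configs give bit-identical data.
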