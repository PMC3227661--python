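# Methods

This note documents the models, conventions and numerical choices behind
`tagomics`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Virtual digestion

Coordinates are 0-based, half-open everywhere. Cut offsets follow the
enzymes' published cut sites: MluI cuts A^CGCGT (offset +1 from the motif
start), NlaIII cuts CATG^ (offset +4). Both recognition sequences are their
own reverse complements, so a forward-strand scan (overlapping occurrences
included) is the complete double-stranded site set.

The MMSDK digestion is simulated under the hypothesis that every cytosine is
unmethylated — i.e. every MluI site cuts. Each MluI cut yields two virtual
fragments: upstream to the nearest NlaIII cut at or left of it, and
downstream to the nearest NlaIII cut right of it, each bounded by the
nearest obstacle (chromosome end or adjacent MluI cut). A fragment whose
NlaIII-side boundary is an obstacle carries `has_internal_nla=False` and
yields no tag. Otherwise the tag is the 18 bases of the fragment immediately
interior to the NlaIII boundary, the CATG motif itself excluded, read from
the boundary into the fragment — forward strand for upstream fragments,
reverse complement for downstream ones — with the 17-mer form being the
18-mer's prefix (the MmeI cut is heterogeneous, releasing 17 or 18 nt).
Fragments with fewer than 18 interior bases past the CATG yield no tag.
Tags exclude the CATG prefix (the classic SAGE convention; the observed
17–18 nt tag lengths are consistent with either reading).

The DGE reference extracts the 17-mer immediately 3′ of every CATG on both
strands (the reverse-strand tag is the reverse complement of the 17 bases 5′
of the motif). Entries overlapping exactly one gene adopt that gene as
their locus, so per-locus counting aggregates expression tags per gene;
entries overlapping zero or several genes keep a coordinate-based locus id.

## CpG islands

Islands are called by the three classic criteria: GC fraction ≥ 0.5,
observed/expected CpG > 0.6 with obs/exp = (#CpG × L)/(#C × #G), and length
strictly greater than 200 bp. The caller seeds 200-bp windows stepped by
1 bp, merges overlapping/touching passing windows, then re-tests each merged
region as a whole, trimming one base at a time (from whichever end is not a
C/G, else the right end) until the region passes or falls to the length
floor. Every emitted region therefore passes a direct re-check of all three
criteria, and results are independent of chromosome ordering. A
pre-computed island track (BED) can be supplied to bypass the caller.

Promoters default to ±1,000 bp around the TSS (configurable); the window is
a pragmatic choice in the common 500–2,000 bp range used for promoter
classification. Region classes are assigned with precedence
promoter > exon > intron > intergenic, and a promoter locus overlapping any
island is a CGI promoter.

## Tag processing

Adapter clipping is an overlap alignment (match +1, mismatch −1, gap −2):
the adapter aligns from its first base over every read suffix, trailing
adapter bases are free, and the read is truncated at the best-scoring start
when the score reaches 7. Score ties between starts go to the rightmost
start — clipping less — which keeps an exact adapter occurrence optimal and
handles substitutions at the adapter's first base correctly. Clipping is
effectively idempotent for genomic tags that do not themselves resemble the
adapter; tags containing adapter-like stretches can be re-clipped on a
second pass, an inherent property of threshold-based clipping.

Mapping replaces a general-purpose aligner: tags are short and the
reference is a small tag library, so an exact + one-mismatch wildcard hash
index gives provably complete results (verified against an all-pairs
Hamming oracle). A read is assigned only when it has exactly one library
entry at its minimal mismatch distance (≤ 1); reads with two or more best
hits are discarded as ambiguous, deterministically and without rescue. This
"unique best hit" contract replaces the MAQ mapping-quality ≥ 20 filter,
which enforces the same uniqueness in practice. Matching is
orientation-aware (both orientations of every entry are indexed) and
length-exact: a read is matched at the longest indexed tag length it covers,
so 17-nt and full-length reads resolve to the same entry without a
cross-length cascade that would weaken the mismatch bound.

Replicate libraries are pooled per condition by the arithmetic mean of
per-locus counts, rounded half-up, with library sizes pooled the same way.
Rounding half-up (0.5 → 1) keeps pooled counts integral for the exact test;
whether the original analysis rounded before or after averaging is not
recoverable, so mean-then-round is the fixed convention here.

## Differential statistics

Counts are normalized to tags per million (TPM). The differential test is
the exact conditional Poisson comparison: conditional on `x` tags in a
library of `n1`, the null distribution of the second count is negative
binomial, `p(k|x) = r^k (x+k)!/(x! k! (1+r)^(x+k+1))` with `r = n2/n1`.
Numerics: log-space terms via `gammaln`, tail sums via `logsumexp`; the
complement tail is clamped to `[pmf(y), 1]` to absorb float cancellation.
Agreement with direct summation is ≤ ~1e-13 over the tested grid
(documented bound 1e-10).

Two-sided convention: twice the smaller tail, capped at 1. Because the
conditional construction is not symmetric in the two libraries for small
counts, it is evaluated in a canonical orientation — conditioning on the
smaller count, ties broken by library size — making the test exchangeable;
an alternative minimum-likelihood ("mass") convention is available behind a
flag. The pseudocount (0.5 TPM, configurable) enters only the log2 ratio,
never the p-value, which uses raw integer counts.

Significance: BH-adjusted p ≤ 0.05 and |log2 ratio| ≥ 1, both inclusive.
BH adjustment is delegated to statsmodels (`fdr_bh`) behind `bh_adjust` and
cross-checked against the textbook step-up in tests. FDR is computed within
each omics layer separately. The region-wise distribution comparison uses
the two-sided Wilcoxon rank-sum test (exact enumeration when both groups
have ≤ 12 observations and no ties, else the tie-corrected normal
approximation); all-tied input returns p = 1 with a warning.

On the null calibration: with Poisson rate 100 and equal libraries, the
fraction of p < 0.05 is ≈ 0.045 — slightly conservative, as expected from
the discreteness of the doubled-tail construction.

## Direction semantics and integration

MMSDK tags mark unmethylated sites, so methylation direction inverts the
tag ratio: tag log2 ≤ −1 ⇒ hypermethylated, ≥ +1 ⇒ hypomethylated. The
gene-level join takes, per gene, the most significant methylation locus
(smallest p, ties by larger |log2|, then lexicographic locus id, which
embeds the coordinate); genes present in both layers are retained and the
joint category (hyper-repressed, hyper-induced, hypo-repressed,
hypo-induced) requires both layers to pass the thresholds. Loci mapping to
no gene are dropped and tallied.

Gene-set enrichment is a right-tailed hypergeometric test (scipy
`hypergeom.sf`) over a user-supplied GMT collection, terms intersected with
the universe first, BH across all tested terms, zero-overlap terms reported
at p = 1. The universe defaults to the genes with data in the relevant
layer(s); with no ontology structure, parent-term propagation is out of
scope.

## miRNA target consensus

Consensus operates at (miRNA, gene) pair granularity — the stricter,
reproducible reading: a pair must appear in ≥ 2 of the 3 prediction sources
("at least two tools agree", read as any 2-of-3 rather than one fixed pair
of tools) and in ≥ 1 experimentally supported database (their union).
miRNA ids are compared case-insensitively with the species prefix stripped;
-3p/-5p arm suffixes are never guessed. Pairing with differential results
keeps pairs whose miRNA is differentially expressed; an optional
anticorrelation filter additionally requires opposite directions with a
significant target.

## Synthetic data generator

The generator emulates the study design: 9 matched tumor/normal pairs and
Poisson tag counts per locus — the distributional assumption of the test —
at a desk-scale size of 5,000 MluI loci with an expected 100 tags per locus
(the real design averages ~4.5M tags over ~21k loci, ≈ 214 per locus; 100
per locus over 5,000 loci preserves the per-locus counting regime at
tractable size). 100 loci are spiked in the tumor condition at
|log2 fold change| = 2 with random sign.

Genomes are i.i.d. background at GC 0.41 with two structural edits: all
accidental ACGCGT occurrences are re-drawn (including at assembly
junctions), so the planted site list is exactly the genome's MluI site set;
and 75 % of background CpG dinucleotides are rewritten, emulating the
genome-wide CpG depletion (obs/exp ≈ 0.25) that makes CpG islands
detectable at all — without it, i.i.d. sequence has obs/exp ≈ 1 and the
island caller fires everywhere. Each planted MluI site sits in a block
flanked by planted CATGs at 30–500 bp on both sides (block-internal
background scrubbed of CATG), guaranteeing both tags are extractable.
Planted islands are drawn at GC ≈ 0.7 with margins over the thresholds
(GC ≥ 0.55, obs/exp > 0.7 at generation) so boundary trimming cannot push
them under the calling criteria; accidental CATG elsewhere is allowed, as in
real genomes. About half of the islands host a gene TSS so CGI-promoter
loci exist.

Counts are independent Poisson per sample with a common per-locus rate
(scaled to a target library size when given); a negative-binomial
(Gamma–Poisson) option exists for robustness studies and is off by default.
Reads are single-end tag+adapter with i.i.d. substitution errors; an
orientation flag reverse-complements a fraction of reads for stress tests.
One integer seed determines everything through per-stage substreams.

What passing synthetic tests do not show about real data: no PCR
duplicates, no indels, no quality-score realism, no methylation-state
mixtures (digestion is all-or-none per site), no overdispersion between
patients by default, and mapping ambiguity is rarer than in a repeat-rich
genome. The digestion bookkeeping at genome scale is covered separately by
the hg18 anchor test, which requires a user-supplied reference
(`data/hg18/hg18.fa` + `data/hg18/cpgIslandExt.bed`, primary chromosomes
chr1–chr22, chrX, chrY, chrM) and fails loudly when it is absent.

## Problem sizes

Defaults and test sizes were chosen once as the package's own desk-scale
conditions: the acceptance script and spike-recovery tests run the full
default design (4 Mb genome, 5,000 loci, 18 libraries); oracle-equivalence
suites use 100 random 50-kb genomes, a 31×31×3 grid for the exact test,
10,000 null loci, and 1,000 random instances for the BH / hypergeometric /
consensus oracles; the read round trip uses 300 loci × 4 libraries at rate
30 so the exact multiset comparison stays fast.
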