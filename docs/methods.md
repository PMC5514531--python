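# Methods

## Scope and data flow

strainsieve implements the downstream, count-level strain analyses of a
shotgun-metagenome workflow. Alignment, variant calling and taxonomic
classification are upstream tools whose outputs are this package's inputs: a
freebayes-style VCF per sample (RO/AO/DP read counts), per-sample mapped
regions, a reference sequence, gene FASTA + category TSV, reads, and a
taxon×sample count table. Stages communicate via files and run in dependency
order (simulate → variants → alleles → consensus; gene screen and community
profiling are independent branches), so a failure in one branch never aborts
the others.

## Variant handling

VCF records are parsed with pysam; records missing any of DP/RO/AO are
skipped with a logged warning and counted rather than aborting the run,
because field placement varies across caller dialects. Complex variants are
decomposed to allelic primitives (1-bp mismatches and 1-bp gaps) by common
prefix/suffix trimming followed by positionwise comparison — not a full
alignment. This is deliberate: gap and complex primitives are discarded by
the substitution-only site filter immediately afterwards, so only SNP-exact
behaviour matters, and for equal-length alleles the primitive count equals
the Hamming distance between REF and ALT by construction. Coordinates are
1-based inclusive end to end; depth is taken from DP, falling back to the
allele-count sum only when DP is absent or non-positive.

## Allele model

Presence requires both an absolute (≥ 3 reads) and a relative (≥ 10 % of
depth) level of support; both are evaluated independently for the reference
and every alternate allele, so multi-allelic presence is representable even
though real data rarely show more than two present alleles. Fractions use
total site depth as the denominator, not the sum of present-allele
observations, because the thresholds are phrased against read depth. The
fraction comparison carries a 1e-9 epsilon so integer boundary cases
(3 of 30 reads at the 10 % cutoff) are not lost to binary rounding.

Fraction histograms use left-open/right-closed bins (x, x+0.1]: a fully
fixed allele (fraction 1.0) falls in the top bin, a fraction of exactly 0.9
in (0.8, 0.9]. An allele at exactly 10 % is present (the rule is ≥) and is
the only possible occupant of (0, 0.1]. The histogram is stratified by the
number of present alleles (reference included) at the contributing position.

A position is mono-allelic when its only present allele is non-reference,
i.e. all observed supporting reads back a non-reference call — the stricter
of the two readings of "one allele present", chosen so that a sample whose
reference allele retains trace support below the presence rule still counts
as mono-allelic.

The sharing spectrum is restricted to positions mapped (depth ≥ 10) in every
sample — otherwise an allele could look "unshared" merely because another
sample had no coverage there. The per-allele fraction matrix is sorted by
samples-present descending and then by mean within-sample fraction
descending; only the first key is externally prescribed, the second is a
deterministic tie-break.

## Consensus and clustering

Nearly fixed means the single most-supported allele holds ≥ 0.90 of depth;
ties between equally supported alleles resolve toward the reference and then
lexicographically. Mapped positions absent from the VCF are treated as
reference-fixed, since variant callers emit only non-reference evidence.
Masked positions record their reason (unmapped vs polymorphic) and are
rendered as N in FASTA output.

Hamming distances exclude masked positions from numerator and denominator.
For the clustering matrix the site set is the *global* intersection of
unmasked positions across all samples, so all pairs are compared on one site
set and the triangle inequality holds by construction. Distances are
reported raw (mismatch counts) and used raw for clustering; the
comparable-site count is emitted alongside for normalisation by the user.
The linkage method is average (UPGMA) by default and configurable — nothing
in the analysis pins a particular linkage, and UPGMA is the conventional
choice for small distance matrices of consensus sequences. Sample order is
lexicographically normalised before linkage so equal-distance merges are
deterministic. Dendrograms are emitted as Newick via scikit-bio.

## Gene screen

Query k-mers are *distinct* canonical 20-mers; a multiset would let repeats
in low-complexity reads inflate matched fractions. Canonicalisation (min of
k-mer and reverse complement) makes assignment strand-invariant, which a
one-strand index would silently break for half the reads. The matched
fraction's denominator is the query's k-mer count — the read is the unit
being classified, and partial gene recovery is explicitly allowed (no
minimum covered-length filter). Ties in the arg-max break to the
lexicographically smaller gene id. Mates of a pair, when available, are
scored jointly on the union of their k-mer sets.

A consequence of the ≥ 90 %-of-20-mers rule worth stating: a read at 95 %
sequence identity to its source (10 substitutions in 200 bp) retains only
~36 % of its 20-mers on average, so such reads score their true gene as the
best candidate but fall below the assignment threshold. The screen is a
strict nearly-identical-match detector — at identity 1.0 recall is 100 %,
and at identity ≤ 0.80 the per-k-mer survival probability (0.8^20 ≈ 1.2 %)
makes assignment effectively impossible, which the tests assert empirically.

Category binning counts an assigned read once per category of its gene
(documented double-binning for multi-category genes); genes absent from the
map count under "uncategorized". The presence/absence comparison between two
samples builds a 2×2 table over the union of categories and uses the exact
hypergeometric two-sided p-value (scipy's Fisher's exact test).

## Community profile

Computed on absolute read counts without rarefying. Chao1 uses the
bias-corrected estimator S_obs + F1(F1−1)/(2(F2+1)) — the common ecology
default, finite even when no doubletons exist; Shannon uses the natural log;
Gini-Simpson is 1 − Σp². These are delegated to scikit-bio's implementations
(verified against hand-evaluated closed forms in the tests). The "top N"
species set is selected globally by summed relative abundance so every
sample shares one species axis; coverage is each sample's read share in that
set. Bray-Curtis comes from scipy on raw counts; PCoA is implemented
directly as classical scaling (double-center −½D², eigendecompose, keep
nonnegative-eigenvalue axes, report negative eigenvalues) with an asymmetry
tolerance of 1e-9, and is cross-checked in the tests against scikit-bio's
independent PCoA. Differential abundance and PERMANOVA are deliberately not
reimplemented; the count matrix is written in a form those tools consume
directly.

## Synthetic data generator

The generator emulates exactly the statistical structure the analyses
consume, at the study's conditions: four samples; 213 planted non-reference
alleles with sharing design {4: 6, 3: 7, 2: 24, 1: 176}; true fractions
drawn from a grid spanning 0.2–1.0 (so presence is unambiguous at the
simulated depths and both polymorphic and fixed sites occur); uniform
per-site depth with binomially sampled alternate counts; per-sample
contiguous unmapped blocks covering 5 % of the genome by default, planted
positions restricted to the jointly mapped core so the sharing design is
recoverable. Default depth is 100×; the parameter-recovery analyses use
1000× so binomial noise (σ ≈ 0.016 at p = 0.3) sits well inside the ±0.05
recovery band.

Gene reads are substrings with exactly round((1−identity)·length)
substitutions at distinct uniform positions — per-read identity is exact by
construction — with random strand. Abundance profiles are
Dirichlet-multinomial with symmetric concentration (smaller ⇒ more
dominance-skewed); each sample gets a paired "PMA" column formed by taxon
dropout plus multinomial subsampling, a stand-in for viability selection,
not a chemistry model.

What the generator does *not* emulate: read-level errors and quality scores,
non-uniform coverage, amplification bias, linkage between nearby variants,
and real database structure (gene families, shared domains). Passing tests
therefore demonstrate correctness of the counting, thresholding, spectrum,
consensus, screening and ordination logic under the stated model — not
robustness to alignment artefacts or caller idiosyncrasies in real data.

## Problem sizes and determinism

The default test-suite and acceptance problem sizes (50 kb genome, 213
sites, depth ≤ 1000, 500 reads, 10 clustering replicates of 4 kb) keep every
analysis exact while running the whole suite in seconds. All generators are
pure functions of their configuration and seed; the pipeline derives stage
seeds by fixed offsets from the run seed, and identical configurations
produce byte-identical outputs (asserted via manifest checksums).

## Thresholds

| parameter | default | unit | role |
|---|---|---|---|
| min_depth | 10 | reads | site analysable at all |
| min_allele_reads | 3 | reads | absolute presence support |
| min_allele_frac | 0.10 | fraction of depth | relative presence support |
| fixation_frac | 0.90 | fraction of depth | nearly-fixed / consensus rule |
| kmer_k | 20 | bases | gene-screen k-mer size |
| min_kmer_frac | 0.90 | fraction of query k-mers | assignment cutoff |

All are configurable per run; the defaults are the published workflow's
values and the tests exercise each rule at its exact boundary.
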