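# Methods

`devtome` re-creates, as a tested library, the analysis chain used to
characterize a de novo developmental transcriptome of a non-model insect
across six stage libraries (egg, larvae, pupae, adult male, adult female,
mated adult female) and to compare it against a well-annotated reference
species. Assembly and quantification engines (Trinity, bowtie, RSEM, BLAST,
HMMER) are out of scope: transcript sets, expected-count tables and tabular
alignment hits are *inputs*, and the synthetic-data module manufactures them
with known ground truth.

## Read preprocessing

A mate passes quality control iff the fraction of bases with Phred quality
≥ `q_min` (default 20) is at least `min_fraction` (default 0.80) — i.e. a
read fails when *more than* 20% of its bases fall below Q20. The original
study used a single-end tool; here a pair is discarded when either mate
fails, keeping R1/R2 synchronized for downstream paired processing. Only
Phred+33 is supported.

Digital normalization makes one pass in input order with an exact (hash
table) canonical k-mer counter: for each pair the median count of its k-mers
(k = 25) is evaluated against the table state *before* the pair's k-mers are
added; pairs at median ≥ `max_cov` (30) are dropped, all others retained and
counted. The procedure is deliberately order-dependent (as in classic
digital normalization) and deterministic for a fixed input order. Because
overlapping mates may contribute the same k-mer more than once per pair, the
post-normalization median can exceed `max_cov` by a small constant.

## Abundance filtering

Both filters act on expected counts pooled across all six libraries,
mirroring a single pooled quantification run:

* isoform share: a transcript is kept iff it holds ≥ `min_percent` (1%) of
  its gene component's pooled expression; genes with zero pooled expression
  retain nothing;
* TPM: kept iff pooled TPM ≥ 0.5 with TPM_i = 1e6·(c_i/l_i)/Σ_j(c_j/l_j).
  Effective length defaults to transcript length; externally supplied
  effective lengths are accepted.

The share filter operates on expected counts (the estimator's primary
output) rather than TPM; both being per-transcript predicates on pooled
values, the two filters commute. N50 uses the sorted-cumulative-half-sum
definition (smallest length at which the running sum reaches half the total).

## ORF prediction

Candidates are enumerated in all six frames; an ORF is complete
(start→stop), 5'-truncated (edge→stop), 3'-truncated (start→edge), or open
edge-to-edge. The single longest candidate of ≥ 100 codons per transcript is
evaluated (ties broken deterministically: plus strand, lower frame, complete
before partial, leftmost). `N` bases break ORFs like stops and score zero.

The coding model is a fixed-order Markov chain (default order 5, i.e.
hexamer contexts) whose transition tables are stratified by codon phase, so
the same nucleotides read in a shifted or reverse frame receive a different
likelihood — this is what makes "outscore the other reading frames"
meaningful. It is trained on the 500 longest candidates with add-one
pseudocounts; the null model is the order-0 composition of the same
sequences after independent seeded shuffling (composition preserved,
structure destroyed). A candidate is retained iff its annotated frame's
log-likelihood ratio is strictly the maximum of the six readings *and*
positive; the positivity requirement suppresses noise retention on short
sequences, which frame-outscoring alone would allow.

Genes roll up as: complete if any isoform has a complete retained call,
else partial if any has a truncated call, else non-coding.

## Expression normalization, binning and stage patterns

TMM factors are computed per library against a reference (the library whose
upper quartile of scaled counts is closest to the mean): genes with zero
counts in either library are excluded; log-ratios M and log-abundances A are
rank-trimmed (30% and 5% per tail); the factor is 2 to the precision-weighted
mean of the surviving M-values, and factors are mean-centered in log space.
One numerical choice departs from the textbook weights: precision weights
are computed on count *proportions*, (1−p)/p + (1−p_r)/p_r, which is
proportional to the delta-method weights at matched depths and makes the
factors a function of relative composition only — hence FPKM and every
downstream category code are exactly invariant to rescaling any library's
counts. Agreement with edgeR's `calcNormFactors` at equal column sums is
< 1e-8.

FPKM_gs = 1e9·c_gs/(l_g·N_s·f_s) with N_s the column sum and f_s the TMM
factor. Gene-level values use summed isoform counts and an
expression-weighted effective length (weights from depth-normalized count
proportions; a sum-of-lengths alternative is exposed).

FPKM is integerized round-half-up (floor available) and binned into eight
ordinal categories with default inclusive upper edges 0, 3, 10, 25, 50, 100,
1000 ("No Expression" … "Extremely High"). The edges are configuration with
documented defaults, matching the convention of public developmental RNA-seq
category sets.

Stage patterns are evaluated in order: constitutive high (code ≥ 5
everywhere); 1-stage specific (≥ 4 in exactly one library, ≤ 3 elsewhere);
k-stage specific for k = 2..5 (≥ 5 in exactly k, ≤ 2 elsewhere);
constitutive low (≤ 3 everywhere); other. The single-stage rule deliberately
uses different thresholds from the multi-stage rule — both are implemented
verbatim rather than harmonized. Report percentages are truncated (not
rounded) to two decimals, the convention under which published per-class
percentages reproduce exactly from their counts; the TF class table rounds
to one decimal for the same reason.

## Clustering

Dissimilarity is Euclidean distance over the six raw TMM-FPKM stage values
(per the source procedure; log transformation is applied only to displayed
profiles), followed by complete-linkage agglomeration. Subclusters are
connected components below `fraction × max merge height`; "sharing 45% of
the tree height" is read as fraction 0.45 from the bottom, with the
complementary reading available. `fraction = 1` (the closed limit) yields a
single cluster; any fraction < 1 necessarily splits the top merge. Display
profiles are log2(FPKM+1), median-centered per gene.

## Orthology and expression divergence

Gene-level best hits take the maximum bitscore over a gene's transcript-level
hits; uniqueness fails when two or more subject genes tie the maximum
exactly. A pair is an ortholog iff each gene is among the other's top
subjects and both tops are unique; mutual pairs failing uniqueness are
reported as `nonunique_excluded` (paralog-ambiguous). Reciprocity considers
all tied winners, so tie exclusion does not depend on lexical order.

Per matched stage (egg↔embryo, larvae, pupae, male↔adult male,
female↔adult female; the mated-female library has no counterpart), ordinary
least squares of log10 expression in the focal species on the reference is
fit over pairs with positive expression in both (zeros are excluded from fit
and flagging and reported as `unfit`). Individual pairs are flagged outside
a 95% interval. The default band is the leave-one-out prediction interval —
equivalent to thresholding externally studentized residuals at the two-sided
t critical value — because the question asked of each point is whether *it*
is consistent with the regression of the others; this rule has exactly
nominal 5% false-positive rate under the model, whereas the in-sample
full-fit prediction band is slightly conservative (≈4.9%) and a confidence
band answers a different question. Both alternatives are exposed
(`band="prediction_insample" | "confidence"`). Pearson rho and its two-sided
p-value accompany each fit. The screen summary counts, per pair, stages
flagged outside: always-within, outside-in-k, always-outside; the
always-within percentage is rounded to the nearest integer.

Detection power: a pair displaced by exactly 3 residual SDs is flagged in
one stage with probability ≈ Φ(3−1.96) ≈ 0.85; across five independently
noisy stages the probability of being flagged somewhere is ≈ 1−0.15⁵. Recall
of planted divergent pairs is therefore assessed at pair level (outside in
at least one stage), which is the decision the screen actually takes.

## Functional mining

TF calling is GO-gated (GO:0003700, GO:0006355, GO:0003705); Pfam domains
then assign one of eleven named classes by a fixed priority order shipped as
an editable table, defaulting to "other". Detoxification tables are built at
gene level: P450 families parsed from gene names with Roman-numeral labels
normalized to Arabic (CYPVI → CYP6); GSTs split into both/N-only/C-only by
domain presence across isoforms; UGTs counted by domain. The
sex-determination screen reports, for every panel gene, transcripts with any
hit at e-value ≤ 1e-10, including zero-match genes.

## Synthetic data: what it emulates and what it does not

The generator plants, per gene component: coding status (ORF with codons
drawn from a biased usage table shipped as package data, uniform UTRs, both
strands), an expression pattern with stage means placed inside the intended
ordinal bins, isoform structure (per-gene Dirichlet share split, optional
sub-1% isoforms, isoforms sharing ≥ 60% of sequence), an ortholog map with
planted bitscore ties and log-expression correlated at `rho_target`, planted
divergent pairs displaced by a stated number of residual SDs, and annotation
labels for the mining rules. Everything is deterministic given the config
seed; independent substreams per generator keep outputs stable when one
generator's internals change.

Two constructions deserve note. First, absolute FPKM bins impose the
closed-system identity Σ_g FPKM_g·l_g = 1e9 per library, so arbitrary
mid-bin targets cannot all be realized by themselves; a small configurable
set of extremely highly expressed "background" genes (housekeeping-like, as
in real libraries) absorbs the remaining mass so that planted genes land on
the intended absolute scale. Second, 5' UTRs terminate in a
reverse-complement-symmetric guard (`TTAATTAATTAA`, stops in all six frames)
immediately before the start codon, making every planted ORF complete and
uniquely the longest for an exhaustive scanner.

Counts are negative-binomial around the design means (dispersion 0 yields
the means exactly, mimicking fractional expected counts). The default
dispersion 0.1 exists for robustness of downstream code; the study itself
has one library per stage with no biological replicates, so recovery-rate
experiments use a near-technical dispersion of 0.02 — at dispersion 0.1 the
coefficient of variation (≈0.32) makes mid-bin single-stage plants straddle
the moderate/low boundary ≈8% of the time, an arithmetic ceiling no
classifier can beat. Reads are uniform-substitution, fixed-length pairs;
there is no splice-graph, positional-bias or quality-by-cycle model, so
passing tests demonstrate correctness of the analysis rules, not robustness
to real library artifacts.

Default study conditions: six stage libraries at a nominal 15M mapped
fragments; mean ~1.9 isoforms per gene; half of genes coding in
predictor benchmarks; planted pattern mix matching the published class
proportions (12.5% constitutive high, 76.5% constitutive low, the remainder
stage-specific); 2×101 bp pairs; ortholog fraction 0.55 with 10% tie and 2%
divergence rates, rho target 0.9. Benchmark problem sizes (500 genes for the
ORF predictor, 1,000 for pattern recovery, 500 pairs × 1,000 replicates for
band calibration) are the package's chosen desk-scale conditions.

## Known limitations

* The Markov model is trained on candidate longest ORFs without
  homology-based rescue; short or atypical coding regions below 100 codons
  are invisible by construction.
* TMM reference selection follows the upper-quartile convention; pathological
  matrices (most genes zero) may need an explicit `ref`.
* The divergence screen assumes homoscedastic log-normal residuals; heavy
  tails inflate the outside rate.
* The k-mer normalizer holds all counts in memory — appropriate for
  desk-scale inputs, not for full lanes.
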