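# Methods

This note documents the models implemented in `uorfevolve`, the
numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the package's known limitations.

## uAUG annotation

Transcripts are loaded either from GFF3/GTF + genome FASTA (UTRs
reconstructed from exon/CDS features, minus-strand sequences
reverse-complemented into mRNA orientation; soft-masked lowercase
stretches recorded as repeat intervals) or from a transcript TSV with
explicit UTR/CDS sequences. Coordinates are 0-based half-open
throughout; GFF's 1-based inclusive intervals are converted on read.

Every ATG occurrence in a 5′UTR yields one record, overlapping
occurrences included. Scanning codons in the uAUG frame through the
whole mRNA, the first UAA/UAG/UGA determines the class: *nORF* when
the stop ends at or before the CDS start, *NTE* when the uAUG is in
frame with the CDS (for a CDS without internal in-frame stops this
stop is necessarily the CDS stop), *oORF* otherwise, and *no_stop*
when no in-frame stop exists before the transcript end. no_stop
records are kept for bookkeeping but excluded from all downstream
uORF statistics, which require a stop-terminated ORF. An oORF whose
out-of-frame scan reads through the CDS into the 3′UTR is still an
oORF (rare; the stop merely falls late).

Analysis-level filters follow common practice for comparative UTR
work: one transcript per gene (longest mRNA, ties broken
lexicographically by transcript id for determinism), 5′UTRs longer
than mean + 3 sample standard deviations removed as likely annotation
artifacts, uAUGs whose start codon overlaps another transcript's CDS
on the same strand removed (an antisense CDS does not contain the
uAUG as codons, so the filter is same-strand only), and species kept
only when more than 25% of genes carry 5′UTR annotation. Repeat
masking (from FASTA soft-masking) flags uAUG records for exclusion in
the divergence-based analyses, where repeat-driven homoplasy would
bias results.

## The O/E statistic

Depletion of a triplet is measured as n_obs / n_exp where n_exp is
the median triplet count over sequences shuffled while preserving
their exact overlapping-dinucleotide multiset, with a 95% CI of
[n_obs/q_97.5, n_obs/q_2.5]. Dinucleotide preservation matters
because base-stacking effects and dinucleotide-biased mutation (CpG
to TpG in particular) shape UTR composition independently of
selection on uORFs.

The shuffler implements the Altschul–Erickson construction: a uniform
random arborescence toward the terminal character (sampled by
rejection over last-exit-edge assignments), a random permutation of
each character's remaining out-edges, and an Euler-path walk. The
draw is uniform over all orderings consistent with the dinucleotide
multiset; endpoints are fixed. Occurrence counting is overlapping.
Sequences containing N are excluded from both observed and expected
counts (the shuffle is undefined over ambiguity codes). Each
permutation replicate shuffles every sequence with an RNG stream
derived from (seed, replicate), so results are independent of
evaluation order and reproducible under any scheduling.

Partitioned variants score subsets separately: 5′ versus 3′UTRs (and
the 64-triplet spectrum with the 5′/3′ relative O/E), subregions
within/beyond L nt of the CDS start (default L = 100), chromosome
classes, and equal-count expression bins (default 20) with a Spearman
correlation of bin rank against ratio. Class-specific O/E re-runs the
uAUG classifier on each shuffled 5′UTR against the real CDS, the
natural null for class counts.

## Fixation model

For a new mutation with selection coefficient s in a diploid
population of size Nₑ, the fixation probability relative to neutral is

    f(s) = 2Nₑ ∫₀^{1/(2Nₑ)} G(x) dx / ∫₀¹ G(x) dx,
    G(x) = exp[−4Nₑshx − 2Nₑs(1−2h)x²],

evaluated by adaptive quadrature at relative tolerance 1e-9. The
exponent is shifted by its maximum over [0,1] before exponentiation
(the shift cancels in the ratio), so strongly selected cases neither
overflow nor underflow prematurely; |4Nₑs| < 1e-8 returns the neutral
limit 1 by continuity. At h = ½ the closed form
2Nₑ(1−e^(−s))/(1−e^(−2Nₑs)) serves as an oracle in the tests, and a
vectorized forward Wright–Fisher simulator (genotype fitnesses
1 : 1+hs : 1+s, binomial resampling of 2N gametes) provides an
independent stochastic cross-check.

New uORFs are modeled as a mixture: fractions p₁ = 0.20 neutral,
p₂ = 0.75 deleterious, p₃ = 0.05 beneficial with equal |s|, giving an
overall relative fixation probability p₁ + p₂f(−s) + p₃f(s) and an
adaptive fraction p₃f(s) / overall. For the Nₑ-grid analysis
(Nₑ ∈ [10², 10⁶]) the default per-copy coefficient is s = 1e-6, so
the scaled strength 2Nₑs sweeps the nearly-neutral to selected regime
(2×10⁻⁴ … 2) across the grid. This choice is load-bearing: because
the beneficial term grows like 2Nₑs, the overall relative fixation
probability is only monotonically decreasing over the whole grid when
2Nₑs stays below ≈4.5 at the top of the range; with larger fixed s
the beneficial contribution eventually dominates and the curve turns
upward. The adaptive fraction is monotonically increasing in Nₑ for
any s > 0.

## Asymptotic McDonald–Kreitman

With polymorphism counts P(x) (test class, e.g. uAUG-creating SNPs in
5′UTRs) and P₀(x) (neutral reference, AUG-creating SNPs in introns)
per derived-allele-frequency bin and fixed differences D, D₀:

    α(x) = 1 − (D₀/D) · P(x)/P₀(x),

fit with α(x) = a + b·exp(−cx) over x ∈ [0.1, 0.9] (the trimmed range
guards against polarization error at the frequency extremes), with a
linear fallback when the exponential fit fails or c < 0;
α_asym = fit at x = 1. Bins are merged with their neighbors until
every neutral bin holds ≥ 5 counts. The CI is a percentile bootstrap
(599 replicates by default) resampling bin counts as independent
binomials conditioned on the class totals; divergence counts are held
fixed. Polarization of newly fixed uAUGs uses single-gain parsimony on
the primate ladder with an outgroup; gains are classed CpG-derived
when the ancestral context was ACG→ATG or CGTG→CATG (a CpG on the
opposite strand), and non-nested presence patterns are flagged as
homoplasy and excluded.

## pN/pS and NG86 ω

SNPs overlapping uORF codons (CDS-overlapping oORF portions and
repeat-flagged starts excluded) are called synonymous only when the
amino acid is unchanged in every overlapping uORF frame,
nonsynonymous only when changed in every frame, and ambiguous
(excluded) otherwise. The expectation under neutrality is the
mutational-opportunity ratio obtained by enumerating all nine
single-nucleotide changes of every codon under a uniform mutation
model (a ts/tv-weighted spectrum can be supplied instead).

Pairwise ω uses Nei–Gojobori counting: per-codon site counts with one
site per position, differences averaged over shortest mutational
pathways, pathways through intermediate stop codons excluded unless
all are. Two stop conventions are provided: mutations to stop codons
counted as nonsynonymous (default for toy counting), or disallowed
with each position's site split over the remaining changes (the yn00
convention). Genome-scale calibrations use the second convention —
with stops-as-nonsynonymous, stop-creating changes inflate the
nonsynonymous site count while the corresponding differences are
never observed in stop-free alignments, biasing ω below 1 even under
neutrality; under the exclusion convention neutrally evolved codon
pairs give median ω ≈ 1, which the tests verify on ~10⁵ codons.
N + S = 3 × codons holds in both modes. A Jukes–Cantor multiple-hit
correction is available and left off for small inputs where the log
is unstable. uORF alignments are ranked by Kozak score and cut into
equal-count bins (1000 at genome scale; tests use fewer), each bin's
concatenated alignment scored separately.

## Conservation scores

A site's presence profile across species comes from MAF blocks: a
species is present iff its aligned triplet at the reference columns
is exactly ATG, gap-free, case-insensitive (soft-masking tolerated);
N counts as absent; species missing from the block are absent; the
first block covering the site in the reference is used. BLS = B₀ /
total tree length, where B₀ sums the branches of the minimal subtree
spanning the present species. A reference-only site scores 0 (a
one-leaf subtree has no edges) — stated explicitly because using the
terminal branch length instead would shift every score. Origination
branches are assigned by single-gain parsimony to the branch
subtending the MRCA of present species, with losses implied inside
the clade. Signal-to-noise at cutoff c is
fraction(signal ≥ c)/fraction(background ≥ c), with annotated start
codons excluded from the background.

The peptide screen aligns the reference uORF peptide (≥ 10 codons;
oORFs truncated to their non-CDS-overlapping portion) against the
three forward-frame translations of each species' orthologous UTR
sequence using local alignment (match +2 / mismatch −1 / gap open −4
/ extend −1, configurable). A species matches when the first aligned
target codon is AUG, no stop codon or indel disrupts the first 80% of
the match, and identity exceeds the threshold (caller-supplied; 0.3
default standing in for the 2.5% quantile of genome-wide protein
identity, which requires external proteome alignments). Frames are
scored independently rather than chained through frameshifts; a
frameshifted target surfaces as a truncated or disrupted single-frame
match, which criterion (2) catches. Matched species feed the same BLS
machinery to give a peptide-level conservation score.

## Kozak context and translation

The PWM covers the seven informative slots −6..−1 and +4 around a
start codon; the invariant +1..+3 AUG would add a constant and is not
scored. Probabilities are (count + 0.01)/(total + 0.04) per position
(pseudocount 0.01 avoids −∞ on unseen bases); short UTR contexts are
skipped during building and N-padded (zero contribution) during
scoring. Scores are log₂ odds against a uniform background (bits);
genomic backgrounds can be supplied. PWM distance is the Euclidean
norm over all entries divided by the number of positions, making
distances comparable across PWM widths.

TIS signal is the initiating-RPF count in the −1..+4 window divided
by mean RNA coverage there, with read floors (defaults: ≥ 2 RPFs and
≥ 4 RNA reads) applied before the score–signal Spearman correlation
over equal-count score bins (50 by default). TE regression is
per-variant OLS of log₂ TE on the non-uORF allele count {0,1,2},
after dropping variants with MAF < 5%, fewer than 3 informative
individuals, or constant genotype; a positive slope means the uORF
allele represses translation. The canonical-versus-noncanonical
validation comparison is a two-sided Fisher exact test on the 2×2
outcome table (one-sided available).

## Synthetic data

Generators return their realized ground truth alongside the data, and
all randomness is derived from counter-based per-gene streams, so a
dataset is reproducible from its seed and identical across retention
settings up to the thinning step.

- **Transcriptomes**: 5′/3′UTRs from a first-order Markov chain
  (default transition matrix mildly CpG-depleted; log-normal lengths,
  medians 150/300 nt, σ = 0.6), CDS of 100–400 sense codons. The
  chain matches the dinucleotide-preserving null by construction.
  Depletion thins uAUG occurrences independently with the
  (class-specific) retention probability; a destroyed AUG is removed
  by swapping one of its bases with a character elsewhere that has
  identical left/right neighbors, which preserves the dinucleotide
  multiset exactly and therefore leaves the permutation-null
  expectation untouched — the O/E ratio recovers the retention
  parameter by construction. Destroying AUGs by plain point mutation
  instead (the fallback when no safe swap exists) also removes AT/TG
  dinucleotides and inflates O/E by ~10% at retention 0.6.
- **Alignments**: reference UTRs evolve down an 8-taxon tree
  (branches 0.1, substitution probability 0.8 × branch length per
  site); designated conserved sites have their AUG restored with
  probability 0.9 per branch. The tree is much shallower than a
  100-species vertebrate alignment, so absolute SNR values are
  conservative relative to deep alignments; ordering properties
  (conserved > background) are what the tests assert.
- **MK data**: neutral SFS ∝ 1/x over 20 bins; the test class adds an
  exponentially low-frequency-concentrated deleterious component;
  D_test is set so the expected adaptive fraction equals the chosen
  α; all counts Poisson-sampled. The naive pooled MK estimator is
  biased downward on these data while α_asym is not, reproducing the
  motivation for the asymptotic estimator.
- **TE panels**: 60 individuals, 30 canonical (β = 0.4) and 30 null
  noncanonical variants; genotypes Binomial(2, f) with f ~ U(0.1,
  0.5); log₂ TE = β·g + N(0, 0.5).
- **TIS data**: expected initiation ∝ 2^score with Poisson sampling
  and log-normal RNA coverage.

What the generators do not emulate: indel evolution and alignment
error, linkage and demography in the SFS (analytic shapes, not
coalescent samples), expression-correlated sequence features, GC
isochores, and paralogy in alignments. Passing tests therefore
demonstrate correctness of the statistics under clean, known-truth
conditions, not robustness to every artifact of real annotation and
alignment pipelines.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run analyses at reduced
scale chosen for desk-size reproducibility: O/E calibration on 200
datasets of 30 × 100-nt sequences with 200 permutations, retention
recovery on 2000–3000 genes, MK recovery over 50 seeds with
199-replicate bootstraps, ω calibration on ~10⁵ neutral codons, and a
50,000-replicate Wright–Fisher cross-check at Nₑ = 500. Every
stochastic step takes an explicit seed; pipeline outputs embed the
seed and parameters in their headers, and re-running a configuration
is byte-identical.

## Limitations

- Non-AUG (noncanonical) uORF starts are out of scope for prediction;
  they enter only as user-supplied exclusion lists and validation
  classes.
- Alternative genetic codes and trans-spliced transcriptomes are not
  handled.
- The peptide screen's per-frame alignment does not chain across
  frameshifts; a mid-peptide frameshift with high downstream identity
  in the new frame is scored as a disruption, not a continued match.
- ω uses NG86 counting, not maximum-likelihood codon models; for
  closely related species at uORF-scale alignments this is standard,
  but saturation handling is limited to the optional Jukes–Cantor
  correction.
- Variant and genotype inputs are consumed as TSV tables; VCF parsing
  is not wired in.
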