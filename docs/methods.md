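# Methods

## Observation model

The unit of observation is a sequenced fragment crossing a window of four
consecutive CpG sites (an epiallele locus). Windows slide by one CpG by
default, so a chromosome with *n* CpGs yields *n* − 3 loci; a `--disjoint`
flag tiles non-overlapping windows instead. Each fragment with a definite
call at all four positions contributes one of 2⁴ = 16 patterns; fragments
covering fewer than four positions, or carrying an unresolved call, are
discarded for that locus (no imputation). Paired mates are merged into one
fragment by default so a molecule is counted once; a position where the two
mates disagree becomes unknown. Optional duplicate removal drops fragments
with identical chromosome, span and calls. Both merge and de-duplication are
flags because either convention is defensible for RRBS libraries.

Coordinates are 0-based half-open internally; locus ids are rendered 1-based
inclusive over the CG dinucleotides (`chr6:155314465-155314568` style).
Calls on reverse-strand reads (which observe the G of the dinucleotide) are
mapped to the forward-strand C, so both strands inform one site.

## Pattern distributions and the pseudocount

Per locus and sample, raw frequencies pᵢ = nᵢ/depth are adjusted as
p'ᵢ = (pᵢ + ε)/(1 + 16ε) and renormalised, keeping Σp' = 1 exactly while
removing zeros from the logarithm's argument. The pseudocount is applied to
probabilities, not counts, so its effect is depth-independent. The default
ε = 6.25×10⁻³ is a required, configurable parameter: small enough that the
dissimilarity of disjoint-support loci stays near 1 at typical depths
(JSD ≈ 0.97 at depth 30), large enough to be numerically meaningful.

## Divergence

Entropies use log₂, so the Jensen–Shannon divergence of any two 16-pattern
distributions lies in [0, 1] and JSD = √JS in [0, 1] is a metric (tested
against the triangle inequality and an independent rational-arithmetic
evaluation). With ε = 0 the 0·log 0 := 0 convention applies. JS values are
clamped to [0, 1] after evaluation because rounding can produce −10⁻¹⁷.

## Calling thresholds

All thresholds are fitted, not fixed: a normal null is moment-estimated from
the observed score distribution itself (mean and ddof-1 standard deviation;
`--robust` substitutes median and normalised MAD) and the threshold is
μ + z₁₋α·σ at one-tailed α = 0.05. Requiring ≥ 30 scores guards against
meaningless fits; an all-constant score set is rejected as degenerate using
a relative tolerance (10⁻¹² of max(1, |μ|)), since the standard deviation of
a constant vector is ~10⁻¹⁷ in floating point rather than exactly 0.

The CSI contrast — max(S) − mean(S ∖ {max}) — is isolated in a single
private function so the alternative max − second-max contrast can be swapped
in one place. Ties at the maximum make a locus ineligible rather than
guessing a winner. Loci whose entire JSD set is zero (identical pattern
counts everywhere) are removed before CSI scoring and before the null is
fitted. Thres1 is fitted per core–periphery pair; Thres2 (local-specific)
once over all eligible loci. For CPDE/specific calls the γ = 0.3 floor on
the core–periphery JSD (or on the assigned sample's mean JSD) reflects where
the core-periphery JSD distribution peaks in multi-region tumor data and
suppresses low-signal calls that a fitted threshold alone would admit.

Because the pooled JSD and CSI null distributions are mildly right-skewed,
the exceedance of the fitted normal threshold on *real* null data sits near,
not exactly at, α; on truly Gaussian scores it is α within binomial error
(verified at n = 10⁵).

## Heterogeneity summaries

Epipolymorphism, 1 − Σpᵢ² over raw frequencies (never pseudocounted), is 0
for a pure population and at most 15/16. A differential epiallele whose
epipolymorphism is higher in the core than the periphery is labelled
*drift*, lower *adaptation*; exact equality gets its own *unchanged* label.
Locus methylation is the count-weighted mean methylation of the four CpGs.
The adjacent-CpG Jaccard index counts fragments with definite calls at both
sites: J = n₁₁/(n₁₁ + n₁₀ + n₀₁), defined as 1 when no fragment is
methylated at either site (perfect agreement). The AUC assigns methylation
0% to the first bin and 100% to the last (the open-interval bin definitions
otherwise leave the endpoints homeless), and empty bins contribute 0, since
a median over nothing is undefined. The operation takes an explicit record
set, so the caller decides which loci (e.g. which pair's differential calls)
enter the summary.

## Genomic annotation

Promoters span TSS − 1500 bp to TSS + 500 bp in the direction of
transcription; CpG-island shores are the 2 kb flanks of islands, shelves the
next 2 kb, everything else opensea, with island > shore > shelf precedence
so the four classes partition the genome. Membership is decided by the locus
midpoint — a 4-CpG locus is tens of bases long, and midpoint assignment
avoids double labels. Overlapping genes resolve by label precedence
(promoter > 5'UTR > exon > intron), then distance to TSS. 5'UTR labels
require a CDS (BED12 thickStart/thickEnd); without one the label degrades to
exon.

## Synthetic cohorts

The generator emulates the targeted study design: one core plus four
periphery samples over a shared locus set, defaulting to depth 25 per locus
(typical RRBS coverage). Null loci share one mixture across samples, drawn
from a sparse Dirichlet (concentration 0.3 over the 16 patterns) that
concentrates mass on a few dominant patterns the way real pattern tables do;
differential loci plant a divergent mixture in one designated sample
(default: the core gets a uniform 16-pattern mixture while the others carry
a `1111` point mass — maximal disorder contrast; a `dirichlet_pair` model
draws both sides randomly for graded effects). Reads are i.i.d. multinomial
draws per locus; fragments exactly cover their locus. Not modelled: read
length and coverage variation, bisulfite conversion errors, sequencing
errors, and spatial correlation between neighbouring loci. Passing tests
therefore demonstrate the correctness of the arithmetic and the calibration
of the thresholds under clean sampling noise, not robustness to the
technical artefacts of real libraries.

Loci are placed on a synthetic chromosome (4 CpGs 10 bp apart, loci 200 bp
apart) so the cohort can be emitted as Bismark-style SAM plus a FASTA
reference whose only CpGs are the loci's; the emit → extract → count round
trip reproduces pattern counts exactly and anchors the alignment reader.

## Problem sizes in the test suite

Calibration and recovery tests use cohorts of 500 null + 20 differential
loci at depth 30 with 1 core + 4 peripheries — large enough for stable
empirical rates (≥ 90% recovery of planted loci at ≤ α false calls) while
keeping the full suite fast; the null-threshold calibration check uses 10⁵
Gaussian draws. All simulations are seeded and deterministic.

## Known limitations

* Epiallele length is fixed at four CpGs; other window lengths, methylation
  haplotype blocks and read-discordance scores (PDR, MHL, FDRP) are out of
  scope.
* No multiple-testing correction beyond the single one-tailed α — calls on
  many loci should be interpreted as a ranked screen, not a family-wise
  error guarantee.
* The normal null is an approximation to a skewed score distribution; the
  `--robust` fit mitigates but does not remove this.
* Non-CpG (CHG/CHH) contexts are ignored.
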