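# Methods

This note documents the models, conventions, numerical choices and known
limitations of wgdkit, stage by stage.

## Codon divergence (NG86 + Jukes–Cantor)

Site counting follows Nei–Gojobori: each codon position contributes the
fraction of its single-nucleotide neighbours that preserve the amino acid;
neighbours creating a stop codon are removed from the denominator, and
nonsynonymous sites are defined as 3 − s so that s + n = 3 holds exactly for
every sense codon.  Differences between codons are classified per
mutational step and averaged over all orderings of the steps; orderings
passing through a stop codon are excluded, and in the degenerate case where
every ordering is blocked all orderings are used, with steps into or out of
a stop classified as nonsynonymous.  Site counts are averaged across the
two sequences.  Both raw proportions are corrected with the Jukes–Cantor
formula d = −(3/4)ln(1 − 4p/3), undefined at p ≥ 3/4; estimates are flagged
saturated at p ≥ 0.74 and saturated pairs are excluded from downstream
distributions.  ω is reported only when dS > 0 and neither rate is
saturated.

These are counting estimators, not maximum-likelihood codon models: with
transition/transversion bias (κ > 1) the synonymous-site count is
systematically low, so dS is slightly overestimated and ω underestimated
(about 10% at κ = 2; the tolerances used in the acceptance checks cover
this).  At κ = 1 the estimator is essentially unbiased, which is why
neutral-calibration checks (ω = 1) are run at κ = 1.

Alignments are protein-guided: an aligned amino-acid row is back-translated
onto its source CDS, verified codon by codon, and any column containing a
gap, an ambiguous base or an in-frame stop in any sequence is dropped and
tallied.  Column dropping is per pair (pairwise deletion).  CDS whose
length is not a multiple of 3 are trimmed at the 3′ end with a warning;
ambiguity codes other than N become N at load.

**4DTv.**  A column contributes one fourfold site when both codons share an
identical 2-base prefix whose four completions encode one amino acid; the
statistic is the fraction of such sites whose third bases differ by a
transversion.  It is reported uncorrected for multiple hits; at the
divergences relevant here (4DTv ≲ 0.3) the correction would be small
compared with the width of the distributions being compared.

**Sliding windows.**  150 bp windows at 30 bp steps over the retained
alignment (post-column-drop coordinates, from the start codon), both
window and step forced to codon multiples; the last window ends at or
before the alignment end, and an alignment shorter than one window yields a
single flagged truncated window.  Windows with dS = 0 report ω undefined.

**Branch assignment.**  With an outgroup O and paralogs P1, P2: a column
where exactly one paralog differs while the other matches O places the
(pathway-averaged) change on the differing paralog's branch; columns where
all three states differ, or where O matches neither, are tallied as
parsimony-ambiguous and skipped.  Branch rates use the branch sequence's
own site counts.  The summed branch counts are therefore a lower bound on
the pairwise counts between the paralogs.

**Neutrality screen.**  In place of a likelihood-ratio machinery, a
counts-based screen: under ω = 1 the probability that an observed
difference is nonsynonymous is N/(N+S), so nd out of round(sd+nd)
differences is tested two-sided against that proportion with an exact
binomial (minimum-likelihood summation, the convention of the standard R
test functions).  The screen is a substitute with the right size under the
counting model's assumptions (verified type-I error ≤ 0.07 at α = 0.05 on
ω = 1, κ = 1 simulations); it is less powerful than branch-site ML tests
and is labelled as a screen in all outputs.

## Pair catalog

Hits are the 12-column tabular similarity dialect, thresholded at
e ≤ 1e-20; self-hits are removed and reciprocal duplicates collapsed
keeping the best bitscore.  Genes flagged as transposable elements (an
input annotation, not recomputed) and genes with more than five distinct
non-self homologs at the threshold ("repetitive") are excluded, with a
reasoned exclusion report.  Families are single-linkage connected
components of the retained-hit graph — a deterministic, dependency-light
stand-in for Markov clustering that preserves the only property used
downstream (family co-membership).  Output ordering is invariant to input
row order.

## WGD inference

The paralog-age distribution uses finite, unsaturated dS values clipped to
[0, 3], a Gaussian KDE with Silverman bandwidth evaluated on a 0.005 grid,
and a mode search restricted to [0.2, 2.0] by default to avoid the
small-scale-duplication spike at dS ≈ 0.  A histogram mode (bin 0.05) is
available as a cross-check.  Fewer than 10 usable pairs is an error.  The
KDE mode is exactly invariant to input order; duplicating the whole sample
changes the Silverman bandwidth slightly (n^(−1/5)), so mode invariance
under duplication holds only to within a grid cell or two.  WGD membership
is a closed dS interval, default [0.5, 0.9].  Dating uses T = dS/(2r)
— pairwise divergence accrues on both lineages — with the lineage factor
exposed in the configuration for the T = dS/r convention; r defaults to
2.81 × 10⁻⁹ synonymous substitutions per site per year.

## Expression divergence

The correlation test runs on the ordered 16-sample series (8 stages × 2
sexes) on the expression values as given; a pair is divergent when
r² < 0.3.  Genes with zero variance leave the correlation undefined and
the pair is excluded from reported denominators.  The Fisher test requires
raw integer counts (an exact 2×2 test is not defined on normalized values):
counts are summed per sex over a user-supplied stage pool (which harvest
stages count as "developing" vs "maturing" is an input, not inferred), the
table is paralogs × sexes, and the two-sided p-value is the
minimum-likelihood hypergeometric summation (delegated to
`scipy.stats.fisher_exact`, verified against exact rational enumeration to
1e-12 over all tables with margins ≤ 30).  Any zero margin returns p = 1
and a degeneracy flag.  Fold bias is log₁₀((male+c)/(female+c)) per paralog
with pseudocount c = 1 by default, flagged when the two paralogs' ratios
differ by more than log₁₀(5).  Raw p-values are reported without
multiple-testing correction, mirroring the analysis style this reproduces;
the absence is deliberate and documented here.

## Sex-chromosome classification

Depth input is 1-based 4-column TSV (contig, position, male, female),
converted to 0-based internally with unreported positions zero-filled.
Windows are non-overlapping, 500 bp by default — fine enough to resolve the
3 kb PAR rule, coarse enough to stabilize Poisson depth at ≈ 20× — with a
kept partial final window.  Per window: female fraction F/(M+F) (NaN when
both are zero), and a repetitive flag when (M+F)/2 exceeds twice the
expected single-copy depth.  Window classes: repetitive if flagged; else
male-specific if female fraction < 0.05 (the "female coverage ≈ 0"
operating point) and male depth ≥ half expected; else PAR-candidate if
female fraction > 0.30; else undetermined.  Consecutive same-class windows
merge; candidate runs become PAR-like only when strictly longer than
3,000 bp, otherwise undetermined; the merge-demote-remerge order makes the
procedure idempotent.  Classification is scale-invariant in the two depths
except for the repetitive flag, which is anchored to the expected
single-copy depth by design.  X-allele sequences are inputs; X–Y dS uses
the same NG86+JC estimator, distances are gene midpoint to anchor
coordinate (absolute by default), decay is Spearman rank correlation with
average ranks on ties and an undefined ρ when either variable is constant,
and a per-gene flag marks X–Y dS exceeding every interspecific baseline
(recombination arrest predating speciation).

## Synthetic data generators

The codon process is mutation–selection: K80 mutation (transition rate κ,
transversion rate 1) with nonsynonymous changes damped or amplified by ω
and stop codons unreachable — simpler than a full codon model with
empirical frequencies, yet able to realize any (dS, ω) pair.  Branch
lengths are calibrated numerically per input composition: the expected
NG86-estimated dS as a function of time is computed from the process's
transition matrix (eigendecomposition, verified against `expm`) through the
same site/difference matrices the estimator uses, and bisection finds the
time hitting the target (well within 1%); targets beyond the Jukes–Cantor
saturation boundary raise an error.  Because calibration targets the
*estimated* dS, generator targets and estimator outputs are directly
comparable without bias bookkeeping.  Pair sets draw WGD-burst dS from a
lognormal (default median 0.69, log-sd 0.08) over an exponential
small-scale-duplication background (default mean 0.15), 300-codon genes,
with a synthetic hit table that round-trips the planted pairs through the
catalog exactly.

Expression counts are negative binomial (dispersion 0.1) around latent
log-profiles; conserved pairs share one profile, divergent pairs draw
independent ones.  The default profile amplitude (log-sd 1.0) is set so the
count-scale correlation of conserved pairs realizes the r² ≈ 0.8 target
given the noise model, keeping false divergence calls ≤ 2% while
independent profiles give E[r²] ≈ 1/15 — comfortably separated from the
0.3 rule.  Planted divergent counts are round(fraction × n).  Sex bias
multiplies one paralog's male-sample means by an odds factor.  Depth
tracks are per-position Poisson draws (male-specific: (d, 0); PAR-like and
background: (d, d); repetitive: (4d, 4d); d = 20 by default), with a
noiseless variant emitting the rates exactly.  Every generator is a pure
function of its arguments including the seed, and each dataset can carry a
JSON "truth" sidecar sufficient to score any downstream call (a region
scorer computing base-level confusion matrices is included; background
bases score as PAR-like, sharing its depth signature).

What the generators do not emulate: alignment error and indels (alignments
are gap-free by construction), GC/codon-usage heterogeneity, rate variation
across sites beyond the ω windows, expression normalization artifacts,
mappability and GC biases in read depth, and read-level noise.  Passing
recovery tests therefore demonstrates estimator correctness and calibration
under the stated models, not robustness to upstream artifacts in real data.

## Problem sizes

The test suite and the acceptance script scale their simulations to run on
one CPU in minutes: mode-recovery checks use 1,250-pair sets (the full
5,000-pair setting runs in the acceptance script), ω/dS recovery uses ten
10,000-codon replicate pairs, the expression check uses the full 1,311
pairs, and the neutrality size check uses 1,000 replicates of 300 codons.
Gene length is kept at 300 codons in scaled-down mode-recovery runs because
gene length, not pair count, sets the per-pair estimation noise the peak
detector must overcome.

## Design choices made where the design was open

* NG86 with Jukes–Cantor chosen as the canonical counting realization of
  "JC-corrected dS/dN"; ML codon models are out of scope.
* Reciprocal hit collapse keeps the maximum bitscore (deterministic).
* The >5-homolog repetitive rule counts distinct non-self subjects.
* 4DTv uncorrected (no HKY-style correction).
* dS window endpoints closed on both sides.
* Dating divides by 2r, with the factor configurable.
* Fisher on raw counts; pseudocount 1 for ratio plots; two-sided tests by
  minimum-likelihood summation throughout.
* Depth-report gaps are zero-filled.
* The single CLI seed fans out to stages by fixed offsets.
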