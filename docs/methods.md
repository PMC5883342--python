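# Methods

## Signal model and genotype calling

A SNP array reports two per-probe signals: the Log R Ratio (LRR), the
log-scaled total intensity relative to a diploid reference, and the B-allele
frequency (BAF), a normalised estimate of the fraction of B alleles among
the chromosomal copies present.  In a region of copy number `c`, a SNP
carrying `k` B alleles has expected BAF `k/c`; its LRR shifts negative for
deletions and positive for duplications, with the duplication shift smaller
in magnitude because the exponential of LRR, not LRR itself, is linear in
copy number.

Genotype calling inside a CNV segment is deliberately simple and auditable:
fixed, closed BAF intervals per state, with open gaps between them mapping
to no-call.  Defaults are haploid A = [0, 0.25], B = [0.75, 1] and triploid
AAA = [0, 0.12], AAB = [0.2, 0.45], ABB = [0.55, 0.8], BBB = [0.88, 1].
These are the kind of cutoffs an analyst fixes after visual review of cohort
BAF plots (the `inspect_baf` summary supports exactly that review); they are
dataset-specific in principle, so `ThresholdScheme` is a first-class
configurable object and the scheme validator enforces the structural
invariants (intervals inside [0, 1], pairwise disjoint, separated by
non-empty no-call gaps).  Endpoints are inclusive because ranges quoted as
"0–0.25" carry no exclusivity statement; closing the intervals makes
boundary behaviour deterministic and testable.  Calling is defined only for
copy numbers 1 and 3: homozygous deletions have no allele to genotype and
four-copy states would need a different cluster model, so both are rejected
rather than guessed.

Call rate is the fraction of SNP×sample observations inside called segments
that receive a state other than no-call, reported as a percentage rounded
half-up to one decimal.  Missing BAF counts in the denominator: a probe that
failed is still a probe the chip interrogated.

## CNV segment handling

Segments are imported from PennCNV `.rawcnv` text output (1-based inclusive
coordinates; thousands separators tolerated) or, for self-contained runs on
synthetic data, produced by a thresholded run-length segmenter: maximal runs
of at least 10 consecutive SNPs with LRR below −0.3 become copy-number-1
segments, runs above +0.2 copy-number-3.  The cutpoints sit roughly midway
between canonical state means (−0.66 / 0 / +0.40).  The segmenter is a
deliberately simple stand-in so the pipeline runs end to end without an
external caller; it is not a reimplementation of an HMM caller and makes no
attempt at GC-wave correction or quality weighting.

The working set is then: filter (keep segments with ≥ 10 SNPs *and* length
≥ 10 kb, both inclusive), merge (same-chromosome, same-copy-number segments
with at most 1,000 uncovered basepairs strictly between them fuse, SNP
counts summed, iterated to a fixed point — a single sorted sweep reaches it,
verified in tests against an exhaustive pairwise-merge oracle), restrict
(keep segments overlapping the target locus; whole segments by default,
clipping optional).  Merging deliberately never fuses segments of different
copy number: a deletion abutting a duplication is not one event.

## Association testing

Each SNP is tested with the Pearson chi-squared statistic on the 2×2
allele-group × phenotype table, closed form `n(ad−bc)² /
((a+b)(c+d)(a+c)(b+d))`, 1 df, **no** Yates continuity correction — the
uncorrected statistic is what reproduces the worked reconstruction below.
Haploid samples group by allele identity; triploid samples by majority
allele (≥ 2 of 3 copies).  No-calls are dropped from that SNP's table only
(pairwise deletion), preserving information at the ~99% call rates the
method achieves.  Tables with a zero margin, or SNPs with fewer than two
informative samples, are flagged untestable instead of contributing a
meaningless p.

Multiple testing uses Bonferroni over the effective number of independent
tests, with two-tier scopes: an a-priori candidate gene can carry its own
(smaller) M_eff while the rest of the locus uses the locus-wide value.
M_eff is estimated by the Li & Ji rule on the eigenvalues λᵢ of the
genotype-dosage correlation matrix (pairwise-complete over no-calls):

    M_eff = Σᵢ [ I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋) ]

Monomorphic SNPs are dropped first; the estimate is clamped to [1, M].  Two
numerical notes.  First, pairwise-complete correlation matrices need not be
positive semi-definite, so eigenvalues are clipped at zero.  Second, f(λ) is
discontinuous at integers, and the structurally exact eigenvalues (λ = 2 for
a duplicated SNP) land on those discontinuities; eigenvalues are therefore
rounded at 1e-10 before the floor.  Because the trace of a correlation
matrix is the integer M, this estimator always returns an integer — a
property worth knowing when comparing against block-based estimators (such
as GEC), which return fractional values like 5.35; those published values
are accepted directly as scope inputs.  A further caveat the test suite
encodes: the intuitive claim "adding an exact duplicate SNP cannot increase
M_eff" is false for this rule on arbitrary data (the integer-valued sum can
jump up when an eigenvalue crosses a floor); it does hold in the structured
cases of identical columns (M_eff = 1) and of duplicating one of M mutually
independent SNPs (M_eff stays M).  The estimate is also bounded by the
sample size: with fewer samples than SNPs the correlation matrix is
rank-deficient and M_eff cannot exceed the rank.

The combined two-group analysis fits `affected ~ diagnosis + genotype +
diagnosis×genotype` by IRLS maximum likelihood (statsmodels GLM, binomial
family, up to 100 iterations, tolerance 1e-8), reports a likelihood-ratio
test of the full model against intercept-only, and Nagelkerke's R²:

    R²_CS  = 1 − exp(2(ℓ₀ − ℓ₁)/n)
    R²_max = 1 − exp(2ℓ₀/n)
    R²_N   = R²_CS / R²_max

When any fitted group probability sits within 1e-6 of 0 or 1 the separation
flag is raised: the log-likelihood is trustworthy but the boundary
coefficient's magnitude is not.  Separation is flagged, not penalised
(no Firth correction), keeping the model exactly the stated one.

### Worked reconstruction

The package's acceptance checks include a reconstruction exercise: given a
25-sample hemideletion cohort with 8 severe cases, one no-call at the peak
SNP, 80% of the risk-allele group severe and 84% of the other-allele group
not severe, exhaustive search over all integer 2×2 tables shows the unique
solution (4, 1 / 3, 16), giving chi² = 7.899 and p = 0.00494.  With M_eff =
5.35 for the candidate gene this adjusts to 0.0265, and the gene-wise
significance threshold is 0.05/5.35 = 0.009346 (quotable as the conservative
bound 0.0094).  Extending with duplication-group counts (majority
other-allele 4/10 affected, majority risk-allele 0/3) and fitting the
interaction model on the resulting n = 37 gives ℓ₀ = −22.517, ℓ₁ = −17.519
and R²_N = 0.336, with the separation flag set by the empty cell.  Published
analyses of data like these can report slightly different pseudo-R² values
depending on the genotype coding (binary majority-allele vs 3-level dosage)
and the exact n analysed; both codings are available here
(`majority_allele_coding`, `dosage_matrix`) and the reconstruction value is
reported as computed, not adjusted toward any external number.

## Synthetic cohorts

`simdata` generates cohorts in which every pipeline stage has known truth.
Defaults describe a single-locus reciprocal-CNV study: 25 deletion and 13
duplication carriers, a 1.4-Mb region (chr7:72,700,000–74,100,000) carrying
1,540 SNPs — at which size the per-SNP×sample denominators are 38,500
(deletion group) and 20,020 (duplication group) — flanked by 150 diploid
probes per side, allele frequencies uniform on (0.05, 0.95), LRR means
−0.66/0.0/+0.40 for copy numbers 1/2/3 with SD 0.15, BAF noise SD 0.03, and
a 1% planted no-call rate.  At these settings the simulated haploid call
rate rounds to 99.0% — the regime the thresholds were designed for.
Haploid B alleles are Bernoulli(f), triploid B counts Binomial(3, f),
diploid flanks Hardy–Weinberg Binomial(2, f).  BAF is the canonical cluster
mean plus truncated Gaussian noise; planted no-calls are produced by
resampling BAF uniformly into the scheme's no-call gaps (never by deleting
records, so call-rate denominators stay meaningful).  An optional risk SNP
drives a binary phenotype through a logistic model on the binary risk group,
with a configurable baseline prevalence (default 0.3) and effect in
log-odds.  Randomness is a single seed fanned out into per-sample substreams
(`numpy` `SeedSequence.spawn`), so output is independent of iteration order
and byte-identical across reruns.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: linkage disequilibrium between SNPs (draws
are independent, so estimated M_eff ≈ M rather than the much smaller values
real LD produces), GC-content waves and batch effects in LRR, asymmetric or
sample-specific BAF cluster positions, mosaicism, and genotyping-failure
modes that are not well described by uniform resampling into the no-call
gaps.  Tests on these cohorts validate the *arithmetic and the contracts* of
the pipeline, not the biology of any particular locus.

## Test and check sizes

The simulation-based checks run at sizes chosen to make their statistics
sharp while keeping the whole suite fast: genotype-recovery checks use the
study-sized 38-sample cohort at 1,000 SNPs (zero-noise recovery must be
exact; at BAF SD 0.05 at least 99% — the binding constraint is the triploid
AAB/ABB clusters, whose interval edges sit about 2.3σ from the cluster
mean at that noise).  The scan's type-I error uses 200 samples × 1,000 null
SNPs with allele frequencies in 0.2–0.8 so that expected cell counts
support the asymptotic chi-squared reference (the check is that the
empirical rejection rate at α ∈ {0.05, 0.01} stays within 3 binomial
standard errors of α).  Power checks plant a risk SNP at allelic odds ratio
10 in 200 samples, where it must rank first; a coarser grid (odds ratios 1,
3, 10) verifies that detection power is monotone.

## Known limitations

- Thresholds are global per scheme, not per-sample adaptive; systematically
  shifted BAF in a sample degrades gracefully into no-calls rather than
  being recalibrated.
- The built-in segmenter fragments segments whenever noise crosses the LRR
  cutpoint for a single probe (missing LRR also breaks runs); with sparse
  probes the 1-kb merge cannot rejoin such fragments.  Real analyses should
  import segments from a dedicated caller.
- The chi-squared test is asymptotic; at very small group sizes its p-values
  are approximate (the package reports the counts alongside every p so exact
  tests can be run externally if needed).
- Li & Ji M_eff is integer-valued and sample-size-bounded, as discussed
  above.
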