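# Methods

## Reference model

The reference is the 16,569-base rCRS coordinate frame, 1-based and
inclusive on every interface, circular, with the standard annotation of
13 protein-coding genes, 22 tRNAs, 2 rRNAs and the control region. The
D-loop is one feature with two arcs (16024–16569 and 1–576) joined
across the origin, because burden analyses treat it as a single gene
category. A position in an overlap region (ATP8/ATP6, ND4L/ND4, TI/TQ,
TC/TY, COIII/ATP6) is attributed to *every* overlapping feature; the
subject-level total counts each position once. Attribution-to-all is
order-independent and conservative when no allocation rule is available.

The packaged FASTA is a deterministic synthetic rCRS-equivalent, not the
real NC_012920.1 sequence: correct length, the 'N' placeholder at
np 3107, realistic base composition (A/C/G/T ≈ 31/31/13/25%), and the
real rCRS reference allele forced at every packaged haplogroup-marker
position so that marker ref/alt bookkeeping is coherent. Every
structural property the pipeline relies on (lengths, gene coordinates,
callable-position count, marker positions such as 12,612 and 13,708 in
ND5) is faithful; analyses that depend on the true base identity at
arbitrary positions would need the real sequence dropped in via
`load_reference(fasta=...)`.

The array leaves 25 of 16,569 positions uninterrogated (16,544 callable).
The identity of those positions is not public; the packaged surrogate
list holds np 3107 plus 24 positions in homopolymeric/hypervariable
tracts that resequencing arrays tile poorly (the CSB poly-C region
around 303–316, the 16183–16193 run, 16519, and a few recurrent problem
sites). The list is a config point (`load_reference(excluded=...)`).

## Intensity model and base calling

All math happens in *sense-base space*: antisense channels are re-indexed
by Watson–Crick complement at file-read time, making every downstream
formula strand-symmetric (swapping the two strands provably leaves calls
unchanged).

The vendor's calling algorithm is unpublished, so the caller is a fully
specified surrogate. For each position the eight log₁₀ intensities
(floored at 1 arbitrary unit to keep logs finite) are fitted by a
two-level template under each of ten genotype models: channels of
present alleles share a level μ_hi, absent channels share μ_lo, both by
least squares subject to μ_hi ≥ μ_lo. The constraint matters: without
it a pair model and its complementary pair partition the channels
identically and would be indistinguishable; when the unconstrained fit
inverts the levels, the constrained solution collapses both to the
grand mean. Model log-score is −RSS/(2σ̂²) with σ̂ pooled across the
subject's best-model residuals (6 degrees of freedom per position,
floored at 0.01 to keep noise-free quality finite); call quality is the
score gap between the best and second-best model in log₁₀ units.

Classification: quality < 3 → no-call; best single base → reference or
homoplasmic; best pair → heteroplasmic iff the background-subtracted
minor fraction lies in [0.2, 0.5] (closed interval, 1e-9 comparison
slack), otherwise the call collapses to the major allele's single-base
state — the sub-20% regime is deliberately *not* a call class and is
left to the REA index. Background per strand is the mean of that
strand's two lowest channels, subtracted and floored at zero; fractions
are computed on strand-averaged, background-subtracted channels, which
makes the noise-free estimate exact under the simulator's signal model.
Per-position degeneracies (all-zero channels, vanishing denominator)
degrade to no-calls with a logged warning rather than aborting a
subject.

## REA and the group scan

REA = log₁₀ of (mean of the two reference strand-channels) over (mean of
the six alternate strand-channels), computed at all 16,544 callable
positions regardless of call state. Pooling intensities before the
single log (rather than averaging per-strand log-ratios) is the default;
the alternative reading is one switch away (`rea_value` accepts the
records directly). The scale of REA is log-base-dependent, but the scan
is not: t and rank statistics are invariant under positive rescaling, so
changing the base alters no p-value and no direction — log₁₀ is chosen
for readability.

The two-group scan gates each position on Shapiro–Wilk normality in both
groups at p > 0.05 (the conventional level; the gate level is a
parameter), using Welch's t test when both pass and Mann–Whitney
otherwise. The Welch form is the safer default for unequal group sizes;
a pooled-variance flag is available in scipy's `equal_var` sense through
the same code path if ever needed. Significance is a fixed per-test
α = 0.001 with *no* multiple-testing correction across the 16,544
positions — that is the documented convention of this analysis style and
is stated here rather than silently "improved". Positions constant in
both groups get p = 1 and a degenerate flag. Direction summaries
(fraction of significant positions where a focus group's mean REA is
higher) raise on an empty significant set instead of returning 0.

## Cohort statistics

* Mann–Whitney: exact null distribution when both n ≤ 8 with no ties,
  otherwise normal approximation with tie and continuity correction —
  cohort group sizes straddle the exact/asymptotic boundary.
* Kruskal–Wallis + Dunn: Dunn's z statistics use tie-corrected rank
  variance and Bonferroni family-wise adjustment over the pairwise
  comparisons, matching the convention of the commonly cited software.
  All-identical data short-circuits to H = 0, p = 1.
* Base prevalence tallies mutations by the *reference* base at the
  mutated position and normalises by that base's count in the reference,
  since the four bases are unequally represented; chi-squared runs on
  the base × group count table with a warning when any expected cell
  falls below 1 and an explicit skip flag for mutation-free input.
* Copy number: 2^(mean Ct_B2M − mean Ct_D-loop) with ≥ 2 usable
  replicates per target; insufficient data yields a missing value, not
  an exception. Platelets carry no nuclear DNA, so only the mean
  mitochondrial Cq is reported. The formula is shift-invariant in Ct.
* Haplogroup flagging scores each packaged haplogroup (H, J, T, U, K —
  a documented marker *subset*, not a Phylotree implementation) by the
  fraction of its markers present; ties break lexicographically, scores
  below 0.5 are labelled undetermined, and an empty variant set gets a
  reference-like label. This is a group-composition screening aid,
  never a clinical call.
* Fisher's exact test with simulated p: tables with the observed margins
  are sampled by label permutation; extremeness is by table probability
  under the multivariate hypergeometric null;
  p = (1 + #extreme)/(n_sim + 1). Default n_sim = 10,000 stabilises the
  third decimal; the seed is explicit.
* Correlations gate both variables on a Lilliefors-corrected
  Kolmogorov–Smirnov test (p > 0.05 → Pearson, else Spearman), drop
  incomplete pairs, and require n ≥ 4. Two different normality gates
  coexist in the package on purpose: Shapiro–Wilk for the REA scan,
  Lilliefors KS for burden/correlation contexts, where each is the named
  convention.

## Synthetic cohorts

The generator emulates the data-generating structure the analysis
assumes, not the physics of the array. Per subject it plants: a
haplogroup backbone (all markers of a drawn haplogroup; a label absent
from the marker table plants nothing), per-gene Poisson homoplasmic
counts at 1.5/kb with group × gene multipliers, heteroplasmic variants
at 0.2/kb with fractions ~ U(0.2, 0.5), and per-position Bernoulli
low-level variants (rate 0.001) with fractions ~ U(0.01, 0.15). Those
rates put subjects at roughly 25–30 homoplasmic and a few heteroplasmic
mutations — the per-subject scale seen in blood cohorts of this kind.
Alt bases favour transitions 10:1 over transversions. A channel carrying
allele share s has mean μ_lo + (μ_hi − μ_lo)·s with μ_hi = 1000,
μ_lo = 50 (20:1 signal-to-background) and multiplicative lognormal noise
σ = 0.1 per channel; strands are i.i.d. Ct values are built as
Ct_D-loop = Ct_B2M − log₂(copy factor) + noise so the 2^ΔCt formula
recovers the planted factor in expectation.

Seeding is hierarchical: a structure seed fixes truth (who carries what),
a separate noise seed fixes intensity/Ct noise, so tests can redraw
noise with truth held constant. Everything is reproducible to the byte
under fixed seeds.

What the simulator does *not* model: spatial array artifacts, probe
saturation, cross-hybridisation beyond a constant background,
linkage between variants, or realistic site-specific mutational
hotspots. Passing recovery tests therefore demonstrate correctness of
the calling/statistics pipeline under the stated signal model, not
performance on real arrays.

## Problem sizes and numerical choices

Recovery tests run cohorts of 15 + 15 subjects over 50 seeded replicates
(planted ND5 homoplasmic multiplier 3, heteroplasmic D-loop/COI/ATP8
boost 4 in the maternal group) — sizes chosen to match the study's
group-size scale while keeping a full end-to-end run (simulate → call →
tabulate → test) in the minutes range. The scan calibration check uses
two groups of 20 across all 16,544 callable positions. Comparison
tolerances: REA against its arithmetic oracle at 1e-12 (identical
arithmetic reordered); Monte-Carlo estimates within ~3 standard errors
of enumerated exact values; the scan's empirical type-I error within the
99% binomial band around α.

## Known limitations

* The caller is a surrogate: it reproduces the documented behaviour
  (diploid detection range, threshold-3 no-calls) but not the vendor's
  exact quality-score scale; only the threshold's *semantics* (score gap
  in log units) carries over.
* The packaged exclusion list and haplogroup marker subset are
  documented surrogates; both are replaceable via configuration.
* Insertions/deletions are out of scope — substitution arrays do not
  interrogate them.
* No FDR control beyond the fixed per-test α of the scan, by design.
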