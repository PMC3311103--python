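# Methods

## The modeling problem

Bisulfite sequencing shows that methylation levels of CpG dinucleotides
vary widely even within a single promoter, and differently in different
cell types. `methylseg` models cell-type-specific methylation
*susceptibility* — the propensity of a CpG site, a DNA segment, or a whole
promoter to be methylated — from sequence alone, using a small set of
k-mer features. Its central object is the segment: a contiguous run of CpG
sites inside one amplicon that shares a methylation status. Where the true
segment boundaries lie is unknown, so the package searches for the
segmentation and the predictive model jointly.

## The k-mer mixture logistic model

For an instance with k-mer occurrence counts x = (x_1, ..., x_m),

    y = 1 / (1 + exp(-f(x))),    f(x) = β₀ + Σᵢ βᵢ xᵢ.

The logistic output is used directly as the calibrated methylation level
in (0, 1). Coefficients are estimated by maximizing the (optionally
weighted) binomial log-likelihood with a small L2 ridge on the slopes
(default 1e-6; the intercept is unpenalized). The ridge exists because
rare long k-mers routinely separate the classes completely, which would
otherwise send coefficients to infinity and break the search loop. The
optimizer is L-BFGS-B with analytic gradients, run to a gradient norm of
1e-8; it accepts a warm start, which the merge search uses to refit
cheaply after each tentative merge. An intercept is included by default —
segment class frequencies are rarely balanced — and `use_intercept=False`
restores the pure mixture form.

## Labels, segments and the objective

A site is labeled + iff its level exceeds the threshold (default 0.5,
strict, so a tie is −). A segment's methylation probability p is the
fraction of + sites it contains and its label t is + iff p > 0.5, again
strict. With S̄ the mean number of sites per segment in a configuration,
the search minimizes the weighted squared error

    O(S) = Σᵢ (S̄ / |Sᵢ|) (ŷᵢ − tᵢ)²,

so large segments are penalized less per site. Segment *selection* during
the search uses the opposite weighting, e_j = (|S_j| / S̄)(ŷ_j − t_j)²:
candidates are drawn with probability proportional to e_j, steering the
search toward large, badly predicted segments while keeping it stochastic.
Both weightings are intentional and play different roles; they are not a
single weight used inconsistently.

## The hill-climbing segment search

Enumerating configurations is hopeless — m boundary variables give 2^m
configurations, and the related parenthesization count P(n) (P(1) = 1,
P(n) = Σ P(i)P(n−i)) grows exponentially — so the search is a randomized
hill climber built from three procedures:

1. **Initialization.** Boundary bits are set wherever adjacent site labels
   differ, giving the finest label-consistent segmentation
   (`label-change`, the default). An `all-boundaries` mode starts from
   singleton segments instead.
2. **A merging pass.** Until every segment has been considered: draw an
   unvisited segment j (probability ∝ e_j; uniform when all errors are
   zero), tentatively merge it with its right neighbor in the same
   amplicon, refit the model (training stage) or keep it frozen (test
   stage), and accept iff the objective strictly decreases. The merged
   product is marked visited, so it is not immediately re-merged within
   the pass. The rightmost segment of an amplicon has no right neighbor;
   drawing it just marks it visited. A merge that would leave only one
   class across all segments is rejected, since the model is then
   unfittable.
3. **Passes and restarts.** Passes repeat until the between-pass
   improvement drops to δ (default 1e-6); the whole search restarts N
   times (default 10) from independent random streams and keeps the
   minimum-error result.

Accepted errors therefore decrease strictly within a pass and by more than
δ between passes; segment counts never increase; merges only clear
boundary bits. A single seeded generator drives selection, restarts and
class balancing, so identical seeds give identical results. The objective
is recomputed from scratch after every tentative merge — correctness
first; at desk scale the refit, not the error, dominates cost, and the
warm start plus an occurrence-position index (two binary searches per
k-mer per segment) keep a pass linear in practice.

## Feature selection

Instances for selection are CpG-site flanks: windows of length l = 100
centered on the CG (truncated, never padded, at amplicon ends), labeled
by their site's status and balanced by down-sampling the majority class.
Features are overlapping k-mer occurrence counts (windows containing N are
skipped); the candidate universe is the k-mers actually observed, not all
4^k strings. Two selectors are provided:

- **Welch t-test**: two-sided, unequal-variance t-test of counts between
  classes per k-mer; keep the top m by p-value (ties lexicographic) or
  all below a threshold. Zero-variance-in-both-classes k-mers get p = 1
  when the means agree and p = 0 when they do not.
- **Random-forest consensus**: k = 30 runs of a 100-tree forest; within
  each run importances are standardized to z-scores across features and
  the top N = 100 with z > 0 are collected; k-mers appearing in ≥ 90% of
  runs survive. Raising the consensus percentage can only shrink the set.

## Cross-validated evaluation

Ten-fold cross validation with the **amplicon** as the fold unit — sites
and segments of one amplicon never straddle the split, so overlapping
sequence cannot leak. Features are selected and coefficients fit on
training folds only. Performance is the rank-based AUC; folds whose test
units are single-class are skipped and counted, not imputed. Three
resolutions share this harness: per-site (flank features), per-promoter
(whole-amplicon features, label + iff more than half the sites are +) and
per-segment. At segment resolution each fold reports two AUCs: the frozen
training model scored on the test amplicons' initial configuration
(`auc_initial`) and on the final configuration found by re-running the
merge search on the test data with the model frozen (`auc_final`).

**A calibration caveat that matters.** The frozen-model test search merges
test segments specifically to reduce (ŷ − t)² against the test labels: it
adaptively redefines the test units toward agreement with the model.
Under a null in which labels are independent of sequence, `auc_final`
therefore sits well above 0.5 (around 0.75 at the default sizes) even
though the model has no predictive power, while `auc_initial` — whose
units are fixed before the model sees them — stays at 0.5. `auc_final` is
how the method reports its end state and is meaningful when compared
against `auc_initial` on the same data; `auc_initial` is the quantity to
use for null calibration, and it is what the acceptance script reports.

## The synthetic generator

The generator emulates amplicon-resequencing methylation summaries with a
known truth. Per amplicon (default 60 amplicons of 1000 bp at CpG density
0.02, i.e. ~20 sites): an i.i.d. background sequence is sampled and
accidental CG dinucleotides removed; one CpG is planted per equal-width
slot so sites are spread out; sites are partitioned into blocks with
1 + Poisson(mean − 1) sites each (default mean 6). Block susceptibility
statuses *alternate* along the amplicon with a random per-cell-type phase:
a block is by definition a maximal run of constant susceptibility, so
adjacent blocks always differ and the planted boundaries are exactly the
block gaps. Copies of planted k-mers (defaults are CG-free 6-mers, one
per cell type) are embedded only in susceptible block spans, about one
copy per 150 bp, never overwriting a site. Each block's susceptibility is
q = logistic(γ₀ + Σ γ_c · count of planted k-mer c in the block span) and
site levels are drawn from Beta(qκ, (1−q)κ) — continuous levels like
bisulfite-derived ratios, with κ (default 20) controlling within-block
noise. Two presets define the study conditions used throughout the tests:
`strong_signal` (γ₀ = −2, γ = +4: q ≈ 0.88 vs 0.12) and `null` (γ = 0,
γ₀ = 0: every q = 0.5, labels independent of sequence).

What the generator does **not** imitate: real base composition or repeat
structure, CpG-island annotations, coverage-dependent noise, spatial
correlation of levels beyond block structure, or trans-acting factors.
Passing tests show the machinery recovers planted sequence-driven block
structure at realistic sizes; they do not certify accuracy on real
bisulfite data.

## Numerical and design choices

- Coordinates are 0-based half-open; a CpG site is addressed by its
  forward-strand C, and minus-strand measurements are mapped to pos − 1
  before joining.
- Predictions are clipped to the open interval (0, 1) at 1e-12 so no
  exact 0/1 is ever returned; the linear predictor is evaluated stably for
  |f| far beyond 1e4.
- Strict inequalities everywhere a label meets its threshold, so ties go
  to −, identically at site and segment level.
- Test problem sizes (fold counts, restart counts of 1–2 in the
  experiment tests, 20–60 amplicons) are the package's own desk-scale
  choices; library defaults stay at N = 10 restarts and δ = 1e-6.
- The parameter-recovery check simulates counts as Poisson(2) with
  coefficients in (−0.5, 0.5) — a well-conditioned design in which the
  logistic information at n = 2000 identifies every coefficient to
  comfortably better than 0.15.

## Known limitations

Only binary merges are searched — no splits, no cross-amplicon segments —
so the climber can be trapped by a bad early merge; restarts mitigate
this. The t-test treats counts per sequence, not per-window frequencies.
Feature selection always uses site-flank instances, also when the model
is later fit on segments. AUC at segment resolution compares units of
unequal size without weighting. None of the experiments here use real
chromosome-21 amplicon data; reproducing published real-data accuracies
is out of scope.
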