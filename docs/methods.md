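# Methods

This note records the statistical conventions the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the known limitations.

## CIS calling by Gaussian kernel convolution

Insertion positions on a chromosome are smoothed with an **unnormalised**
Gaussian kernel, `density(x) = Σᵢ exp(−(x − xᵢ)²/(2σ²))`, so one insert
contributes height 1 at its own position and N coincident inserts height
N.  The kernel is evaluated on a regular grid (step = σ/10, floored at
100 bp — finer grids change called peaks negligibly but cost linearly) and
truncated at ±8σ, where the omitted mass (≤ 1.3 × 10⁻¹⁴ per insert) is far
below the 10⁻⁹-relative agreement the tests demand against the exact
double sum.

**Null and p-values.**  The null hypothesis is uniform placement of the
same number of inserts on the same chromosome.  Each of `n_perm`
permutations records the profile maximum; the raw p of an observed peak of
height h is the add-one estimator `(#{null ≥ h} + 1)/(n_perm + 1)`, which
cannot return zero.  TA-dinucleotide or mappability maps are not modelled;
the uniform null is the explicit, testable default.

**Peaks, footprints, scales.**  Local maxima above the null's (1 − α)
quantile become candidates.  A peak's footprint is the contiguous
half-maximum contour, whose width in kb is the reported CIS width.  The
scan runs a ladder of scales (default 15/30/60/120/240 kb); candidates
whose footprints overlap — transitively, across scales — collapse to the
single candidate with the smallest raw p (ties: larger height, then
smaller scale), which keeps its own footprint so the width stays
interpretable at the winning scale.  N (distinct samples) and I (inserts)
are counted inside the footprint before same-tumour collapsing, which is
why I can exceed N.

**Correction.**  `corrected_p = min(1, raw_p × #candidates on the same
chromosome)` — a per-chromosome Bonferroni over candidate peaks.  Only
peaks with corrected p < α (default 0.05) are reported.  No genome-wide
FWER control is attempted beyond this.

**Monte-Carlo comparison caller.**  Half-overlapping windows scored by
insert count; the window p is the add-one fraction of simulations in which
*any* window reaches the observed count (a family-wise max statistic).  It
exists to cross-check peak rank order, not to replace the GKC scan.

## Contamination filters

*Same-site inserts (SSI)*: a dinucleotide occupied by ≥ 2 distinct samples
is treated as cross-contamination and **all** copies are removed —
independent re-insertion into one TA site is too unlikely to keep either
copy.  Within-sample duplicates at one site are first collapsed to the
highest-read-count record; they are tallied separately
(`duplicates_collapsed`) and the conservation identity
`input = retained + ssi_removed + sti_removed` is stated on the
post-collapse count.  *Same-tumour inserts (STI)*: within a called CIS
footprint each sample keeps one insert (highest read count, leftmost on
ties); overlapping footprints claim sites in order of raw p.

## Mode-of-action inference

A CIS is called *Gain* when ≥ 80 % of stranded inserts share one
orientation and all lie upstream of the assigned gene or within its 5′
quarter (promoter/enhancer activation by the transposon cassette); *Loss*
when inserts spread beyond the 5′ quarter of the body in mixed orientation
(truncation); otherwise *Unknown* — including uniformly-oriented inserts
across the body, which the orientation rule alone cannot classify.  The
80 % threshold and quarter boundary are conventions; they are exposed in
code rather than config because the decision trace, not the label, is the
auditable output.

## Network clustering

The clustering statistic is the mean over CIS genes of the unweighted
shortest-path distance to the nearest other CIS gene.  Edge weights are
ignored for topology.  A CIS gene disconnected from all others contributes
network diameter + 1 — dropping it would bias toward significance.  The
null draws gene sets uniformly from **all** network nodes (a degree-
matched null is available via the same core by supplying a stratified
draw); p uses the add-one estimator with ties counted against the observed
set, so the test is conservative on graphs where the statistic has heavy
atoms.  The calibration suite therefore runs on a 500-node random
recursive tree, whose broad distance distribution keeps the discrete
estimator close to uniform; on dense small-world graphs the same estimator
is visibly conservative, which is a property of tie handling, not an
error.

Fisher tests on 2×2 count tables use exact point-mass summation
(scipy's implementation); hypergeometric term enrichment corrects across
terms by Benjamini–Hochberg step-up.

## Metagene

Gene orientation: sign of the summed Spearman correlation with the other
set members (+1 on an exact zero, with a warning).  Where a gene has
several probes, the probe with the highest mean expression across samples
represents it.  The score is the **mean** (not sum) of signed z-scored
log2 expression, keeping scores comparable across gene-set sizes; genes
with zero variance are skipped.  The orientation rule requires a dominant
orientation in the set: if positive and negative genes nearly balance, the
expected evidence for majority-sign genes cancels and orientations become
unidentifiable — the synthetic generator therefore plants a 5/2 split.

Association battery: one-way fixed-effects ANOVA across subgroups
(samples with unknown labels excluded per test; singleton groups dropped);
metastasis tested by the Welch t reported as-is with a two-sided
label-permutation p (`n_boot` relabelings, add-one corrected); survival by
a median split (ties at the median go to the high group) and the standard
observed-minus-expected log-rank statistic (delegated to lifelines;
verified in tests against an independent O−E/V summation oracle,
exhaustively on small datasets).

## Cross-species projection

NMF minimises squared Frobenius error by multiplicative updates (2000
iterations max, stop when the relative residual improves by < 10⁻⁶; 10
seeded restarts keep the best).  The per-iteration residual trajectory is
retained and asserted non-increasing.  Expression is made nonnegative by
per-gene minimum subtraction.  H rows are reported scaled to unit maximum;
the scaling constants are stored so projected scores stay commensurate
with the training scores.

Projection restricts W to the ortholog rows (many-to-many pairs are
collapsed greedily, most-variable reference probe first — the two probe
sets share no samples, so a correlation-based pairing is not computable)
and solves one nonnegative least-squares problem per target sample.

**A homogeneity caveat found during validation:** per-gene min subtraction
applied to a *homogeneous* target cohort (all samples of one subgroup)
strips the shared signal, because the per-gene minimum then carries it.
`project_metagenes(..., shift_target=False)` projects data already on the
factorisation scale unchanged; raw log2 data from a heterogeneous cohort
should keep the default shift.

Classification: linear one-vs-rest SVM, C = 1 (no tuning protocol is
defined; C is exposed).  Training accuracy is reported alongside
predictions and decision margins.

## Expression statistics

Differential expression uses the pooled-variance Student t, so the df is
nA + nB − 2 for every gene; no multiple-testing correction by default
(BH behind a flag).  2^−ΔΔCt: ΔCt = Ct_target − Ct_reference,
ΔΔCt = ΔCt − ΔCt_calibrator, RQ = 2^−ΔΔCt; the calibrator's RQ is 1 by
construction and RQ is invariant to any global Ct shift.  Preranked GSEA:
hits step the running sum up by |score|^weight (weight 1 default; 0 gives
the classic Kolmogorov–Smirnov form), misses step down by 1/(N − set
size); ES is the extremum.  The null permutes gene labels (random
same-size sets); NES and the nominal p are computed sign-separately.
Sets meeting the ranked list in fewer than 2 genes are skipped.

## Synthetic data: what it emulates, what it does not

`simulate_insertions` plants background inserts uniformly (Poisson count
per sample, chromosome chosen proportional to length) plus CIS spikes with
positions Normal(center, width/4), so ~95 % of spiked inserts fall within
the declared width.  `simulate_expression` builds log2-scale matrices:
baseline 6.0, Gaussian noise sd 1.0, four disjoint marker blocks (+2.0 for
the own-subgroup samples, 40 genes each), and a latent per-sample metagene
N(subgroup shift, 1) loading on 7 network genes (signs 5+/2−, effect 2.0).
Default subgroup proportions 0.14/0.22/0.22/0.42 follow a WNT-light,
Group4-heavy cohort; the latent shifts (0, −0.5, +0.5, +1) put the highest
network activity in Group4 and the lowest in SHH.  Survival is exponential
with log-hazard −0.5 per metagene unit (higher activity protective in the
generator), administratively censored at 15 months, matching an ageing
study horizon; metastasis is Bernoulli with log-odds −1 + 0.5·metagene
(base rate ≈ 0.3).  The co-expression network is a random backbone tree
over all genes plus a chain through the network genes and 2·n_genes decoy
edges.

Not emulated: sequencing reads and splinkerette artefacts, TA-site
placement bias, probe-level microarray noise, copy-number structure, and
competing risks.  Passing tests therefore demonstrate that the *methods*
recover planted structure under clean conditions — not that real screens
meet these assumptions.

## Problem sizes used by the validation suites

The spike-in suite plants 10 CISs (5 samples × 2 inserts, 10 kb wide) on a
45 Mb three-chromosome genome over Poisson-10 background in 20 tumours,
scanning 3 scales with 500 permutations.  Calibration suites use 200
replicates (cluster test and GSEA, 199/99 permutations each) and 500
simulated survival studies of 60 samples.  The cross-species suite uses
300 genes, 108 reference and 30 target samples.  These sizes give stable
pass/fail behaviour across seeds while keeping the whole validation run in
the tens of seconds on one CPU.

## Known limitations

* The GKC null ignores insertion-site sequence preference; hot regions of
  the genome can inflate peak calls on real data.
* The per-chromosome Bonferroni controls error only within chromosomes.
* The cluster test's uniform null is not degree-matched; hub-heavy CIS
  sets will look more clustered than a degree-aware null would report.
* NMF factors are identifiable only up to permutation and scaling; factor-
  to-subgroup assignment is empirical (highest mean score in the subgroup).
* The MOA rule uses orientation and position only; expression evidence is
  not consulted.
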