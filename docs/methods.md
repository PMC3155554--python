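# Methods

## The model

Each tumour sample carries a probe-level copy-number profile on the linear
scale (diploid = 2).  Somatic gains and losses are contiguous; the analysis
reduces them to a per-sample dose code x_ij ∈ {−1, 0, +1} on a common
segment grid and models recurrence hazard as

    h_i(t) = h0(t) · exp( Σ_j β_j x_ij + γ′ z_i )

where z_i are clinical covariates (age ≤ 50, tumour size ≥ 2 cm, nodal
involvement) and, in the "full" model, tumour-subtype indicators.  Dose
coding puts gain and loss of one locus on a single axis, so one coefficient
expresses opposing effects of the two directions (a protective gain shows
HR < 1, the corresponding loss HR > 1).

## Segmentation

*Reduction.*  Running medians over groups of 25 consecutive probes within a
chromosome.  A remainder group shorter than 25 is kept as a short final bin
by default (coverage over uniform bin size); disabling it gives exactly
⌊n/25⌋ bins.

*CBS.*  For a binned chromosome, the candidate split is the arc [i, j)
maximising |mean_in − mean_out| / (s·√(1/k + 1/(n−k))) with s the span's
sample SD and both sides at least `min_seg_bins` = 3 bins.  Significance is
a permutation test: the span's values are shuffled (default 1,000 draws, a
chunked early stop once the α = 0.01 level is unreachable) and the split is
accepted if the permutation p-value of the max-arc statistic falls below α.
Accepted splits are recursed on both (or three) resulting pieces.  No
smoothing or undo step is applied.  Degenerate spans (zero variance, fewer
than 2·min_seg_bins values) never split; a span of b bins cannot reach
significance when its permutation multiplicity is below 1/α, which bounds
usable resolution on very short chromosomes.

*Calling and recombination.*  Segment means call as +1 at ≥ 2.5 and −1 at
≤ 1.5 (boundaries inclusive — the thresholds sit midway to one copy gained
or lost from the diploid 2).  The union of all samples' change-points
partitions each chromosome; adjacent cells whose per-sample call vectors
agree in at least 99.5% of samples are merged by repeated left-to-right
sweeps until a fixpoint.  A merged segment inherits, per sample, the call of
its larger constituent in bins, ties favouring the left.  These order and
tie rules are fixed for determinism; results are independent of the order
in which samples are segmented.

## Marker selection

Componentwise likelihood boosting for the Cox model, Breslow ties.  At each
step every candidate j is scored around the current linear predictor (as an
offset) by its penalized one-step update δ_j = U_j/(I_j + λ); the candidate
maximising the second-order penalized log-likelihood gain U_j²/(I_j + λ) is
updated by δ_j.  Mandatory covariates, when supplied, are refit unpenalized
each step.  After M steps the signature is every candidate with a nonzero
coefficient.  Defaults: M = 100; λ = 9 × number of events, the cited
convention for this family of boosting algorithms.  Both are exposed in
`BoostConfig`; the selection count is sensitive to both knobs.  The partial
likelihood is non-decreasing along the path (each update is a damped Newton
step on a concave one-parameter likelihood).

Standard multivariate fits use lifelines (Efron ties, Newton–Raphson,
observed-information SEs); an internal Breslow engine backs boosting and
model averaging where thousands of small evaluations are needed, and the
two are cross-checked in the tests.  AIC backwards elimination drops the
non-forced covariate whose removal lowers AIC most, stopping when no
removal helps; AIC counts nonzero coefficients.

## Risk groups

With training coefficients β (the boosted values by default — the index is
defined by the selection step's model; refitted coefficients can be
substituted), the risk index is r_i = Σ_j β_j x_ij over the selected
markers.  Samples with no imbalance at any selected marker form the
intermediate "no-CNI" group; carriers split by sign(r).  Exact cancellation
(r = 0 with nonzero doses) goes to no-CNI with a warning, resolving the
ambiguity between "index zero" and "no marker event" in favour of the
latter.  Group hazards come from a Cox fit on high/low indicators against
the no-CNI reference.

## Discrimination

*C-index.*  Harrell's C over usable pairs: the pair contributes when the
earlier time carries an event (time ties count only when exactly one member
is an event; both-event ties are excluded).  Tied risk scores count ½.  The
SE is the binomial counting estimator √(c(1−c)/n_pairs).  Model comparison
bootstraps the evaluation samples (default 200 replicates), recomputes both
models' C per replicate, and applies an unpaired two-sample t-test — a
paired test would be more powerful, but the unpaired construction matches
the two-sample framing this procedure mirrors.

*Time-dependent ROC.*  Cumulative/dynamic estimator with Kaplan–Meier
weighting: with D(t) = 1 when the event occurred by the horizon,
sensitivity(c) = P(X > c | D(t)=1) and specificity(c) = P(X ≤ c | D(t)=0)
are obtained from KM survival within the strata {X > c} and {X ≤ c} via
Bayes' rule.  The naive plug-in can jitter non-monotonically under heavy
censoring, so the curve is monotonized by cumulative maxima before the
trapezoid AUC.  With no censoring before the horizon the estimator equals
the empirical ROC of the binary event-by-t label exactly.

## Bayesian model averaging

Candidate models are subsets of the (post-selection, ≤ 30) markers.  Each is
scored by BIC = −2·logPL + k·log(d) with d the number of events — the
effective sample size for censored data — and weighted by exp(−BIC/2) under
a uniform model prior.  Models whose posterior odds against the best exceed
the Occam's-window ratio (default 20) are discarded and the rest
renormalised; a covariate's posterior effect probability is the summed
posterior of retained models containing it.  Search is exhaustive up to 15
covariates, otherwise a stepwise add/drop neighbourhood expansion from the
null, full and univariate models to a fixpoint within the window.
Interpretation bins: < 50% evidence against, [50, 75) weak, [75, 95)
positive, [95, 99) strong, ≥ 99% very strong — the published rule-of-thumb
text leaves a gap between 50 and 59%, which the contiguous [50, 75) bin
closes.

## Subtypes and frequency tests

HER2 status comes from array ERBB2 copy number with a gain threshold of 2.8,
calibrated by ROC against binarised IHC scoring (0/1+ vs 3+; 2+ excluded);
the suggested threshold maximises Youden's J, ties resolved upward.  HER2
precedes the luminal split so categories stay mutually exclusive; ER+
(≥ 1% staining) tumours split at Ki67 20% into LUM A/B; ER−/PR− is TNBC;
ER−/PR+/HER2−, or a missing Ki67 where it is needed, is unclassified.

Recurrent imbalances are segments gained or lost in at least 10% of a group
(boundary inclusive).  Subtype association per segment tests the dose
category × subtype table: chi-square generally, Fisher's exact when the
collapsed table is 2×2 with an expected cell below 5 (the test choice is
fixed per segment from the observed table and reused across permutations,
whose margins it shares).  The FDR is the permutation plug-in: labels are
shuffled B times (default 1,000; ≥ 100 enforced), FDR(t) = mean null count
of p ≤ t over the observed count, evaluated at each observed p and
monotonized so tightening the threshold never raises the estimate.
Benjamini–Hochberg is deliberately not used — the permutation null respects
the dependence between segments.

## Synthetic cohorts

The generator emulates a MIP-array cohort at desk scale: a default genome of
4 chromosomes × 2,500 evenly spaced probes (the full-size layout is a
config away), a diploid baseline with additive Gaussian probe noise
(sd 0.15; a Student-t option mimics heavier-tailed FFPE noise), and twelve
planted contiguous events of one copy whose carrier frequencies depend on
subtype.  Subtypes are drawn first, at the reference cohort's classified
proportions (LUM A/LUM B/HER2/TNBC = 389:156:158:184); marker panels
(ER/PR/Ki67/ERBB2 CN) are then generated consistent with the assigned
subtype so the subtype rules round-trip.  Clinical covariates follow the
published descriptive distributions (age ≈ N(54.4, 12.6²); size ≥ 2 cm and
node-positive rates ≈ 0.39/0.40).  Recurrence times are inverse-transform
draws from an exponential (or Weibull) baseline with log hazard linear in
event doses plus clinical terms; censoring is an administrative horizon of
240 months plus uniform dropout with probability 0.2, calibrated together
with the baseline scale (500 months) to an observed event fraction near
30%, the reference training set's rate.  The marker-level generator skips
the probe layer: 150 candidate segments, carriers at frequency 0.30, six
prognostic with |β| = 0.7, 0.7, 0.65, 0.6, 0.5, 0.4 — the upper half of the
planted-effect band, mirroring the magnitude spectrum of the reported
selected markers; markers much below |β| ≈ 0.4 sit under the maximum noise
score of ~144 null candidates at this sample size and are not recoverable
by any selector.  A single seed feeds named per-stage streams
(subtype/events/noise/clinical/survival/censoring) via
`SeedSequence.spawn`, so each stage reproduces independently.

What the generator does not emulate: probe-specific GC/affinity bias,
tumour purity and ploidy mixtures, germline CNV polymorphism, batch
effects, or within-event magnitude heterogeneity.  Passing recovery tests
therefore show the algorithms are correct under the stated statistical
structure, not that real FFPE data meet that structure.

## Experiment scales and numerical choices

The bundled experiments run at sizes chosen so the whole suite completes on
one CPU in minutes: segmentation recovery on 60 samples × 10,000 probes;
selection recovery with 10 generator seeds at the training size 728; the
discrimination ordering on one signal cohort of 800 (75/25 split) and, for
the chance level, the mean test C over three signal-free cohorts of 600
with a 50/50 split — a single quarter split estimates C with an SD near
0.05, too coarse to locate 0.5 within ±0.05, and averaging narrows the SE
below 0.02 without changing the estimand.  Newton iterations stop at
gradient norm 1e−8; monotone-likelihood trajectories are capped at |β| = 50
with a warning; permutation p-values use the add-one estimator
(1 + exceedances)/(B + 1).

## Known limitations

- CBS here implements the core recursive arc test only (no hybrid p-value
  approximation, undo, or smoothing); on very long chromosomes the exact
  permutation loop is the runtime bottleneck.
- The per-direction hazard ratios printed for a dose-coded marker are
  exp(β) for gains and exp(−β) for losses of the same segment; both views
  are reported because a single coefficient underlies them.
- The bootstrap C-index comparison is unpaired by construction and
  conservative for highly correlated models.
- Risk-group fractions depend on the planted event frequencies and are not
  calibrated to match any particular cohort's group sizes.
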