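# Methods

This note documents the statistical procedures `transcpm` implements, the
assumptions of its synthetic cohort generator, the numerical choices made
where the conventional descriptions of these methods leave freedom, and
what the package's tests do and do not establish about real data.

## Data model

A cohort is a `TaskConnectomeSet` — subjects × tasks × edges, where the
edge axis is the strict upper triangle of the symmetric node-by-node
Fisher-z connectivity matrix, row-major, 0-based internally (1-based in
files and reports).  n nodes give n(n−1)/2 edges.  A `PhenotypeTable`
carries diagnostic group, motion summaries (mean frame-to-frame
displacement, mm) and behavioral measures; a `NetworkMap` assigns each node
to one of ten canonical functional networks (medial frontal,
frontoparietal, default mode, motor, visual A/B, visual association,
salience, subcortical, cerebellum).

Motion QC excludes a subject when grand-mean displacement exceeds 0.15 mm
across tasks or any single task exceeds 0.20 mm.  Comparisons are strict
(`>`): a subject exactly at a limit is retained.  Missing motion excludes
the subject (conservative; no imputation).

## Connectomes

`compute_fc` correlates all node pairs, clips |r| at 1 − 1e−7 (atanh is
unbounded at ±1 and duplicate nodes do occur in degenerate inputs), applies
atanh, zeroes the diagonal.  Zero-variance nodes get zero edges and a
warning rather than an error, so one flat region does not abort a batch.
`general_fc` z-scores each run per node before concatenating frames —
without standardization, runs with larger amplitude would dominate the
pooled correlation; the task-evoked signal is deliberately not removed.

## Latent phenotypes

Constructs are the first principal component of the z-scored training
measures (correlation-matrix PCA; covariance would let an instrument's
scale set its weight).  The loading sign is fixed so the loading sum is
non-negative — PCA is sign-ambiguous, and with positively scored
instruments this makes higher scores mean better performance.  Centering,
scaling and loadings are training statistics only; test subjects are
projected, never re-fit.  One component is the default ("one construct
score per subject"); more are available for sweeps.

## Ridge CPM

Edge selection tests each task/edge correlation with the phenotype at
two-sided P < alpha (default 0.01), pooling both signs into one mask.
Two-sided is the coherent choice when both signs are kept.  With motion
supplied, edge and phenotype are residualized on motion and the residuals
correlated (partial correlation, df = n − 3; df = n − 2 otherwise);
p-values come from t = r·sqrt(df/(1−r²)).  Internally selection compares
|r| against the critical value implied by alpha — algebraically identical
to p < alpha and much cheaper over 2×10⁵ features.  Zero-variance edges are
never selected, without error.

The ridge model pools selected features from all tasks (task connectomes
are strongly dependent; one joint penalized fit handles this), z-scored by
training statistics, intercept = training mean (unpenalized).  λ minimizes
inner 5-fold CV mean squared error over a log-spaced grid (10⁻³…10³, 13
points by default; smallest λ wins ties).  Coefficients for the whole grid
come from one SVD per inner fold: β(λ) = V·diag(s/(s²+λ))·Uᵀy.  A fold
with zero selected edges yields a flagged null model predicting the
training mean rather than an exception, so a single degenerate fold cannot
abort a 1000-division run.

## Validation

**10-fold.**  Folds are random, sizes differing by at most one, drawn
regardless of group.  Everything — construct PCA, selection, ridge — is
re-fit within each training fold.  Out-of-fold predictions pooled over the
10 folds give one q² per division; the median over divisions is the
headline statistic (1000 divisions at study scale; tests use 25–50).
Negative q² is reported as-is with √q² flagged undefined (NaN), not
clamped.

**Behavior permutation.**  Measure rows are shuffled against connectomes
(motion stays with the connectomes — it is an imaging-side variable) and
the entire pipeline re-run.  p = (#{null > observed} + 1)/(n_perm + 1),
one-tailed.  The compared statistic is the per-run median q² rather than
√q²: the root is undefined for negative q² (the typical null outcome),
and q² is a strictly monotone transform of √q² wherever the root exists,
so the count — and therefore p — is unchanged where both are defined and
well-defined everywhere.

**Leave-one-group-out.**  One exhaustive split per diagnostic group; no
iteration (the possibilities are exhausted).  Performance is Pearson r in
the left-out group — predictions there are not pooled across folds, so q²
against the group's own mean would conflate calibration with association.

**Group permutation.**  Group labels are permuted preserving group sizes,
leave-group-out re-run per permutation.  Observed r above the 97.5th /
below the 2.5th percentile of a group's null suggests the true label
detracts from / contributes to prediction.  Empirical two-sided p-values
are BH-FDR corrected across groups at 0.001, and the reported
classification requires both the band excursion and FDR significance; the
band-only classification is also exposed.  Note the arithmetic: with B
permutations the smallest empirical p is 1/(B+1), so at the default
B = 200 the 0.001 FDR gate cannot pass — the corrected classification is
then "uninformative" by construction, which is the intended reading of a
correction that strict at that permutation count.  Users wanting band-only
inference should read `band_classification`.

**Selection consistency.**  An edge is consistently selected when it
appears (in any task, any fold) in at least 95% of divisions; a node's
consistency degree counts its consistent incident edges, so degrees sum to
twice the consistent-edge count.  The threshold comparison is inclusive
(≥): 94 of 100 fails at 0.95, 95 passes.

**External validation.**  Each dataset fits its own "general memory"
construct by PCA over *all* of its subjects (the two datasets need not
share instruments), each subject gets one combined connectome (general
functional connectivity from concatenated time courses, or the task-mean
edge vector when cohorts are generated directly at the edge level), the
model trains on the full training dataset and is scored by Pearson r on
the other.  Both directions are supported; the datasets must share the
node atlas.

## Mass multivariate analysis

Per edge, the m-task response vector is tested against the group factor.
The omnibus statistic is Wilks' Λ with Rao's F approximation (Pillai's
trace available); with one task it reduces exactly to the one-way ANOVA F,
which the tests assert to 1e−10.  Pairwise contrasts use two-sample
Hotelling's T² with its exact F transform.  All statistics are computed
batched from per-edge scatter matrices (einsum + batched slogdet/solve),
which is what makes a 35 778-edge analysis take seconds; `statsmodels`'
MANOVA serves as the per-edge oracle in tests, never the implementation.
Edges with singular within-group scatter are flagged and assigned p = 1
rather than a spurious statistic.  Significance is BH-FDR across all
tested edges at q = 0.05.  Node scores sum F over significant incident
edges; network cells sum F by endpoint-network pair.

## Interpretation

Wₙ sums B(k,m)·βₘᵏ·std(Eₖ(:,m)) over the edges incident to node n and all
tasks — each selected edge credits both endpoints.  Contributions are
signed by default (the weight's direction is information); a magnitude
option exists for display.  Wₘ uses |β|·std so task proportions are
non-negative and sum to 1; a signed variant is available behind a flag.
Network profiles are arithmetic means of Wₙ over member nodes.

Edge-set enrichment per network cell uses the hypergeometric right tail
p = P(X > x) for X ~ Hypergeom(M, K, n) — the "1 − cdf(x)" convention,
evaluated through scipy's log-gamma-based survival function.  Because this
tail excludes the observed count it is anti-conservative for small cells
and discrete; the calibration test therefore compares the empirical
rejection rate against the exact null rate of the statistic, not against
uniformity.  The "cumulative likelihood" 1 − p exists only for stacked
profile displays and is labeled non-inferential.

## Synthetic cohorts

The generator plants exactly the structure the pipeline assumes, with a
ground-truth record:

* latent trait mᵢ ~ N(0,1); behavioral measures xᵢⱼ = λⱼmᵢ + εᵢⱼ in three
  construct families (working 0.9/0.8/0.7; short 0.85/0.75; long
  0.9/0.8/0.7; noise SD 0.5) — realistic instrument reliabilities with
  enough measures per family to exercise construct-level PCA;
* edges eᵢₜₖ = μₖ + b·profileₜ·mᵢ·1[k∈signal] + δ_g·1[k∈group] +
  c·motionᵢ + noise, with baseline μₖ ~ N(0.25, 0.25²) and noise SD 0.15
  (typical Fisher-z magnitudes), 150 signal edges at planted edge–trait
  correlation 0.35 (b = σ·r/√(1−r²)), and 50 group-difference edges with
  shifts of about one noise SD — disjoint from the signal set by default
  so that "the predictive network" and "the group-difference network" are
  distinct by construction and recovery tests are unambiguous;
* motion |N(0.08 mm, 0.03 mm)|, so a realistic few percent of subjects
  fail QC; optional trait correlation via a Gaussian copula and optional
  leakage into every edge (both 0 by default; confound scenarios set
  them);
* default composition 75/30/35/32 = 172 subjects in four diagnostic
  groups, six tasks, 268 nodes (tests use fewer nodes; see below).

Two cohorts generated with the same explicit planted-edge indices share
the underlying predictive network — the cross-dataset setting.

`generate_timeseries` produces frames × nodes series where a planted
pair's two nodes share a common signal with mixing weight
base + gain·profileₜ·mᵢ (floored at 0), so planted functional connectivity
increases with the trait; it requires ≥ 50 frames because shorter series
make correlation estimates too unstable to test against.

What the generator does *not* emulate: autocorrelated BOLD dynamics,
task-evoked structure, spatially structured noise, edge-edge dependence
beyond the planted factor, scanner/site effects, non-Gaussian behavioral
distributions, and image-level motion artifacts.  Passing recovery tests
therefore show the estimator chain is correct and calibrated under its own
assumptions — not that real fMRI cohorts will yield similar effect sizes.

## Problem sizes and numerical tolerances

Desk-scale runs use 30–64 nodes and 2–6 tasks so the whole suite completes
on one CPU: calibration uses a 60-subject, 30-node, 2-task null cohort
(100 replicates × 100 permutations), MMA uniformity a 400-subject, 64-node
(2016-edge) null, and recovery/transdiagnostic checks the full 172-subject
composition at 60 nodes (1770 edges × 6 tasks) with 50 fold divisions and
10 seeds.  The 268-node edge arithmetic (35 778 / 214 668) is exact and
checked directly.  Oracles: ridge vs closed-form solve at 1e−8, MANOVA vs
ANOVA and T² vs pooled t² at 1e−10, hypergeometric vs exhaustive
enumeration for all populations M ≤ 25 at 1e−12, round trips at 1e−12.

## Known limitations

* The omnibus MMA F uses Rao's approximation; it is exact for m ≤ 2 or
  g ≤ 3 and approximate otherwise (the null-uniformity test bounds the
  practical error).
* Partial-correlation motion control removes linear motion effects only.
* The group-permutation FDR gate at 0.001 is unattainable below 999
  permutations (see above) — a faithful implementation of a strict
  correction, exposed alongside the uncorrected band classification.
* `run_experiment` simulates its external cohort with the same generator
  family; heterogeneous-acquisition effects (different tasks, scanners,
  measure batteries) are represented only by independent baselines and
  noise draws, plus dataset-specific PCA.
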