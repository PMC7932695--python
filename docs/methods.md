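# Methods

## The statistical problem

Functional annotations (GO terms, phenotypes, localization screens) attach to
whole proteins, but the sequence elements that carry many of those functions
are individual intrinsically disordered regions (IDRs), and most proteins
contain more than one predicted IDR. `faidr` treats this as a
multiple-instance learning problem: each protein is a bag of IDR instances,
the bag carries a binary label Y, and a hidden indicator X_ij marks which IDR
j of protein i is responsible for the label.

Each IDR carries a molecular-feature vector Z_ij — either evolutionary
signatures (Z-scores of the mean and log variance of sequence-distributed
features across orthologous IDRs, against a simulated null of IDR evolution)
or single-sequence features standardized to zero mean and unit variance.  The
per-IDR model is logistic,

    P(Y_i = 1 | Z_ij, b) = h(Z_ij) = 1 / (1 + exp(-(Z_ij . b + b0))),

and marginalizing the hidden indicator with a uniform prior P(X_ij = 1) = 1/r_i
over the r_i IDRs of protein i gives the likelihood

    P(Y | Z, b) = prod_i sum_j (1/r_i) h(Z_ij)^{Y_i} (1 - h(Z_ij))^{1 - Y_i}.

## Fitting by EM with a penalized, truncated-IRLS M-step

The E-step computes responsibilities by Bayes' rule,

    <X_ij> = [Y_i h_ij + (1 - Y_i)(1 - h_ij)] / sum_k [Y_i h_ik + (1 - Y_i)(1 - h_ik)],

initialized uniformly at 1/r_i.  The M-step maximizes the expected complete
log-likelihood — a logistic regression over IDR rows in which each row
carries its protein's label with weight <X_ij> — under an elastic-net
penalty.  It runs a fixed number of IRLS iterations (5 by default); each
iteration solves the penalized weighted least-squares subproblem exactly by
cyclic coordinate descent with an active-set strategy, using the modified
IRLS weights

    w_ij = <X_ij> h_ij (1 - h_ij),

floored at `weight_floor` (1e-8) when they reach zero.  M-steps are
warm-started from the previous round's coefficients.  EM stops when the
largest absolute change in any responsibility falls below `em_tolerance`
(1e-4) or after `max_em_iterations` (100) rounds.

### Penalty normalization

The penalty is glmnet-like — lambda * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2),
intercept unpenalized, defaults lambda = 0.2 and alpha = 0.99 (the small
ridge admixture stabilizes IRLS when positives are scarce relative to the
number of features).  The quadratic subproblem is normalized by the fixed
constant

    W0 = (1/4) * sum_ij v_ij

where v are the observation weights (the responsibilities during EM): W0 is
the value the IRLS weight total takes at h = 1/2, so lambda is on the scale
of a weighted LASSO on the IRLS working response.  Two properties motivated
this choice over per-iteration renormalization by the current weight total:

* it reproduces the same coordinate-entry threshold at the b = 0 starting
  point, so lambda = 0.2 selects features at the intended strength; and
* W0 is constant across IRLS iterations and EM rounds, making each M-step a
  fixed convex problem.  Consequently EM provably ascends the penalized
  marginal log-likelihood — defined as the marginal log-likelihood minus
  (n_proteins / 4) * lambda * penalty(b) — whenever the M-step is run to
  inner convergence.  This quantity is recorded in `objective_trace`.  (An
  adaptive variant that renormalizes by the current weight total was
  evaluated; it changed held-out performance negligibly but sacrificed the
  monotone trace, so the fixed normalization is used.)

With the default five truncated IRLS iterations the per-round ascent is not
guaranteed but the trace improves from start to finish in practice; with one
IDR per protein the EM collapses exactly to a single penalized weighted
logistic fit.

Inputs are assumed pre-standardized (evolutionary signatures are Z-scores;
single-species features are scaled before fitting with `zscore_columns`); no
internal re-standardization is applied, to avoid double-scaling Z-scores.
A fit with fewer than `min_positives` (5) positive proteins is refused.

## Prediction

* Per IDR: h(Z_ij) under the fitted coefficients.
* Per protein: for unseen proteins the label-conditional posterior over the
  responsible IDR is unavailable, so P(X_ij = 1) = 1/r_i and the protein
  score is the simple average (1/r_i) sum_j h(Z_ij) — a convex combination of
  the per-IDR probabilities.

## Evaluation protocols

* **Protein level**: fivefold cross-validation, randomly partitioning
  proteins (never splitting a protein's IDRs across folds), scoring held-out
  proteins with the uniform average and reporting per-fold and mean AUC.
  Fold assignment is unstratified by default (an optional stratified mode
  avoids degenerate folds for rare annotations).
* **IDR level**: train on protein-level labels for 80% of proteins; score
  each IDR of the held-out 20% with the per-IDR probability and evaluate
  against independent IDR-resolved ground truth (e.g. phosphosites or
  targeting-signal coordinates mapped into IDR intervals: an IDR is positive
  iff it contains at least one site, strict 1-based inclusive containment).
  The number of positive held-out IDRs (Np) is reported with the ROC.
* AUC is the rank-based (Mann-Whitney) statistic with midrank tie handling;
  ROC curves sweep thresholds over the distinct scores in descending order
  and integrate by trapezoid.  The two agree to numerical precision.

## Feature-function associations

For each function, the features with nonzero penalized coefficients are
refit by unpenalized logistic regression and summarized by Wald t-statistics
(coefficient / standard error from the weighted Fisher information);
unselected features are assigned t = 0 exactly.  For multi-IDR proteins the
refit rows are the per-IDR rows weighted by their final responsibilities
(consistent with the model's soft assignment); a max-responsibility-IDR
alternative is available via `mode="max_idr"`.  Quasi-separation (detected by
non-convergence, runaway coefficients, or a collapsed deviance) is reported
as sign(coefficient) * 50 with a warning flag rather than a meaningless Wald
value.

The function x feature matrix is filtered to features with at least one
t-statistic at or above a threshold (3 by default).  The filter compares the
signed maximum by default — matching the literal "3 or greater" rule — with
an absolute-value mode available that also retains strong negative
associations; both choices are logged.  The filtered matrix is clustered
agglomeratively under uncentered correlation distance,
d(x, y) = 1 - (x . y)/(||x|| ||y||) (identical to cosine distance), with
average linkage, and written as a CDT-like clustered text table.  Cluster
3.0's optional "calculate weights" scheme (cutoff 0.1, exponent 1) is not
reproduced; plain average linkage is used.  Linkage tie-breaking follows the
deterministic order of the underlying linkage implementation, so repeated
runs give identical leaf orderings.

## Sequence features

The single-sequence calculators cover the feature families that recur in
disordered-region analysis:

* **Isoelectric point** — bisection on the Henderson-Hasselbalch net charge
  over pH in [0, 14] (tolerance 0.005), counting D/E/C/Y side chains and the
  free C-terminus as acidic and H/K/R and the free N-terminus as basic.  Net
  charge is strictly decreasing in pH, so the root is unique.  The default
  pKa set is the DTASelect table (Nterm 8.0, Cterm 3.1, C 8.5, D 4.4, E 4.4,
  H 6.5, K 10.0, R 12.0, Y 10.0), chosen because it reproduces the published
  pI values of all four Cox15 IDR variants within 0.15 (the wild-type value
  to the printed precision); Bjellqvist/ExPASy and EMBOSS tables are
  available via `pka_table`, and the table in use is part of the call
  signature rather than hidden state.
* **Hydropathy** — arithmetic mean of the Kyte-Doolittle scale; any
  per-residue scale covering the 20 canonical amino acids can be supplied.
* **Compositions** — single-residue and residue-class fractions.
* **Motif and repeat counts** — non-overlapping left-to-right scans of
  consensus patterns written as dash-separated positions with `/`
  alternatives and `x` wildcards (e.g. `S/T-P`), or literal substrings.
* **Z-score utilities** — column standardization and signature Z-scores use
  the sample (n-1) variance.

The default catalog registers 82 named features (length, 20 residue
fractions, 7 class fractions, mean hydropathy, mean net charge, pI, 20
doublet-repeat counts and 31 consensus-motif counts); an evolutionary
signature built from it therefore has 164 columns — a mean and a log
variance (floored at 1e-12 before the log) per feature across an ortholog
set, Z-scored against profiles of simulated null sets.  The registry is
data-driven, so users can supply their own catalog.

DNA translation uses the standard code; sequences must be multiples of three
over A/C/G/T, a single terminal stop is stripped, and an internal stop is an
error distinct from length and alphabet errors.

## Synthetic data generator

The generator draws data from exactly the structure the model assumes: per
protein, r_i ~ uniform on {1, 2, 3, 4}; feature vectors i.i.d. standard
normal (mimicking Z-scored signatures; an exchangeable-correlation option
stresses the LASSO with collinear features); a responsible IDR j* uniform on
1..r_i; and Y_i ~ Bernoulli(h(Z_ij*)) with a sparse true coefficient vector
(10 nonzero entries of magnitude 2 with random signs) and intercept -1.
The true coefficients depend only on the seed, while a `data_offset`
redraws features and labels from the same model, giving honest held-out
evaluations against ground truth.  All draws flow from one root generator,
so datasets are bit-reproducible from the seed.

What the generator does **not** emulate: correlated annotation columns,
feature correlation structure of real signatures (unless enabled), uncertain
IDR boundaries, and label noise beyond the Bernoulli sampling.  Passing
recovery tests therefore demonstrates correctness of the inference machinery
under the model's own assumptions, not performance on proteome data.

Two quantitative ceilings of these study conditions are worth knowing.
First, identification of the responsible IDR among multi-IDR positives is
limited even with the true parameters: the linear predictor is strongly
saturated (sd ~ 6.3), so several IDRs of a positive protein often have
probabilities near one and the posterior over the responsible one is nearly
flat among them; Bayes-optimal top-1 accuracy is about 0.63 at the default
settings, and the fitted model reaches about 0.59.  Second, the
uniform-average protein score dilutes the responsible IDR's signal with up
to three unrelated IDRs: with the true parameters it attains AUC of about
0.84-0.87 across seeds, and the fitted lambda = 0.2 model about 0.80 —
comparable to published cross-validation performance of this model class on
real proteome annotations.

## Numerical choices

* Linear predictors are clipped at +/-700 before exponentiation; probability
  terms entering logs are clamped at 1e-12.
* Coordinate descent iterates to a coefficient-change tolerance of 1e-9
  (at most 1000 sweeps), alternating full and active-set sweeps.
* IRLS runs exactly the configured number of iterations — no early stopping —
  so iteration schedules compose exactly (two k-iteration calls with a warm
  start equal one 2k-iteration call).
* The E-step denominator is mathematically positive; an assertion guards it.
* Problem sizes in the test-suite experiments (n = 120-2000 proteins,
  m = 15-164 features) were chosen so each experiment is a direct, fully
  reproducible instantiation of the generator's default study conditions or
  a scaled-down version with the same structure.

## Known limitations

* lambda is fixed (0.2), not selected along a path; informative priors over
  the responsible IDR are not supported.
* The responsibility-weighted refit for t-statistics is a modeling choice;
  where responsibilities are diffuse, its standard errors are optimistic
  relative to a design with one row per protein.
* The uniform-average protein score is the correct marginal prediction under
  the model but is conservative when only one IDR carries the function (see
  ceilings above).
* pI values are pKa-table dependent at the 0.1-0.5 level; comparisons across
  studies should fix the table.
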