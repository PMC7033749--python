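# Methods

## The model

`mlmirt` works with two-level mixture two-parameter logistic (2PL) item
response models for dichotomous responses of persons nested in clusters
(students in schools, patients in clinics).  Person *j* in cluster *k* belongs
to a within-level latent class *g* ∈ {1..G} and carries a within-level ability
θ_jkg ~ N(0, σ_g²); cluster *k* belongs to a between-level latent class
*b* ∈ {1..B} and carries a between-level ability θ_k ~ N(μ_b, τ²).  The
response probability for item *i* is

    logit P(Y_jki = 1) = a_ig·θ_jkg + b_i·θ_k − β_ig ,

with class-specific within-level discriminations a_ig and thresholds β_ig and
class-invariant between-level discriminations b_i.  A model with *m* between
and *n* within classes is labeled CBmCn.

The between-level class structure is parameterized as: class *b* shifts the
between-ability mean (μ_1 ≡ 0 as anchor) and sets the conditional within-class
mixing proportions π_{g|b}.  The marginal within-class proportions are
π_g = Σ_b P(b)·π_{g|b}.  The between discriminations are held class-invariant,
exactly as the response function above is written; nothing in the model
definition makes them class-specific.

## Estimation

`fit()` maximizes the marginal likelihood (both abilities integrated out, both
discrete classes summed out) with a plain EM algorithm.  Design choices that
matter:

- **Discretized likelihood with a fixed grid.**  The within ability is
  integrated with Gauss–Hermite quadrature (15 nodes by default).  The between
  ability is replaced by a *fixed* grid that never moves with the parameters:
  plain Gauss–Hermite when B = 1, and for B > 1 a uniform grid over
  ±(3.5τ + 2) with the class means entering through normalized discrete node
  probabilities p_t(b) ∝ exp(−(x_t − μ_b)²/2τ²).  Because the grid is fixed,
  the discretized marginal likelihood is a fixed, smooth function of the
  parameters and the EM ascent property is exact — the observed-data
  log-likelihood never decreases across iterations.  A 7-node between rule
  (the natural first choice) proved far too coarse for this scheme — the node
  spacing exceeded τ and visibly distorted the between-level estimates — so
  the estimator defaults to 21 between nodes (spacing ≈ 0.55τ); 15 nodes is an
  acceptable economy setting, and one-off likelihood evaluations through
  `cluster_marginal_likelihood` default to mean-centered Gauss–Hermite nodes
  instead, which is more accurate per node for a single evaluation.
- **M-step.**  Item parameters: per-item weighted logistic-regression Newton
  updates on posterior-weighted quadrature cells, with step halving so the EM
  Q-function (and therefore the log-likelihood) can only increase.  Mixing
  proportions and between-class probabilities: closed form, floored at 1e-4 to
  prevent silent class collapse (floor events are logged).  Non-anchor between
  means: one-dimensional concave Newton on the discrete-grid Q-term.
- **Identification.**  σ_g² = τ² = 1 and μ_1 = 0 fixed; discriminations free.
  The ability scales are absorbed by the discriminations and the between
  location by the thresholds, so these constraints cost no likelihood.
- **Starting values.**  The first start perturbs a one-class 2PL base fit
  (class-specific N(0, 0.5²) threshold noise); remaining starts are fully
  random.  Mixture likelihoods are multimodal; the informed start finds the
  dominant basin in well-behaved designs, and restarts (`n_starts`, default 5)
  guard the rest.  The best restart is returned, with all restart
  log-likelihoods reported.
- **Convergence.**  Relative log-likelihood change < 1e-5 *and* absolute
  change < 0.01 (`rel_tol`, `abs_tol`), at most 500 iterations.  The relative
  criterion alone declares convergence while the log-likelihood of a
  5000-person fit still climbs ~0.3 per iteration, which is too loose for
  information-criterion comparisons; the absolute cap fixes that.
  Non-convergence is reported in the result, never raised.
- **Parameter count.**  d = 2GI + I + (B−1) + B(G−1) + (B−1): thresholds and
  within discriminations per class, between discriminations, and the free
  mixture probabilities and means net of the anchors.  Fixed variances are not
  counted.

Only point estimates are produced.  Standard errors (robust/sandwich or
otherwise) are out of scope: the quantities this package studies —
log-likelihoods, parameter counts, posteriors, recovery error — do not depend
on how standard errors would be computed.

## Label switching and scale placement

Mixture class labels are arbitrary, so before computing recovery statistics
`align_labels` (a) picks the within-class permutation (exhaustive over G!)
minimizing the summed squared threshold difference to the generating
parameters, (b) orders between classes by ascending mean, and (c) places the
estimates onto the generating scale: the between-ability location is only
identified up to convention, so the shift c minimizing
Σ (β̂_gi − b_i·c − β_gi)² is absorbed into the thresholds through the between
discriminations and subtracted from the between means.  Step (c) is an exact
reparameterization (the likelihood is unchanged) and corresponds to the usual
mean-shift linking onto the generating metric; without it, recovery error
conflates threshold misestimation with the arbitrary between-location
convention.

## Classification

Each person's posterior class probability is computed two ways: the proper
marginal posterior from the final E-step (`FitResult.posterior_within`), and
the plug-in formula P_jkg ∝ π̂_g Π_i P^y (1−P)^{1−y} evaluated at predicted
ability scores (`posterior_within_probs`), with EAP (posterior-mean) abilities
as the predicted scores.  The study pipeline uses the plug-in variant for
classification accuracy, assigning each person to the highest-posterior class
(ties to the lowest index).  The normalizing denominator carries a single π̂_g
per class, so rows sum to one.

## Model selection

AIC = −2logL + 2d, BIC = −2logL + d·ln N, CAIC = −2logL + d·(ln N + 1),
SABIC = −2logL + d·ln((N+2)/24), natural logs, N = number of examinees
(level-1 units, never the cluster count; a cluster-level N variant is
deliberately not wired into the pipeline).  Smaller is better; ties break
toward smaller d, then lexicographic label.

## The synthetic world

The generator reproduces the study's factorial design: 10/30/50 items, equal
(0.5/0.5) vs unequal (0.75/0.25) mixing, 30/60/90% class-variant items, 50/100
clusters, cluster sizes 10/50 — 72 cells, generated from CB2C2.  Values the
design leaves unstated were fixed once:

- Class-1 thresholds: N(0, 1) draws; a CSV loader accepts a user-supplied
  table (e.g., thresholds calibrated from real data) in its place.  The harness draws one
  threshold set per test length so conditions sharing a test length share
  items, as a single empirical pool would.
- Class difference δ = 1 logit on the variant items, alternating sign — a
  mid-range uniform-DIF magnitude in the mixture-IRT simulation literature.
- Discriminations 1 at both levels (Rasch-like baseline, conditions stay
  comparable across factors).
- Between structure: B = 2 with P(b) = (0.5, 0.5), means (0, 1), and
  conditional mixing rows tilted ±0.2 around the target marginal so the
  between classes differ in composition as well as in mean.
- Dataset seed for replication r of condition c: base + 10000·c + r.

The acceptance checks of model selection use a deliberately stronger
separation (δ = 1.5, means (0, 2), tilt 0.3), standing in for an empirical
calibration with strongly separated classes — the regime in which the BIC
family is expected to detect CB2C2 nearly always at the larger level-1 sizes.
These stand-ins were fixed before any selection run was scored.

What the generator does **not** emulate: the empirical threshold pattern
itself, varying discriminations, guessing behavior, missing responses, or
polytomous items.  A green recovery or selection test therefore establishes
that the estimator recovers *this* stated world at desk scale — not that any
particular empirical calibration is reproduced.

## Numerical notes

- All likelihood accumulation is in log space (log-sum-exp); 50-item response
  patterns underflow raw probability space.
- Items answered identically by everyone (all-0/all-1 columns) trigger a
  warning and have their thresholds bounded at ±8 logits.
- Posterior rows are normalized to sum to 1 within 1e-8 or better.
- `threshold_rmse` averages per-(class, item) RMSE over classes and items;
  a variant-items-only restriction is available.  Replications whose fit did
  not converge are excluded by the harness and counted separately.
- Study runs are a pure function of the configuration, including under
  condition-level joblib parallelism (conditions share no state).

## Known limitations

- EM convergence near degenerate optima (a class chasing a handful of
  response patterns in small samples, discriminations drifting large) is slow;
  small-sample cells (50 clusters of 10) frequently hit the iteration cap.
  These are also the cells where recovery is intrinsically hardest.
- The fixed between grid trades per-node accuracy for exact monotonicity;
  between-level means and discriminations carry a discretization bias that
  shrinks with `quad_between`.
- Between-level classification accuracy is computed but the study pipeline
  reports within-level (examinee) accuracy only, matching the source tables.
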