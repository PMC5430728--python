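# Methods

## Model

The observed tensor **O** (I patients × J diagnoses × K prescriptions) holds
admission-level co-occurrence counts: entry (i, j, k) is the product of the
within-admission counts of diagnosis j and prescription k in patient i's used
admission.  The product rule is the only simple counting rule consistent with
both canonical cases — one diagnosis with one drug order co-occurs once, one
diagnosis with two orders of the same drug co-occurs twice — and it extends
multiplicatively if a diagnosis is itself coded more than once.  By default a
patient contributes their chronologically first admission
(`admission_policy="first"`, matching the convention of using the first
admission of surviving patients); `"last"` and `"sum"` (accumulate every
admission) are available, the latter being what makes the synthetic
generator's event emission exactly invertible.

Preprocessing keeps diagnosis codes charted for ≥ 5% of distinct patients and
prescriptions for ≥ 10%, drops ICD-9 "V"/"E" supplementary codes and
configurable base-fluid prescriptions, and caps counts at 10 (or at the
empirical top-1% value with `cap="p99"`) so frequently re-dosed small-dose
drugs cannot dominate the fit.

The constrained CP objective combines three ingredients, solved by
block-alternating projected Newton steps:

* **Data fit.**  Per patient row, ‖A_i:(C⊙B)ᵀ − O_(1)i:‖²; per code factor,
  ‖B(C⊙A)ᵀ − O_(2)‖² (⊙ = Khatri–Rao).  Unfoldings use the column-ordering
  that makes O_(1) = A(C⊙B)ᵀ exact for an exact CP model.
* **Supervised term** (weight ω, default 1).  −ω log P(y_i | [A_i:,1]·θ)
  added to each *training* patient's row objective, with θ (length R+1,
  intercept last) refreshed once per sweep by ridge-penalized logistic
  regression (weight c, default 1; the source method leaves c unspecified).
  Only the first R components of θ enter the row gradient and Hessian — the
  intercept does not depend on A_i:.  Held-out patients are always updated
  with ω = 0, so no outcome information reaches their memberships.
* **Similarity term** (weight μ, default 1000).  μ‖S^B − BBᵀ‖² and
  μ‖S^C − CCᵀ‖², the symmetric-NMF form of the spectral-clustering trace
  Tr(BᵀSB); the identity ‖S − BBᵀ‖² = ‖S‖² − 2Tr(BᵀSB) + ‖BᵀB‖² (verified
  numerically in the tests) shows the two rank candidate factors
  identically, while the residual form additionally pushes BᵀB toward
  orthogonality.

### Contextual similarity

One token sequence per admission, events ordered by timestamp with ties
broken deterministically (diagnosis before prescription, then code
lexicographically) so shuffled input files produce identical corpora.  Two
embedding backends satisfy one contract (codes co-occurring within the
window score higher cosine than codes that never do):

* `sgns` — skip-gram with negative sampling (5 negatives, 5 epochs, linearly
  decaying learning rate from 0.025), implemented in numpy and fully seeded;
  defaults d = 500, window = 30 mirror the reference configuration.
* `ppmi-svd` — positive PMI of symmetric windowed co-occurrence followed by
  rank-d truncated SVD with a deterministic sign convention.  SGNS is an
  implicit factorization of shifted PMI, so the two agree qualitatively;
  the deterministic backend is what the tests and reproducible pipelines
  use (d = 16, window = 5 suffice at desk scale).

The raw cosine matrix (diagonal zeroed) is sparsified per row to the
l = ⌊log₂ n⌋ largest nonnegative entries (negatives are dissimilarity and
dropped first; ties at the cutoff all kept), symmetrized by elementwise
maximum so no kept edge is lost, then degree-rescaled S ← D^(−1/2)SD^(−1/2),
which bounds the spectral radius by 1 and hence keeps the symmetric-NMF
target well scaled.  Sparsify-then-normalize is the default order; the
alternative is exposed (`nc_order="nc-first"`).

## Algorithm and numerical choices

Each sweep: all patient rows (batched R×R Newton solve; the rank-1
supervised Hessian correction is folded in by Sherman–Morrison), θ refit,
one Newton step on B, one on C.  Safeguards around the raw Newton updates,
which can diverge under projection:

* every Hessian is ridged by η = 10⁻⁸ before solving;
* every step is backtracked (halving, ≤ 20 times) until the block objective
  does not increase; if no step improves, the block is left unchanged;
* the JR×JR Newton solve for a code factor is used while JR ≤ 2000,
  otherwise a backtracked gradient step (constant step chosen by halving
  from 1) — the printed curvature of the similarity term is exact only at
  R = 1 (it omits cross-column coupling), which the backtracking absorbs;
* a singular curvature matrix falls back to the gradient step with a
  warning.

**Convergence.**  The fit statistic is fit = 1 − ‖O − X‖/‖O‖.  The nominal
rule |fit_old − fit| < 5×10⁻⁴ is necessary but not sufficient when μ is
large: the similarity term reshapes B and C for tens of sweeps while the
data term barely moves (A absorbs the rescaling), so stopping on fit alone
freezes the factors mid-transient and can even invert the regularizer's
intended effect.  Convergence therefore additionally requires the similarity
objective to have stabilized (same relative tolerance) and only arms after
`min_iter` (default 10) sweeps; `max_iter` defaults to 200.

After convergence each factor column is divided by its Euclidean norm
(λ_r = product of the three norms; zero columns keep λ_r = 0) and entries
below the mode threshold are zeroed: 10⁻⁶ for patients, 10⁻³ for code modes.
Columns are *not* renormalized after thresholding — thresholding is the last
step.

Initialization is i.i.d. uniform(0, 1) from the run seed; the factorization
is non-convex, so all randomness flows from one `RunConfig.seed`.

## Evaluation

* **Discrimination**: repeated stratified k-fold CV.  The factorization is
  refit inside every fold (leakage guard: the tests assert the refit
  happens); a fresh logistic regression on the training Ā rows scores the
  held-out patients.  AUC is the rank statistic; sensitivity/specificity use
  probability threshold 0.5 (configurable — the choice is a reporting
  convention); 95% CIs are t-intervals over fold × repeat values.
* **Distinction**: relative length = mean over phenotypes of
  (nnz(B̄_:r) + nnz(C̄_:r))/(J + K); average overlap = mean pairwise cosine
  of the phenotype columns over both code modes with the printed
  normalization Σ_{r1<r2}[cos_B + cos_C]/(R(R−1)).  Overlap uses the
  thresholded normalized columns (cosine is scale-invariant, so only the
  thresholding matters; `use_thresholded=False` gives the raw-factor
  variant).
* **RMSE** is defined over *all* I·J·K entries including zeros — stated
  prominently because comparisons depend on this convention.

## Reporting

Forward stepwise logistic regression on Ā: starting from the intercept-only
model, each step adds the candidate minimizing the deviance of the augmented
model provided its Wald p-value there is below 0.05, and stops when no
candidate qualifies; the reported coefficients/p-values come from the final
refit.  Complete separation (deviance ≈ 0 or runaway coefficients) triggers
a small-ridge refit (c = 10⁻⁴) so reported coefficients stay finite.
Representative phenotypes are those with |coefficient| > 20 (configurable).
Quadrants: the top five selected phenotypes by λ (ties by prevalence, then
index) are "common", the rest "rare"; positive coefficient = high risk.
Membership-decile mortality tables report the death fraction per width-0.1
bin of Ā_:r, blanking bins with fewer than 10 patients; a membership of
exactly 1 falls in the last bin.

## Synthetic worlds

The default world: I = 400 patients, J = 60 diagnoses, K = 80 prescriptions,
R_true = 6 phenotypes occupying disjoint contiguous code blocks, code
memberships uniform(0.5, 1) inside a block, patient rows Dirichlet(0.5),
columns rescaled so every λ_r = 400 (chosen so mean counts are of order one —
mirroring real co-occurrence data where most nonzero counts are 1 — before
the Poisson draw).  Counts are Poisson at the low-rank mean; the outcome
follows a logistic model on two of the six phenotypes with alternating signs,
each scaled to contribute logits of standard deviation 2 and an intercept
centering the logits (the balanced cohort of a case-control mortality
design).  Event emission creates one admission per nonzero diagnosis row —
diagnosis once, each co-occurring prescription repeated its count — with
same-block prescriptions placed adjacent to the diagnosis, so windowed
co-occurrence carries the planted blocks; re-counting the admissions with
`admission_policy="sum"` reproduces the tensor exactly.

What a green test does and does not establish: the generator has exactly
low-rank structure plus Poisson noise, disjoint code blocks, no background
"everyone gets acetaminophen" co-occurrence, no code-frequency skew, and no
temporal drift.  Recovery and regularizer-effect results on it demonstrate
correctness of the machinery, not performance on real EHR data.

Two regime notes, decided up front and documented here:

* *"Noiseless" recovery* uses the exact continuous low-rank mean tensor: an
  integer count tensor can never be exactly rank 3 (rounding alone
  contributes ≈ 5% relative noise and caps the attainable fit near 0.95).
* *Regularizer-effect comparisons* run at the over-complete analysis rank
  R = 10 > R_true: real-data analyses fit R far below the data's latent
  complexity, and at R = R_true the desk-scale CP baseline already recovers
  perfectly distinct phenotypes, leaving both regularizers nothing to
  improve (every comparison would be a vacuous tie).

## Known limitations

* The supervised term at its reference weight ω = 1 moves each patient row
  by roughly 10⁻⁴ of the data-fit gradient at desk scale (the per-row
  residual norm dwarfs a log-likelihood bounded by log 2), which is below
  the resolution of a rank-based AUC on 100 held-out patients; the paired
  supervised-vs-unsupervised comparison in the acceptance suite measures
  exactly this and is reported as it comes out.  Large ω demonstrably
  reshapes the factors; the mechanism is exercised and finite-difference
  verified.
* The exact Newton path is dense: the tensor is densified internally, which
  is fine at desk scale (≲ 10⁷ entries) but the I·J·K memory footprint, not
  the solver, is the binding constraint for large cohorts.
* Eq-15-style curvature for the similarity term is a rank-1-exact
  approximation used as printed; for R > 1 backtracking guarantees monotone
  block objectives but convergence can be slow near column-merging
  transients (hence the convergence rule above).
* The forward-selection procedure (deviance-greedy, Wald entry at 0.05) is a
  declared convention; other stepwise criteria are equally defensible and
  would select slightly different phenotype subsets.
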