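# Methods

## Model

The generative model for the N matrices to be aligned is a perturbation
model: Xᵢ = αᵢ (M + Eᵢ) Rᵢᵀ with Rᵢ ∈ O(m) (rotations *and* reflections —
no determinant correction is applied anywhere), αᵢ > 0, and matrix-normal
noise Eᵢ ~ MN(0, Σₙ, Σₘ).  Translations are handled solely by column
centering (`center_columns`); the model is then stated directly on the
centered data.  The rank-reducing projection that makes centered rows
exchangeable is not materialized: it leaves the rotation estimates
unchanged, and operating on Cₙ·Xᵢ keeps the code simple.  One visible
consequence: centered matrices have row rank ≤ n − 1, so the thin-SVD
path always reports one data-free trailing direction.

Estimation with known nuisance parameters is closed-form: the ML rotation
is UVᵀ from the SVD of the whitened cross-product XᵀΣₙ⁻¹MΣₘ⁻¹, and the ML
scale is ‖Σₘ^{-1/2}R̂ᵀXᵀΣₙ^{-1/2}‖²/tr(D).  That scale is simultaneously
the least-squares minimizer of ‖XR/α − M‖², which is what keeps the GPA
loop monotone when scaling is enabled.

With unknown nuisance parameters, `gpa_align` iterates: per sweep, each
subject's rotation (and optionally scale, re-estimated immediately after
the subject's rotation) is solved against the current template; the
template is then refreshed as the element-wise mean of the aligned
matrices.  The recorded objective is the negative (prior-penalized) total
Frobenius loss, −(Σᵢ‖X̂ᵢ − M̂‖² − 2k Σᵢ tr(FᵀR̂ᵢ)); both half-steps solve
their subproblem exactly, so the trace is non-decreasing.  Convergence is
declared when the relative change of the penalized loss falls below `tol`
(default 1e-7) within `max_iter` sweeps (default 50; neither value is
canonical — they are this package's defaults).

Row/column covariances are estimated, when requested, by the two-stage
flip-flop: Σ̂ₙ = Σᵢ Resᵢ Σ̂ₘ⁻¹ Resᵢᵀ/(Nm) alternating with
Σ̂ₘ = Σᵢ Resᵢᵀ Σ̂ₙ⁻¹ Resᵢ/(Nn).  The estimator exists iff N ≥ m/n + 1
(`min_subjects_required`); only the Kronecker product Σₘ ⊗ Σₙ is
identified, so the returned factors are normalized to tr(Σ̂ₙ) = n.

## The vMF prior

The matrix von Mises–Fisher density f(R) ∝ exp{k tr(FᵀR)} is conjugate:
the posterior location is F* = XᵀΣₙ⁻¹MΣₘ⁻¹ + kF, and the MAP rotation is
the same SVD computation applied to F*.  The normalizing constant (a
hypergeometric function of matrix argument) is never needed and never
computed.  The prior mode is the polar orientation factor P of F = PK;
with full-rank F the MAP is unique — `promises_align` sets
`result.unique` from the prior rank and the observed posterior ranks.
The prior on the product αᵢRᵢ is honored implicitly: the scale and
rotation MAP estimators are computed exactly in their closed forms; no
separate hyperparameter for α exists.

Builders:

* `build_identity_F(m)` — identity location, stored sparse so the
  m × m array is never allocated (required at fMRI scale).
* `build_spatial_F(coords)` — Euclidean similarity kernel exp(−distance),
  unit diagonal.  Above m = 2,000 a cutoff radius (default 3 grid units)
  zeroes distant entries exactly and stores the matrix sparse; the kernel
  decays exponentially so little mass is lost, but full rank is no longer
  guaranteed and the rank diagnostics warn accordingly.
* `load_custom_F` — user matrices (dense file, triplet file, or array),
  with rank diagnostics and a uniqueness warning on rank deficiency.

F is used exactly as built; k is therefore on the scale of the data
cross-product (entries of XᵀM grow like n).  If cross-product magnitudes
vary wildly across datasets, pre-normalize the data (‖Xᵢ‖_F = 1 is
available behind the `scaling` machinery or by hand) before comparing k
values.

### Choosing k

`select_k_cv` performs leave-one-subject-out cross-validation: for each
candidate k the N−1 training subjects are aligned; the held-out subject's
MAP rotation toward the training template is fitted on the first half of
the rows (`fit_fraction`, default 0.5); the score is the mean column-wise
Pearson correlation between the *remaining* rows, rotated, and the
template's remaining rows.  Ties go to the smallest k.  The row split is
deliberate: scored on the fitting rows themselves, k = 0 is (near-)optimal
by construction because the unregularized rotation directly maximizes the
in-sample fit, and the criterion carries no information about
generalization.  Scoring held-out rows is the standard validation design
for functional alignment and makes the criterion favor k > 0 exactly when
the unregularized rotation over-fits noise.  When an explicit Σₙ is in
use, the row split ignores it (identity rows within the fold), since the
full n × n row covariance does not conform to a subset of rows.

## Efficient path

For n ≤ m, each subject is reduced by its thin SVD Xᵢ = LᵢSᵢQᵢᵀ and
aligned in its own n-dimensional column frame.  Per sweep the posterior
location is (XᵢQᵢ)ᵀ Σₙ⁻¹ (MQᵢ)/σ² + k QᵢᵀFQᵢ, with M the full-space
template projected per subject (the template has no thin-SVD frame of its
own; projecting it as MQᵢ preserves the trace identity and the O(mn²)
budget).  For F = I the reduced prior is analytically Iₙ.  Rotations are
persisted as factored pairs (Qᵢ, Rᵢ*); the induced m × m operator
QᵢRᵢ*Qᵢᵀ has rank n and is never materialized.

The reduction requires an isotropic column covariance Σₘ = σ²Iₘ; an
explicit Σₘ raises.  This does not assume column independence of the
data — the column dependence is carried by Rᵢ — and matches common
practice of setting both covariances proportional to identities.

Two subtleties worth stating precisely:

* **Fit equality, solution inequality.**  The reduced and full problems
  attain the same maximized data trace at any fixed reference (the
  cross-product's row and column spaces lie inside the thin-SVD frames),
  but they optimize over different constraint sets — rank-n transports vs
  full orthogonal matrices — so the rotation solutions, and the template
  sequences the two algorithms generate, are not identical.  Tests assert
  equal objective values, never equal rotations.
* **Prior term.**  The trace identity extends to the prior only on the
  rank-n component: tr((QᵢR*Qⱼᵀ)ᵀ kF) = k tr(R*ᵀ QᵢᵀFQⱼ) exactly, but an
  ambient full-rank F also rewards the orthogonal complement, which the
  reduced problem cannot see (an unconstrained O(m) maximizer of
  tr(Rᵀ(A + kI)) earns up to k(m − n) more than any rank-n transport).
  The equivalence test therefore compares the with-prior maxima with the
  prior embedded on the reduced frames, which is the identity the
  efficient algorithm actually relies on.

## Synthetic data

`simulate_stack` draws from the stated model: E = noise_sd · √Σₙ G √Σₘ
with standard-normal G, Haar-uniform rotations via QR with the R-diagonal
sign fix (vMF sampling is out of scope and unnecessary for testing),
matrix square roots via symmetric eigendecomposition with tiny negative
eigenvalues clipped at zero (warned).  Identity rotations are special-cased
so no m × m identity is ever built.  Same config + seed ⇒ bit-identical
output.

The generator emulates the perturbation model only.  It does not emulate
realistic fMRI signal (no HRF convolution, drift, physiological noise, or
spatial autocorrelation beyond an explicit Σₘ), so a green recovery test
establishes correctness of the estimators under the model's own
assumptions — not performance on real BOLD data.

## Numerical choices

* SVD sign convention: each left singular vector is flipped so its
  largest-magnitude entry (ties: lowest index) is positive, with the
  matching right vector flipped too — bit-reproducible runs.  Tied
  singular values keep the backend's order and raise
  `DegenerateSVDWarning` (the product UVᵀ is still well-defined for
  full-rank inputs).
* Numerical rank: singular values below max(n, m)·ε·s_max count as zero.
* Zero cross-product (or posterior location) ⇒ "degenerate alignment
  problem" error; tr(D) ≤ 0 or non-finite scale ⇒ error; zero residuals in
  covariance estimation ⇒ error.
* Stopping: relative penalized-loss change below `tol`; optionally also
  the largest per-sweep rotation change below `rotation_tol`.  The second
  criterion exists because with a weak prior the loss flattens to machine
  precision while the solution still creeps along the weakly pinned
  common-rotation mode; certifying uniqueness to 1e-6 needs the rotations
  themselves to settle.  A loop that hits `max_iter` returns
  `converged=False` with a warning (CLI exit code 3).
* Scaling (α) is off by default, as common in fMRI practice; enable with
  `scaling=True`/`--scaling`.

## Limitations

* With a weak prior (k small relative to ‖XᵀM‖) the fixed-point iteration
  converges geometrically but slowly along the near-flat common-rotation
  mode; expect hundreds to thousands of cheap sweeps for tight tolerances.
* The efficient path's fit is measured against rank-n transports; at
  n ≪ m with strongly rotated truth its Frobenius loss against the mean
  template can exceed the full path's, even though each pairwise trace
  maximum matches.
* Covariance estimation needs N ≥ m/n + 1 — rarely satisfiable at fMRI
  scale (n = 200, m = 200,000 ⇒ N ≥ 1,001); use identity or isotropic
  covariances there.
* `rank`/polar diagnostics of a sparse F are computed only up to
  m = 2,000 (densification guard); beyond that uniqueness is not
  certified (warning), though F = I is handled analytically.
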