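# Methods

## Model

`srmkl` trains a binary classifier on style-grouped data by minimizing

    J(w, b, μ, {A_j}) = 1/2 Σ_i μ_i w_iᵀw_i + λ/2 Σ_{j,k} e_{jk}²
                        + λγ Σ_j ‖A_jᵀ − I‖_F²
    s.t.  y_j^k = Σ_i μ_i w_iᵀ A_jᵀ Φ_i(x_j^k) + b + e_j^k,
          μ on the probability simplex,

an LSSVM with multiple-kernel weights μ and one style matrix A_j per group,
the matrices regularized toward the identity. Assumptions: binary labels,
both classes present in training; every sample carries a style-group id
that the caller supplies (the package never infers style membership); a
group's distortion is well approximated by a single affine map in feature
space; and test samples either belong to a trained group (Rule 2) or form
a style-homogeneous group of their own (Rule 3).

### Combined-map convention

The objective above writes one A_j acting on each base feature map Φ_i. The
transformed-Gram algebra, however, is only expressible in kernel values at
the level of the μ-combined map Φ with ⟨Φ(x), Φ(z)⟩ = Σ_i μ_i k_i(x, z).
The package therefore implements one A_j per group acting on the combined
feature space — not one per (group, kernel) pair. Under this convention the
stationarity condition of the A_j block gives the rank-one form

    A_jᵀ = I + c · w v_jᵀ,   c = 1/(2λγ),
    w   = Σ_m α_w[m] Φ(x_m),     v_j = Σ_{k ∈ group j} α_s[k] Φ(x_k),

and the transformed Gram is a rank-two correction computable from Gram
entries alone:

    K̂ = K + c (q sᵀ + s qᵀ) + c² W q qᵀ,
    s = K α_w,  W = α_wᵀ K α_w,  q_a = Σ_{m ∈ g(a)} α_s[m] K[a, m].

A `StyleModel` therefore stores two coefficient vectors: the classifier
dual snapshot α_w (defining w) and the subproblem multipliers α_s (defining
the v_j). The correctness of this algebra is pinned by an explicit-feature
oracle: for a linear kernel the map is the identity, the A_j can be
materialized as d×d matrices, and the rank-two update must reproduce
x_aᵀ A_{g(a)} A_{g(b)}ᵀ x_b to machine-level accuracy. The same oracle
validates the penalty identity ‖A_jᵀ − I‖_F² = c² W · (v_jᵀ v_j).

### Exact style update

With the classifier (w, b, μ) fixed, the A_j block is a ridge problem whose
kernelized exact solution is a t_j × t_j linear system per group:

    (I + (W/2γ) K_jj) e_j = ρ_j,    α_s = λ e,

where ρ = y − (K α_w + b) are the residuals at A = I and K_jj is the
group's block of the combined Gram. The package solves this system rather
than re-using the classifier's own multipliers as the update coefficients:
the classifier multipliers equal λ times residuals measured at the *old*
A, so they do not minimize the subproblem, whereas the exact solve does —
it agrees to 1e−6 with an independent quadratic solve over all d² entries
of A_j (tested), and it keeps the alternation a genuine block-coordinate
descent step.

### Alternation and the objective monitor

Each outer iteration (a) fits MK-LSSVM on the current transformed Grams,
(b) evaluates J, (c) updates the style coefficients in closed form. Within
one iteration the style correction Δ is a fixed matrix added to every base
Gram; because simplex weights sum to one, Σ_i μ_i (K_i + Δ) = Σ_i μ_i K_i + Δ,
so the SILP can relearn μ with the A_j held fixed. Δ is defined against the
combined Gram of the weights in force when the style was last updated;
the model records those weights (`mu_style`) alongside the final μ, and
prediction reuses both so that test-time kernel values extend the training
geometry exactly.

Two approximations mean J carries no global descent guarantee: the weight
vector w is re-expanded over the *original* feature map when the style
block is solved (the snapshot convention that keeps everything in Gram
entries), and μ changes between the Δ used for a fit and the Δ implied by
the new weights. J is therefore monitored: the loop stops at relative
change < `tol`, and any increase beyond a 1e−6 relative slack aborts the
loop with the best iterate retained (`converged=False`). In practice the
trace descends for the first iterations and the guard triggers once the
style block has extracted what it can — the reported model is the best
visited iterate, never the last.

Iteration 1 starts from A_j = I, so its classifier is bit-identical to
plain MK-LSSVM on the untransformed Grams (tested at 1e−10); `max_outer=1`
is the package's MKL baseline.

### SILP solver

The MKL subproblem min_μ max_α is solved by column generation: each inner
LSSVM dual solve at the current μ yields the exact inner value S(μ) (a
convex function of μ) and one linear cut; a small LP over the accumulated
cuts proposes the next μ and a lower bound. Termination: incumbent-minus-
bound gap below `tol` (relative), or `max_iter` cuts. The recorded
objective trace is the *incumbent* value — the best S(μ) visited — which is
non-increasing by construction; raw cutting-plane iterates are not
monotone. The returned weights are the incumbent's. Correctness is pinned
against a 0.01-resolution exhaustive scan of the two-kernel simplex.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lam` (λ) | 1.0 | LSSVM ridge; larger fits residuals harder. Unitless; enters K̃ = K + I/λ. |
| `gamma` (γ) | 1.0 | style-penalty strength; γ→∞ freezes A_j = I. The simulation study uses 0.1, mid-range of the e⁻⁵…e⁻¹ grid typical for this method family. |
| `max_outer` | 20 | outer alternation budget. |
| `tol` | 1e−4 | relative objective tolerance, outer loop and SILP alike. |
| kernel bank | 10 kernels | gaussians at median pairwise distance × 2^{−3..3}, linear, polynomial degrees 2–3 (coef0 = 1). The bank is a field convention: only μ is learned, never kernel hyperparameters. |
| `normalize` | on | cosine normalization of base Grams to unit diagonal, making heterogeneous kernels commensurable in the SILP. |

Numerical conventions: `sign(0) = +1` everywhere, making predictions
deterministic; a Cholesky factorization of K̃ with two right-hand sides
(never an explicit inverse), with a 1e−10·trace/n jitter retry and a
symmetric-solve fallback for numerically indefinite transformed Grams;
degenerate groups with a single sample are allowed and get a valid A_j.

## Synthetic data

The generator emulates the stylized-data premise at feature level: per
group, two isotropic Gaussian classes (means `class_sep` apart along the
first axis, spread `noise_sd`) pushed through a random rotation of angle
`style_strength` radians plus a Gaussian shift of scale 0.3·`style_strength`.
Affine distortions are exactly what a linear-kernel style matrix can undo,
so the generator probes the model's own assumption class. Defaults — 3
groups of 40 samples in 4 dimensions, `class_sep=2`, `noise_sd=1` — give a
pooled problem that is comfortably learnable unstyled and visibly degraded
at strength 2. Splits are label-stratified within groups; a split plan can
hold whole styles out of training for the unseen-style (Rule 3) design.

What it does *not* emulate: raw EEG time series (classifiers consume
post-KPCA features anyway), non-affine or within-group drift, label noise,
class imbalance, or styles correlated with the class. Passing the
simulation study therefore shows the method exploits group-wise affine
structure when present and is benign when absent — not that it improves any
particular real dataset.

The committed study conditions for the simulation: λ=1, γ=0.1, default
bank, 50/50 within-group splits, generator seeds 0–9 (offset by the
acceptance script's `--seed`). Measured there, the Rule-2 vs plain-MKL mean
accuracy gap is ≈ +0.03…+0.05 at strength 2 and ≈ −0.03…0 at strength 0.

## Prediction rules

Rule 2 transforms cross-kernel values with the trained A of the declared
group; with an identity style model it equals Rule 1 exactly (and the
implementation short-circuits to guarantee it). An unknown group id raises
an error directing the caller to Rule 3. Rule 3 is one pass — temporary
labels, a single refit with the group appended as style N+1, a Rule-2
prediction — with no label re-estimation loop; whether to re-optimize μ in
the refit was an open choice, and the full refit was implemented. With
γ→∞ in the refit Rule 3 reduces to Rule 1 whenever the refit classifier
reproduces its own training labels, which holds on separable data (the
regime the consistency test uses).

## EEG front-end

The Bonn loader accepts the corpus's one-integer-per-line ASCII layout
(sets A–E or their historical code letters Z/O/N/F/S), treats each set as
one style group, and labels A–B healthy (+1), C–E patient (−1). Features
are kernel-PCA projections of whole recordings (default 70 components,
gaussian kernel at the median-distance width — the KPCA settings of
published experiments on this corpus are typically unstated, so results
depend on this documented convention). The four benchmark designs are
50/50 within-group splits over {A,B,E} and {B,D,E}, and style-holdout
splits over {A,C,E}; the published description does not identify which set
the two holdout designs exclude, so the holdout is a parameter (defaults:
C and A respectively). Nothing in the test suite touches real Bonn data.

## Complexity

Per outer iteration the dominant costs are the SILP (a handful of O(n³)
LSSVM solves plus trivial LPs) and the style update (per-group O(t_j³)
solves). The method family's literature quotes an overall
O(iter·(M²n³ + N²n²)) alongside O(M²n²) for the SILP step; the package
documents this as-printed and does not assert it.

## Limitations

- The alternation optimizes a min–max objective blockwise; only the best
  visited iterate is guaranteed, not a stationary point.
- One affine map per group: multi-modal or time-varying styles within a
  group are outside the model.
- Rule 3 inherits Rule 1's errors through its temporary labels; on hard
  unseen styles it can only partially recover.
- Serialization stores training features verbatim (required by kernel
  prediction); artifacts scale with n.
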