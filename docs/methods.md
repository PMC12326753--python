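# Methods

## The estimator

For symmetric positive definite `M`, `log|M| = tr(log M)`.  The package
estimates the trace by Hutchinson probing with Rademacher vectors
(entries ±1 with probability ½):

    log|M| ≈ (1/s) Σ_{i=1..s} v_i' log(M) v_i .

The estimator is unbiased; its per-sample variance is
`2 Σ_{i≠j} (log M)_{ij}²`, i.e. it depends only on the off-diagonal mass of
`log M`.  Both the per-sample values and their standard deviation are
reported so the Monte Carlo error is always visible alongside the estimate.

`log(M) v` is never formed through an eigendecomposition.  It is evaluated
through the Cauchy integral

    log(M) v = (M / 2πi) ∮_Γ z⁻¹ log(z) (zI − M)⁻¹ v dz ,

with `Γ` a closed contour around the spectrum avoiding the branch cut
`(−∞, 0]`.  The substitution `z = w²` maps the problem to the interval
`[√λ_min, √λ_max]` in the `w`-plane; a conformal map of an annulus built
from Jacobi elliptic functions places `n_int` midpoint nodes on the midline
of the fundamental rectangle, with elliptic modulus
`k = ((λ_max/λ_min)^{1/4} − 1) / ((λ_max/λ_min)^{1/4} + 1)`.  Each node `j`
contributes one shifted solve `(w_j² I − M) z_j = v` and a closed-form
weight; the final combination is `M` times the imaginary part of the
weighted sum, which is exactly real for SPD `M` up to quadrature error.
The quadrature error decays geometrically in `n_int` at rate
`≈ exp(−π² n_int / (ln κ + 3))` with `κ = λ_max/λ_min`; measured on random
SPD fixtures each +2 nodes shrinks the error by a factor ~40 at κ = 10⁴.

### Inner solves (COCG)

`(w²I − M)` is complex symmetric but not Hermitian, so the inner solver is
COCG: the CG recurrences with the unconjugated bilinear form `r'r`.  The
default preconditioner is the Jacobi diagonal `w² − diag(M)` whenever the
operator can expose its diagonal (all operators in this package can);
"none" is available for operators that cannot.  Iterations are capped at
`n_cocg` (default 20) with tolerance 1e-8 — the cap wins, and a capped
unconverged solve is used as-is (flagged in the solve report) rather than
aborting the quadrature.  Bilinear-form breakdown is likewise flagged, not
raised.  The final residual in every report is recomputed from the returned
solution, never the recurrence value.

### Spectral bounds (Lanczos)

Extreme eigenvalues come from Lanczos with full (two-pass)
reorthogonalization, started from a Rademacher vector drawn from the seed.
If a basis budget smaller than `n_lanczos` is configured, the process
restarts from the sum of the current extreme Ritz vectors and combines
extremes monotonically across cycles; Ritz values always lie inside the
true spectrum, so this preserves interlacing.  Before the contour is built
the interval is widened outward by `max(ritz residual, 1e-10·λ̂_max)` on
each end — Ritz values approach the spectrum from the inside, so an
unwidened interval could leave eigenvalues outside the contour when the
smallest eigenvalue is under-converged.  The widened lower end is clamped
to `0.01·λ̂_min` to stay positive.

### Exact reference

`exact_logdet_ldl` computes the (pseudo) log-determinant from an LDL'
factorization with Bunch–Kaufman pivoting, summing `log d` over block
eigenvalues above `rank_tol = n·ε·max|d|` (the usual pivot-tolerance
convention; an exact "d > 0" indicator is not implementable in floating
point).  Pivots below `−rank_tol` raise: the input is not PSD.  The Monte
Carlo path requires numerically positive definite input; pseudo-
determinants of singular matrices are exact-path only, since placing a
contour around a spectrum containing zero is not possible.

## Mixed-model layer

Model: single-trait `y = Xb + Σ_k W_k u_k + e`, `Var(u_k) = σ²_k K_k`,
`Var(e) = Iσ²_e` (homogeneous residual only).  Covariance kinds for `K_k`:
the pedigree relationship `A`, the single-step relationship `H`, or the
identity (permanent environment).  Equation order is fixed effects first,
then each random effect's levels — fixed for reproducibility, numerically
irrelevant.

* `A⁻¹` by Henderson's rules from Mendelian sampling variances
  `d_i = 0.5 − 0.25(F_s + F_d)` (unknown parent ⇒ F = −1), with inbreeding
  from the Meuwissen–Luo recursion by default (a flag disables it, which
  changes `log|A|` and is therefore controlled in tests).
* `G = Z_c Z_c' / (2Σp(1−p))`, `Z_c` centered by twice the allele
  frequency; frequencies are computed from the genotyped set itself
  (configurable) — the base-population frequencies are unknown in the data
  this emulates.  `G` is blended as `(1−w)G + w·A22` with `w = 0.05`, the
  standard single-step practice that guarantees the invertibility `H⁻¹`
  needs.
* `H⁻¹ = A⁻¹ + [0; G_b⁻¹ − A22⁻¹]` with the dense correction kept separate
  from the sparse part; `log|H| = −log|H⁻¹|` because only `H⁻¹` has a cheap
  matrix–vector product.
* `−2 log L_r = n log σ²_e + Σ_k (q_k log σ²_k + log|K_k|) + log|C| + y'Py`
  up to a constant independent of the variances (the same constant for both
  backends, so curves and optima are comparable).  This equals the V-form
  `log|V| + log|X'V⁻¹X| + y'Py` exactly; the test suite checks the identity
  on dense fixtures.  `y'Py = y'R⁻¹y − θ̂'rhs` with `θ̂` from a
  Jacobi-preconditioned CG solve of the MME.
* Profiling over heritability defaults to the true profile likelihood: the
  overall scale is profiled out analytically
  (`ŝ = y'P₀y/(n−p)`), so the curve depends on h² alone.  A fixed-total
  mode exists but needs a sensible user-supplied total variance — fixing
  the total at `var(y)` double-counts the fixed-effect variance and can
  push the minimum to the grid boundary.
* DF-REML minimizes over log-variances (unconstrained, positivity for
  free) with Powell's direction-set method as implemented in
  `scipy.optimize`, tolerance 1e-4 on −2logL_r, bounds a factor 10³ around
  the start.  With the approximate backend the probe sequence is forced to
  be a pure function of the seed (common random numbers); without that the
  optimizer chases Monte Carlo noise.
* EM-REML (validation only, dense): `σ²_k ← (û'K⁻¹û + σ²_e tr(K⁻¹C^{kk}))/q_k`,
  `σ²_e ← y'(y − Θθ̂)/(n − p)`, iterated to a relative change below 1e-8.
  EM crawls near its fixed point (hundreds to thousands of rounds), which
  is why it is the reference, not the workhorse.

## Synthetic data

The generator emulates livestock evaluation data: a multi-generation
pedigree from random union of sires and dams (no selection, no assortative
mating), SNP genotypes by gene dropping — founders from Hardy–Weinberg at
the founder allele frequencies (default U(0.1, 0.9) per locus), each
descendant receiving one fair-coin gamete per parent per locus — and
phenotypes from sequential Mendelian sampling down the pedigree
(`u_i = ½u_s + ½u_d + m_i`, `m_i ~ N(0, d_i σ²_u)`), never from a dense
factorization of `A`.  Records attach to all non-founders (founders
predate recording, as in the dairy/beef structures this mimics);
contemporary groups are assigned at random with N(0,1) effects; the
genotyped subset is drawn from the youngest generations.  Defaults:
h² = 0.3, 20 contemporary groups, 10% genotyped.

What this does *not* emulate: selection (so no selection-induced
disequilibrium or likelihood distortion), linkage (loci segregate
independently; no recombination map), heterogeneous residual variances,
maternal effects, multi-trait covariance.  Passing tests therefore show
that the numerics are right under the assumed model, not that the model
fits any particular real population.

## Problem sizes and the accuracy of the scaled-down benchmark

The package's accuracy benchmark runs single-step datasets of 2000–5000
pedigree animals (~500 genotyped at 1000 SNPs) at the default operating
point and compares against exact LDL' values; measured mean absolute
relative difference for `log|C|` is ~3×10⁻³.  Two size-dependent effects
are worth knowing:

* `log|H⁻¹|` at these sizes has magnitude ~10³ (vs ~10⁵–10⁶ for `log|C|`
  at national-evaluation scale), so the same absolute probe noise is a
  larger *relative* error for `H⁻¹` than the headline `C` numbers.
* Likelihood comparisons at ~10³ animals: with 5 probes the slowly varying
  Monte Carlo error of `log|C|` across variance-component values is
  comparable to the profile's curvature.  The package's desk-scale
  recommendation, used in the examples and tests, is `n_samples = 25` for
  profiles and DF-REML at these sizes; at evaluation scale the default 5 is
  the right trade-off because curvature grows with the number of records
  while relative probe noise shrinks.  Even so, a dataset whose exact
  profile is flat to <0.2 units between adjacent grid points cannot pin its
  argmin at that grid resolution — no estimator with nonzero noise can.

## Known limitations

* Single trait, homogeneous residual; no maternal effects, metafounders or
  unknown-parent groups.
* The MC path needs numerically PD input; rank-deficient matrices go
  through the exact pseudo-determinant path.
* The Hutchinson estimate is unbiased but not exact: treat the reported SD
  as part of every downstream number, and reuse probes whenever two
  likelihoods will be compared.
* Dense desk-scale steps (tabular `A`, `A22⁻¹`, blended `G⁻¹`, EM's
  `C⁻¹`) are quadratic/cubic in their block sizes and are meant for
  validation-sized problems, not production pedigrees.
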