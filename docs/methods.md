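# Methods notes

## Model and assumptions

`nspnet` analyses nonnegative, unit-diagonal FC matrices built from
Pearson correlations of parcellated BOLD series. Zeroing negative edges
makes the matrix entrywise nonnegative, so the Perron–Frobenius theorem
guarantees a uniform-sign leading eigenvector whenever the network is
irreducible (in practice: strictly positive), which is what lets level 1
represent the whole brain as a single module. The nested partition
assumes that the sign pattern of successive eigenvectors is a meaningful
module contrast — exact for block-structured matrices (the second
eigenvector of a two-block matrix is the block indicator contrast) and a
useful approximation otherwise.

The level score `H_i = Λ_i²·M_i·(1−p_i)/N` combines the mode's energy
(Λ_i²), the resolution of the partition (M_i/N) and a regularity factor
`1−p_i`, where `p_i = Σ_j|m_j − N/M_i|/N` is the mean absolute deviation
of module sizes from the equal-split size, normalized by N; p_i = 0 for
equal modules and approaches 1 for maximally lopsided splits. Two
readings of the level formula are defensible from its flattened sources
(`Λ_i²` vs `Λ_i`); the quadratic form is the default (consistent with
the squared eigenvector entries in the regional mapping) and
`variant="linear"` selects the other. Every conservation identity —
`H_In + H_Se = (1/N)ΣH_i`, regional means reproducing globals — holds
under either, and rank-based downstream results are unaffected.

## Numerical choices

- **Eigendecomposition.** `numpy.linalg.eigh` on the exactly
  symmetrized matrix; eigenvalues sorted descending, then negatives
  clipped to zero (clipped modes keep their level with H_i = 0).
  Eigenvector signs are canonicalized (largest-magnitude entry
  positive). Within a degenerate eigenspace the basis is
  solver-dependent; measures depend on it only through U, and exact
  tests use non-degenerate matrices.
- **Sign ties.** Entries with |U_ij| < 1e-12 join the positive side of
  a split — deterministic and measure-zero for generic data.
- **Partitioning always runs to level N**; modules that cannot split
  persist, so singleton-complete partitions arise naturally for
  generic matrices.
- **Calibration** multiplies each subject's component by
  `target / group-mean`, so calibrated group means equal the stable
  targets to machine precision, ranks are preserved, and the operation
  is idempotent. Regional values are rescaled by the same per-subject
  factor expressed against the *global* group mean; the alternative
  reading (per-region group means) would destroy the per-subject
  proportionality that motivates the construction, so it is not used.
  `H_B` is recomputed from calibrated `H_In` and `H_Se` (it has no
  calibration target of its own). Calibration runs per group by
  default (`per_group=False` pools both groups' series into one
  stable network).
- **ANCOVA** is OLS of the measure on group and mean framewise
  displacement (FD, in mm); the group term's partial F (= t²) and p are
  reported. FD is the default covariate because head motion is the
  confound that differs between groups; age/sex are optional. A
  zero-variance covariate is dropped, reducing the model to a plain
  two-group comparison rather than failing on a singular design.
- **Likelihood-ratio test.** Gaussian maximum-likelihood
  log-likelihoods (ℓ = −n/2·(log 2πσ̂² + 1), σ̂² = RSS/n) for nested OLS
  fits, df = 1, χ² reference. If the linear model already fits to
  numerical precision the statistic is defined as 0 (the quadratic
  term could only chase rounding error). The vertex −b/(2a) is
  reported only when the quadratic opens upward.
- **LOO-CV.** `loo_cv_predict` refits OLS explicitly per fold and
  reports rank-deficient folds by index. The search and permutation
  loops use the exact hat-matrix identity
  `pred_i = (ŷ_i − h_ii y_i)/(1 − h_ii)`, which is algebraically the
  same (tested against the explicit loop) and O(n²k). Leverages within
  1e-8 of 1 are treated as rank-deficient folds.
- **Feature selection** is computed once on all subjects and held
  fixed during CV, matching how the permutation test is defined
  (features fixed, scores shuffled, full CV re-run, add-one p
  estimator). This makes the observed r optimistic under the null —
  deliberately so, since the permutation distribution carries the
  inferential burden; both facts are asserted by simulation in the
  test suite. `nested=True` re-ranks features inside each fold for
  sensitivity analysis. Ties: equal r across K prefers the smaller K;
  equal F in ranking prefers the lower feature index.
- **System weight maps** average coefficients over *selected* regions
  only; systems with no selected region report 0 and are flagged,
  rather than being averaged over zeros.
- **Multiple testing**: regional/system maps are uncorrected by
  default; Benjamini–Hochberg is available (`stats.fdr_correct`) but
  off, mirroring exploratory-map practice.

## Synthetic cohorts

The generator emulates the second-order structure the method consumes:
hierarchical block covariances (7 systems with Schaefer-like sizes
(24, 13, 13, 12, 10, 14, 14); within-system correlation 0.35; two
nested sub-blocks per system adding 0.10; between-system 0.15, lowered
by `delta_between = 0.10` in the patient-like group), stationary
Gaussian series of T = 152 volumes for 49 + 49 subjects, FD covariates
(means 0.137 / 0.188 mm, SD 0.12, truncated at zero), and scores that
depend on the network by construction — linearly on z-scored regional
features, or quadratically on the global balance,
`y = γ·((H_B − c)/sd(H_B))² + ε` with γ = 2, ε-SD 1 and c defaulting to
the cohort mean so the vertex lies inside the sampled range (γ is
expressed per squared SD of H_B so its default does not depend on the
network's scale). Correlation defaults were chosen to give realistic
positive-edge fractions and clearly modular networks; the nested
compound-symmetric structure is provably positive definite for the
admissible parameter ranges, and the builder floors numerically
negative eigenvalues at zero (rejecting anything indefinite beyond
1e-10).

What the generator does **not** emulate: hemodynamics, autocorrelated
BOLD noise, motion artifacts coupled to the signal (an FD–network
coupling would have to be added explicitly), scanner drift, or
heavy-tailed score distributions. Passing tests therefore demonstrate
that the pipeline recovers structure *of the kind it assumes*; they do
not validate the method against physiological confounds.

A bundled region→system lookup table ships with the package so the
100-region pipeline runs out of the box; it uses Schaefer-style region
names with plausible per-system counts and is synthetic — substitute
the real atlas table for empirical work.

## Scan-length bias and what calibration buys

At T = 152 the raw single-subject H_Se is strongly inflated and, across
a grid of between-system couplings, not even monotone in the true
coupling — the bias interacts with structure. The stable-network values
(and hence calibrated group means) are monotone and track the
population values closely; tests of coupling trends are therefore
phrased on the calibrated/stable quantities, which are what the
pipeline reports.

## Problem sizes in the test suite

Study-shaped simulations (100 regions, T = 152, 49 + 49 subjects) are
used where group-level behavior is the claim: 50 cohort replicates for
group-difference power, 200 for the U-shape power, 2000 small null
datasets for LRT size, 50 replicates for prediction recovery and 200
for permutation-test size (500 permutations each). Unit tests use 3–14
region networks where closed forms exist. These sizes were chosen so
the whole suite gives stable Monte-Carlo estimates in a few minutes.

## Known limitations

- Eigenvector-basis ambiguity under eigenvalue degeneracy makes
  regional measures solver-dependent on exactly symmetric inputs;
  empirical FC matrices are generically non-degenerate.
- The best-K search optimizes the CV correlation itself; reported r
  values are model-selection-optimistic and only the permutation p
  should be interpreted inferentially.
- Calibration assumes each subject's regional proportions are
  trustworthy even when the global component is biased; nothing in the
  package re-derives the length-bias mechanism itself.
- The CLI covers simulation and prediction; group-difference analyses
  are intended to be driven from Python.
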