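# nspnet

Segregation, integration and their balance in resting-state brain
functional networks, measured by nested-spectral partition (NSP), with
the calibration, group-statistics and symptom-prediction pipeline that
goes with it.

## What problem this solves

Resting-state fMRI gives, for each subject, a functional connectivity
(FC) matrix: Pearson correlations between the BOLD time series of N
parcellated brain regions. A healthy brain balances *segregation*
(specialized processing inside modules) against *integration* (global
communication across them), and deviations from that balance are a
candidate marker for psychiatric conditions such as bipolar disorder.
`nspnet` is for researchers who have parcellated time series (e.g.,
Schaefer-100 parcels mapped to the Yeo 7 systems) plus covariates and
clinical scores, and want to quantify that balance per subject, per
region and per system, compare groups while adjusting for head motion,
and predict symptom severity from regional network features.

## The method

With negative edges zeroed and unit diagonal, the FC matrix is
eigendecomposed, `C = U Λ Uᵀ`, modes sorted by descending eigenvalue.
Eigenvector signs split the network recursively: level 1 is the whole
brain (the leading eigenvector of a positive matrix has uniform sign);
at level *i* each module of level *i−1* divides into the positive- and
negative-sign members of mode *i*. A level with `M_i` modules of sizes
`m_j` scores

```
H_i = Λ_i² · M_i · (1 − p_i) / N,      p_i = Σ_j |m_j − N/M_i| / N
```

and the global components are `H_In = H_1/N` (integration, level 1),
`H_Se = Σ_{i≥2} H_i / N` (segregation, all deeper levels), with balance
`H_B = H_In − H_Se` and deviation-from-balance `|H_B|`. Squared
eigenvector entries map the same components onto regions
(`H_In^j = H_1 U_1j²`, `H_Se^j = Σ_{i≥2} H_i U_ij²`), and system means
aggregate regions into the seven canonical systems.

Because short scans inflate segregation, individual components are
*calibrated*: each group's subject values are rescaled so their mean
equals the value from the group's "stable" network (FC of all subjects'
z-scored series concatenated in time). Group comparisons then run as
ANCOVA with framewise displacement as covariate; symptom associations
use linear/quadratic regression with a likelihood-ratio test for
U-shapes; and prediction uses F-statistic feature ranking, best-K
multiple regression under leave-one-out cross-validation, and
permutation significance — with weighted degree and participation
coefficient as graph-theory baselines through the identical path.

A synthetic-cohort generator (hierarchical block covariances, group
coupling differences, motion-like confounds, scores wired linearly or
quadratically to the network) makes the entire pipeline testable
without any imaging data.

## Worked example

```python
import numpy as np
import nspnet as nn

# two modules of two regions: within-module r = 0.8, between = 0.2
fc = np.array([[1.0, 0.8, 0.2, 0.2],
               [0.8, 1.0, 0.2, 0.2],
               [0.2, 0.2, 1.0, 0.8],
               [0.2, 0.2, 0.8, 1.0]])
m = nn.nsp_measures(fc)
print(f"H_In = {m.h_in:.4f}   H_Se = {m.h_se:.4f}   H_B = {m.h_b:.4f}")

# a full synthetic study: 49 + 49 subjects, 100 regions, T = 152
spec = nn.CohortSpec(seed=1)
hc, bd = nn.generate_cohort(spec)
res = nn.group_difference_analysis(hc, bd, spec.atlas())
print(res.stable.round(4))
row = res.ancova.query("scale=='global' and measure=='HSe'").iloc[0]
print(f"ANCOVA group effect on calibrated H_Se: F = {row.F:.1f}, p = {row.p:.3g}")
```

prints

```
H_In = 0.3025   H_Se = 0.2650   H_B = 0.0375
       HIn     HSe      HB
HC  0.0375  0.3083 -0.2708
BD  0.0138  0.3439 -0.3301
ANCOVA group effect on calibrated H_Se: F = 105.7, p = 4.14e-17
```

The toy two-block network is near balance (H_B ≈ 0.04): its dominant
mode and its modular split contribute almost equally. In the simulated
study the patient-like group was generated with weaker between-system
coupling; its stable network is accordingly more segregated (higher
H_Se, lower H_In), and after calibration the ANCOVA recovers that
planted group difference decisively while adjusting for the groups'
different head-motion levels.

There is also a thin CLI: `nspnet simulate --out DIR --seed 0` writes a
cohort of per-subject TSV time series with a manifest, and
`nspnet predict --features X.tsv --score Y.tsv --out PREFIX` runs the
best-K LOO-CV prediction with permutation significance.

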