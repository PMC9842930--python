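"""Group comparison and symptom-association statistics.

Group differences in network measures are tested with an ANCOVA
(OLS of the measure on group plus mean framewise displacement, FD),
because head motion differs between patient and control groups and
would otherwise confound the comparison; age and sex can be added as
covariates. Symptom associations use Pearson correlation, and a
likelihood-ratio test (LRT) between nested linear and quadratic
regressions detects U-shaped relationships between symptom scores and
balance measures: under Gaussian maximum likelihood the statistic
2(ℓ_quad − ℓ_lin) is χ²(1) under the linear null.

Regional maps are reported uncorrected by default (mirroring common
practice for exploratory maps); Benjamini–Hochberg FDR is available as
an opt-in switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["AssociationResult", "ancova_compare", "quadratic_lrt",
           "correlate", "fdr_correct"]


@dataclass
class AssociationResult:
    """Outcome of the linear-vs-quadratic association test."""

    coef_linear: np.ndarray       # [intercept, b] of y ~ x
    coef_quadratic: np.ndarray    # [intercept, b, a] of y ~ x + x^2
    p_linear: float               # slope p in the linear model
    p_quadratic: float            # x^2 term p in the quadratic model
    lrt_stat: float
    p_lrt: float
    r: float                      # Pearson r of y with x
    minimum: float | None         # -b/(2a) when a > 0 (U-shape vertex)


def ancova_compare(values, group, fd, age=None, sex=None):
    """Group effect (F, p) from OLS of ``values ~ group + FD [+ age + sex]``.

    ``group`` is any two-level labelling; FD is the mean framewise
    displacement covariate. Returns the partial F statistic and p-value
    of the group term.
    """
    y = np.asarray(values, dtype=float)
    g = pd.Categorical(np.asarray(group))
    if len(g.categories) != 2:
        raise ValueError("group must have exactly two levels")
    codes = g.codes.astype(float)
    if min((codes == 0).sum(), (codes == 1).sum()) < 2:
        raise ValueError("each group needs at least two members")
    cols = {"group": codes, "fd": np.asarray(fd, dtype=float)}
    if age is not None:
        cols["age"] = np.asarray(age, dtype=float)
    if sex is not None:
        cols["sex"] = pd.Categorical(np.asarray(sex)).codes.astype(float)
    # a constant covariate carries no information and would only make the
    # design singular; dropping it reduces the model to a plain comparison
    cols = {k: v for k, v in cols.items()
            if k == "group" or np.ptp(v) > 0}
    x = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, x).fit()
    f = float(fit.tvalues["group"] ** 2)
    p = float(fit.pvalues["group"])
    return f, p


def _gaussian_llf(resid: np.ndarray) -> float:
    n = resid.shape[0]
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return -n / 2.0 * (np.log(2.0 * np.pi * sigma2) + 1.0)


def quadratic_lrt(x, y) -> AssociationResult:
    """Compare y ~ x against y ~ x + x² by a Gaussian likelihood-ratio test.

    The LRT statistic 2(ℓ_quad − ℓ_lin) is referred to χ²(1). When the
    quadratic coefficient is positive the vertex −b/(2a) of the fitted
    parabola (the U-shape minimum) is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    x_lin = sm.add_constant(x)
    x_quad = sm.add_constant(np.column_stack([x, x**2]))
    fit_lin = sm.OLS(y, x_lin).fit()
    fit_quad = sm.OLS(y, x_quad).fit()
    rss_lin = float(fit_lin.resid @ fit_lin.resid)
    if rss_lin <= 1e-12 * max(float(y @ y), 1.0):
        # the linear model is already an exact fit; the quadratic term
        # can only chase rounding error, so the models are equivalent
        stat = 0.0
    else:
        stat = max(0.0, 2.0 * (_gaussian_llf(fit_quad.resid) -
                               _gaussian_llf(fit_lin.resid)))
    p_lrt = float(sps.chi2.sf(stat, df=1))
    a = float(fit_quad.params[2])
    b = float(fit_quad.params[1])
    minimum = -b / (2.0 * a) if a > 0 else None
    r, _ = correlate(x, y)
    return AssociationResult(
        coef_linear=np.asarray(fit_lin.params, dtype=float),
        coef_quadratic=np.asarray(fit_quad.params, dtype=float),
        p_linear=float(fit_lin.pvalues[1]),
        p_quadratic=float(fit_quad.pvalues[2]),
        lrt_stat=float(stat),
        p_lrt=p_lrt,
        r=float(r),
        minimum=minimum,
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fdr_correct(pvalues, alpha: float = 0.05):
    """Benjamini–Hochberg adjusted p-values (opt-in; maps default to raw)."""
    rej, p_adj, _, _ = multipletests(np.asarray(pvalues, dtype=float),
                                     alpha=alpha, method="fdr_bh")
    return rej, p_adj
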