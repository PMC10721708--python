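"""Donor-effect statistics on the per-donor per-fold accuracy grid.

The per-donor accuracies A_{d,f} (d donors, f cross-validation folds) are
modelled as a mixed linear model

    A_{d,f} = mu + alpha_d + a_f + eps_{d,f},
    a_f ~ N(0, sigma_A^2),  eps ~ N(0, sigma^2),

with the donor effects alpha_d fixed (sum-to-zero coding) and the fold
effect a random. Three questions are answered:

1.  Is there a fold effect?  A restricted-maximum-likelihood likelihood-
    ratio test of sigma_A^2 = 0. Because the null value lies on the edge
    of the parameter space, the chi-square(1) tail p-value is halved
    (its asymptotic null distribution is an equal mixture of a point mass
    at 0 and chi-square(1)), so p is bounded by 0.5.
2.  Is there a donor effect?  A one-way fixed-effects ANOVA over donors
    with folds as replicates (df = D-1, D(F-1)).
3.  Do the two classes differ?  A between-class one-factor ANOVA on the D
    donor-averaged accuracies (df = 1, D-2).

The design is exactly balanced (every donor appears in every fold), so the
REML profile and all ANOVA quantities have closed forms, implemented here
directly; unbalanced grids are refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixedModelResult",
    "AnovaTable",
    "lrt_random_effect",
    "anova_donor_fixed",
    "anova_class_difference",
    "halved_chi2_p",
]


def halved_chi2_p(lrt: float, df: int = 1) -> float:
    """Boundary-test p-value: half the upper chi-square tail at the LRT."""
    if lrt < 0:
        raise ValueError("LRT statistic must be non-negative")
    return 0.5 * float(stats.chi2.sf(lrt, df))


@dataclass
class MixedModelResult:
    """REML fit of the balanced two-way model and its boundary LRT.

    ``loglik_null``/``aic_null`` describe the reduced model (sigma_A^2 = 0)
    whose removal the LRT tests; ``aic_null`` uses -2 logLik + 2k with
    k = D mean parameters + 1 variance parameter. The restricted
    log-likelihoods are defined through orthonormal error contrasts, so
    they are comparable between the two fits (the LRT is invariant to the
    contrast convention) but their absolute level follows this package's
    constant.
    """

    mu: float
    alpha: np.ndarray           # donor fixed effects, sum-to-zero
    sigma2_A: float             # fold random-effect variance
    sigma2: float               # residual variance
    loglik_full: float
    loglik_null: float
    aic_null: float
    lrt: float
    df: int
    p_boundary: float
    n_donors: int
    n_folds: int


def _check_grid(acc: np.ndarray) -> np.ndarray:
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2:
        raise ValueError("accuracy grid must be 2-D (donors x folds)")
    if not np.isfinite(acc).all():
        raise ValueError("accuracy grid is unbalanced or has missing cells; "
                         "the closed forms require a complete balanced grid")
    return acc


def _reml_loglik(ss_fold, ss_resid, df_fold, df_resid, lam, sig2):
    """Restricted log-likelihood in the orthonormal contrast basis.

    ``lam = sigma^2 + D * sigma_A^2`` is the variance of the fold-contrast
    components, ``sig2`` that of the interaction components.
    """
    return -0.5 * (
        df_fold * (np.log(2 * np.pi) + np.log(lam)) + ss_fold / lam
        + df_resid * (np.log(2 * np.pi) + np.log(sig2)) + ss_resid / sig2
    )


def lrt_random_effect(acc) -> MixedModelResult:
    """Boundary likelihood-ratio test of the fold variance component.

    Fits the balanced two-way model by REML, profiling over
    sigma_A^2 >= 0: the error contrasts orthogonal to the donor design
    decompose into F-1 fold-mean contrasts with variance
    sigma^2 + D sigma_A^2 and (D-1)(F-1) interaction contrasts with
    variance sigma^2, so the interior optimum is the method-of-moments
    solution and the boundary case has a pooled variance. The LRT against
    sigma_A^2 = 0 is referred to half a chi-square(1) tail.

    Grids with zero interaction variance (e.g. every accuracy identical)
    have an unbounded likelihood; they return the limiting decision
    (p = 0.5 with no fold variation, p = 0 with fold-only variation) and
    NaN log-likelihoods.
    """
    acc = _check_grid(acc)
    D, F = acc.shape
    if F < 2 or D < 2:
        raise ValueError("need at least 2 donors and 2 folds")
    grand = acc.mean()
    row = acc.mean(axis=1)          # donor means
    col = acc.mean(axis=0)          # fold means
    ss_fold = D * float(((col - grand) ** 2).sum())
    resid = acc - row[:, None] - col[None, :] + grand
    ss_resid = float((resid ** 2).sum())
    df_fold, df_resid = F - 1, (D - 1) * (F - 1)

    if ss_resid <= 0.0:
        # degenerate grids (e.g. every accuracy identical, or zero
        # interaction variance): the Gaussian likelihood is unbounded, so
        # report the limiting test decision instead of a variance fit
        degenerate_fold_evidence = ss_fold > 0.0
        return MixedModelResult(
            mu=float(grand), alpha=row - grand,
            sigma2_A=(ss_fold / df_fold / D if degenerate_fold_evidence
                      else 0.0),
            sigma2=0.0,
            loglik_full=float("nan"), loglik_null=float("nan"),
            aic_null=float("nan"),
            lrt=float("inf") if degenerate_fold_evidence else 0.0,
            df=1,
            p_boundary=0.0 if degenerate_fold_evidence else 0.5,
            n_donors=D, n_folds=F,
        )

    ms_fold = ss_fold / df_fold
    ms_resid = ss_resid / df_resid
    if ms_fold >= ms_resid:         # interior REML optimum
        sigma2 = ms_resid
        sigma2_A = (ms_fold - ms_resid) / D
        lam = ms_fold
    else:                           # boundary: sigma_A^2 = 0, pooled variance
        sigma2_A = 0.0
        sigma2 = (ss_fold + ss_resid) / (df_fold + df_resid)
        lam = sigma2
    ll_full = _reml_loglik(ss_fold, ss_resid, df_fold, df_resid, lam, sigma2)

    sigma2_null = (ss_fold + ss_resid) / (df_fold + df_resid)
    ll_null = _reml_loglik(ss_fold, ss_resid, df_fold, df_resid,
                           sigma2_null, sigma2_null)

    lrt = max(2.0 * (ll_full - ll_null), 0.0)
    k_null = D + 1                  # D mean parameters + 1 variance
    return MixedModelResult(
        mu=float(grand),
        alpha=row - grand,
        sigma2_A=float(sigma2_A),
        sigma2=float(sigma2),
        loglik_full=float(ll_full),
        loglik_null=float(ll_null),
        aic_null=float(-2 * ll_null + 2 * k_null),
        lrt=float(lrt),
        df=1,
        p_boundary=halved_chi2_p(lrt),
        n_donors=D,
        n_folds=F,
    )


@dataclass
class AnovaTable:
    """Classical ANOVA table: one row per term plus a residual row."""

    terms: list                 # term names, residual last
    df: list
    ss: list
    ms: list
    f_stat: float
    p_value: float
    degenerate: bool = False
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.terms)
        return pd.DataFrame({
            "term": self.terms,
            "df": self.df,
            "sum_sq": self.ss,
            "mean_sq": self.ms,
            "F": [self.f_stat] + [np.nan] * (n - 1),
            "p": [self.p_value] + [np.nan] * (n - 1),
        })


def _f_table(term, ss_term, df_term, ss_resid, df_resid) -> AnovaTable:
    ms_term = ss_term / df_term
    degenerate = ss_resid <= 0
    if degenerate:
        ms_resid = 0.0
        f = float("inf") if ms_term > 0 else float("nan")
        p = 0.0 if ms_term > 0 else float("nan")
        notes = ["degenerate: zero residual variance"]
    else:
        ms_resid = ss_resid / df_resid
        f = ms_term / ms_resid
        p = float(stats.f.sf(f, df_term, df_resid))
        notes = []
    return AnovaTable(
        terms=[term, "residual"],
        df=[df_term, df_resid],
        ss=[float(ss_term), float(ss_resid)],
        ms=[float(ms_term), float(ms_resid)],
        f_stat=float(f), p_value=p, degenerate=degenerate, notes=notes,
    )


def anova_donor_fixed(acc) -> AnovaTable:
    """One-way donor ANOVA on the accuracy grid, folds as replicates.

    Tests the donor fixed effects alpha_d (the fold random effect having
    been found negligible): df = (D-1, D(F-1)), F = MS_donor / MS_resid.
    """
    acc = _check_grid(acc)
    D, F = acc.shape
    if F < 2:
        raise ValueError("need at least 2 folds as replicates")
    grand = acc.mean()
    row = acc.mean(axis=1)
    ss_donor = F * float(((row - grand) ** 2).sum())
    ss_resid = float(((acc - row[:, None]) ** 2).sum())
    return _f_table("donor", ss_donor, D - 1, ss_resid, D * (F - 1))


def anova_class_difference(donor_means, classes) -> AnovaTable:
    """Between-class ANOVA on donor-averaged accuracies.

    One observation per donor (its fold-averaged accuracy), one factor with
    two levels (fetal/adult): df = (1, D-2). Equivalent to the squared
    pooled-variance two-sample t test.
    """
    y = np.asarray(donor_means, dtype=float)
    classes = np.asarray(classes)
    levels = sorted(set(classes))
    if len(levels) != 2:
        raise ValueError("exactly two classes are required")
    for lv in levels:
        if (classes == lv).sum() < 2:
            raise ValueError(f"class {lv!r} has fewer than 2 donors")
    grand = y.mean()
    ss_class = 0.0
    ss_resid = 0.0
    for lv in levels:
        g = y[classes == lv]
        ss_class += len(g) * (g.mean() - grand) ** 2
        ss_resid += float(((g - g.mean()) ** 2).sum())
    return _f_table("class", ss_class, 1, ss_resid, len(y) - 2)
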