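"""Log-scale analysis of 2x2 crossover bioequivalence trials.

The fit is the classical crossover ANOVA: ordinary least squares of the
log metric on subject, period and treatment fixed effects.  For complete
balanced data this is numerically identical to the mixed model with
subject as a random effect, and the sequence term is aliased with the
subject effects, so a single parameterisation serves both conventions.
Bioequivalence is declared when the 90% CI of the geometric mean ratio
lies within [0.80, 1.25].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CrossoverFit", "BEDecision", "CrossoverDataError",
           "fit_2x2", "cv_intra", "be_decision"]

BE_LIMITS = (0.80, 1.25)


class CrossoverDataError(ValueError):
    """Crossover dataset unsuitable for analysis."""


@dataclass(frozen=True)
class CrossoverFit:
    metric: str | None      # e.g. "cmax" or "auc_last"
    gmr: float              # geometric mean ratio test/reference
    ci90: tuple[float, float]
    omega_resid: float      # residual SD on the log scale
    cv_intra: float         # % (log-normal intrasubject CV)
    df: int                 # residual degrees of freedom
    n_evaluable: int        # subjects contributing both periods


@dataclass(frozen=True)
class BEDecision:
    pass_cmax: bool
    pass_auc: bool

    @property
    def pass_both(self) -> bool:
        return self.pass_cmax and self.pass_auc


def cv_intra(omega_resid: float) -> float:
    """Intrasubject %CV from the residual log-scale SD.

    The exact log-normal relation 100*sqrt(exp(w^2)-1); approximately
    100*w for small w.
    """
    if omega_resid < 0:
        raise ValueError("omega_resid must be >= 0")
    return 100.0 * math.sqrt(math.expm1(omega_resid ** 2))


def fit_2x2(data: pd.DataFrame, metric: str | None = None,
            value_col: str = "value", test_label: str = "T",
            log_values: bool = False) -> CrossoverFit:
    """Fit the crossover ANOVA to one PK metric.

    Parameters
    ----------
    data : one row per subject x period with columns ``subject``,
        ``sequence``, ``period``, ``treatment`` and ``value_col``.
    test_label : the ``treatment`` value identifying the test arm.
    log_values : set True when ``value_col`` is already log-transformed.

    Subjects without exactly one test and one reference observation are
    dropped (complete-case).  Raises :class:`CrossoverDataError` with
    fewer than 3 evaluable subjects in either sequence.
    """
    df = data[["subject", "sequence", "period", "treatment", value_col]]
    df = df.dropna()

    # complete-case: one test and one reference record per subject
    grp = df.groupby("subject", sort=True)
    ok = grp["treatment"].transform(
        lambda s: len(s) == 2 and (s == test_label).sum() == 1)
    df = df[ok.to_numpy(dtype=bool)]
    if df.empty:
        raise CrossoverDataError("no evaluable subjects")

    subj_codes, subj_uniq = pd.factorize(df["subject"], sort=True)
    n = subj_uniq.size
    seq_per_subj = df.groupby("subject", sort=True)["sequence"].first()
    seq_counts = seq_per_subj.value_counts()
    if len(seq_counts) != 2 or seq_counts.min() < 3:
        raise CrossoverDataError(
            "need >= 3 evaluable subjects per sequence, got "
            f"{seq_counts.to_dict()}")

    y = df[value_col].to_numpy(dtype=float)
    if not log_values:
        if np.any(y <= 0):
            raise CrossoverDataError("metric values must be > 0 to log")
        y = np.log(y)

    periods = pd.factorize(df["period"], sort=True)[0]
    is_test = (df["treatment"] == test_label).to_numpy(dtype=float)

    # design: intercept | period2 | treatment | subject dummies (n-1)
    nobs = y.size
    X = np.zeros((nobs, 3 + n - 1))
    X[:, 0] = 1.0
    X[:, 1] = (periods == 1)
    X[:, 2] = is_test
    rows = np.flatnonzero(subj_codes > 0)
    X[rows, 2 + subj_codes[rows]] = 1.0

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = nobs - X.shape[1]
    if dof <= 0:
        raise CrossoverDataError("no residual degrees of freedom")
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(max(s2, 0.0) * xtx_inv[2, 2])

    est = float(beta[2])
    tcrit = float(stats.t.ppf(0.95, dof))
    lo, hi = est - tcrit * se, est + tcrit * se
    omega = math.sqrt(max(s2, 0.0))
    return CrossoverFit(
        metric=metric, gmr=math.exp(est), ci90=(math.exp(lo), math.exp(hi)),
        omega_resid=omega, cv_intra=cv_intra(omega), df=dof, n_evaluable=n)


def _within_limits(fit: CrossoverFit) -> bool:
    lo, hi = fit.ci90
    return BE_LIMITS[0] <= lo and hi <= BE_LIMITS[1]


def be_decision(fit_cmax: CrossoverFit, fit_auc: CrossoverFit) -> BEDecision:
    """Bioequivalence verdict: both 90% CIs within [0.80, 1.25]."""
    return BEDecision(pass_cmax=_within_limits(fit_cmax),
                      pass_auc=_within_limits(fit_auc))
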