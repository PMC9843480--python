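"""Logistic outcome models, likelihood-ratio tests and rank-based AUC.

The analysis compares, per endpoint, a reference logistic model
(baseline symptom grade + mean gland dose) with an extended model that
adds one z-normalised radiomics feature.  The added value of the feature
is judged by a likelihood-ratio test (deviance difference against a
chi-square law, 1 df) and by the apparent AUC of each model on the full
analysis set — deliberately without cross-validation, since the question
is whether a previously reported association is present at all, not how
an optimism-corrected model would transport.

Maximum-likelihood fitting is delegated to statsmodels' ``Logit``
(Newton IRLS); Wald p-values are the z-based coefficient tests it
reports.  The AUC uses the Mann-Whitney midrank formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "LogisticFit",
    "LrtResult",
    "RocResult",
    "DegenerateFeatureError",
    "zscore_normalise",
    "fit_logistic",
    "univariate_association",
    "likelihood_ratio_test",
    "auc",
]

CONVERGENCE_TOL = 1e-8
MAX_ITER = 100


class DegenerateFeatureError(ValueError):
    """A feature has no variance (or too few values) to normalise or test."""


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model: MLE coefficients and inference summaries."""

    params: pd.Series          # includes "intercept"
    llf: float                 # maximised Bernoulli log-likelihood
    bse: pd.Series             # coefficient standard errors
    pvalues: pd.Series         # Wald (z) p-values
    converged: bool
    n: int

    @property
    def deviance(self) -> float:
        # saturated log-likelihood is 0 for binary outcomes
        return -2.0 * self.llf

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(name for name in self.params.index if name != "intercept")


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_cases: int
    n_controls: int


def zscore_normalise(values, name: str = "feature") -> np.ndarray:
    """Centre and scale to unit SD (denominator n-1) across patients.

    Missing values (NaN) are ignored in the moments and stay missing.
    Raises :class:`DegenerateFeatureError` when fewer than two values are
    observed or the SD is zero.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise DegenerateFeatureError(f"'{name}': need >= 2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise DegenerateFeatureError(f"'{name}' is constant across patients")
    return (x - obs.mean()) / sd


def fit_logistic(design: pd.DataFrame, outcome) -> LogisticFit:
    """Fit a logistic model by maximum likelihood; intercept added internally.

    ``design`` holds the predictors only (possibly zero columns for an
    intercept-only model).  Perfect separation or non-convergence yields a
    flagged fit (``converged=False``) whose log-likelihood at the iteration
    boundary still supports likelihood-ratio testing.
    """
    design = pd.DataFrame(design)
    y = np.asarray(outcome, dtype=float)
    if design.shape[0] != y.size:
        raise ValueError("design and outcome lengths differ")
    if np.isnan(design.to_numpy()).any() or np.isnan(y).any():
        raise ValueError("missing cells in design or outcome; drop them listwise first")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size < 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    X = sm.add_constant(design, has_constant="add").rename(columns={"const": "intercept"})
    model = sm.Logit(y, X)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, tol=CONVERGENCE_TOL, maxiter=MAX_ITER)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=MAX_ITER)
            converged = False
    return LogisticFit(
        params=pd.Series(res.params, index=X.columns),
        llf=float(res.llf),
        bse=pd.Series(res.bse, index=X.columns),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        converged=converged,
        n=int(y.size),
    )


def univariate_association(feature, outcome, name: str = "feature") -> float:
    """Wald p-value of a single z-normalised predictor in a logistic model.

    Patients with a missing feature value are dropped listwise.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(outcome, dtype=float)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    z = zscore_normalise(x, name)
    fit = fit_logistic(pd.DataFrame({name: z}), y)
    return float(fit.pvalues[name])


def likelihood_ratio_test(reference: LogisticFit, extended: LogisticFit) -> LrtResult:
    """Deviance-based test of nested logistic models against chi-square."""
    ref_set, ext_set = set(reference.predictors), set(extended.predictors)
    if not ref_set < ext_set:
        raise ValueError(
            f"models are not strictly nested: reference {sorted(ref_set)} "
            f"vs extended {sorted(ext_set)}"
        )
    if reference.n != extended.n:
        raise ValueError("nested models were fitted on different numbers of patients")
    statistic = 2.0 * (extended.llf - reference.llf)
    if statistic < -1e-6:
        raise ValueError(f"extended model has lower likelihood ({statistic=}); check fits")
    statistic = max(statistic, 0.0)
    df = len(ext_set) - len(ref_set)
    return LrtResult(statistic, df, float(scipy.stats.chi2.sf(statistic, df)))


def auc(scores, labels) -> RocResult:
    """Mann-Whitney AUC with midranks for ties.

    ``AUC = (R1 - n1(n1+1)/2) / (n1 * n0)`` where ``R1`` is the rank sum of
    the cases; the probability that a random case outscores a random
    control, counting ties as half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.size != y.size:
        raise ValueError("scores and labels lengths differ")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0 or n1 + n0 != y.size:
        raise ValueError("labels must be 0/1 with both classes present")
    ranks = scipy.stats.rankdata(s)  # midranks
    r1 = ranks[y == 1].sum()
    value = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return RocResult(float(value), n1, n0)
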