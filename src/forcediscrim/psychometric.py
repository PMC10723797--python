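"""Maximum-likelihood logistic psychometric fits, PSE/JND, McFadden's R².

The psychometric model for a 2AFC force-discrimination block is a binomial
GLM with a logit link:

    p(x) = exp(b0 + b1*x) / (1 + exp(b0 + b1*x))

where ``x`` is the (binned) comparison-force magnitude and ``p`` the
probability of reporting the comparison as stronger than the 2 N test force.
Two derived quantities summarise a fit: the point of subjective equality
PSE = -b0/b1 (the comparison magnitude judged equal to the test, p = 0.5) and
the just noticeable difference JND = ln(3)/b1 (the 50%-to-75% distance on the
curve, a discrimination-sensitivity measure; natural log, since
logit(0.75) = ln 3).  Fit quality is McFadden's pseudo-R²,
1 - loglik(model)/loglik(intercept-only).

Fitting is iteratively reweighted least squares (Newton) with step-halving.
The canonical-link binomial likelihood is concave, so a failure to converge
indicates complete or quasi-complete separation or a degenerate design, not a
local optimum; separation is detected explicitly and flagged instead of
returning divergent estimates.  Trial-level and level-aggregated data give
identical likelihood maxima — trials are aggregated to per-level counts
internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("forcediscrim")

__all__ = [
    "PsychometricFit",
    "DerivedMeasures",
    "FitDataError",
    "SeparationError",
    "fit_psychometric",
    "fit_counts",
    "derive",
    "predict_prob",
    "fit_table",
    "FIT_TABLE_COLUMNS",
]

RESPONSE_COMPARISON = "comparison_stronger"

#: Divergence guard: |beta| beyond this is treated as separation.
_BETA_BOUND = 50.0


class FitDataError(ValueError):
    """Raised when the data cannot support a two-parameter fit."""


class SeparationError(ValueError):
    """Raised when derived measures are requested from a separated/invalid fit."""


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted (or flagged) logistic psychometric function."""

    beta0: float
    beta1: float
    loglik_model: float
    loglik_null: float
    converged: bool
    separation_flag: bool
    n_trials: int
    per_level_counts: Mapping[float, tuple[int, int]]  # level -> (k_comparison, n)
    n_iter: int = 0


@dataclass(frozen=True)
class DerivedMeasures:
    """PSE, JND and McFadden's R² derived from a converged fit."""

    pse: float
    jnd: float
    mcfadden_r2: float


def _binom_loglik(beta: np.ndarray, x: np.ndarray, k: np.ndarray,
                  n: np.ndarray) -> float:
    eta = beta[0] + beta[1] * x
    # log(1+e^eta) computed stably
    return float(np.sum(k * eta - n * np.logaddexp(0.0, eta)))


def _null_loglik(k: np.ndarray, n: np.ndarray) -> float:
    K, N = k.sum(), n.sum()
    if K == 0 or K == N:
        return 0.0
    pbar = K / N
    return float(K * np.log(pbar) + (N - K) * np.log(1 - pbar))


def _detect_separation(x: np.ndarray, k: np.ndarray, n: np.ndarray) -> bool:
    """Complete / quasi-complete separation on aggregated counts.

    True when the observed proportions are all 0 or 1 and consistent with a
    perfect threshold in either direction (including the all-0 / all-1 case).
    """
    props = k / n
    if not np.all((props == 0) | (props == 1)):
        return False
    order = np.argsort(x)
    p = props[order]
    return bool(np.all(np.diff(p) >= 0) or np.all(np.diff(p) <= 0))


def fit_counts(
    levels: Sequence[float],
    k_comparison: Sequence[int],
    n_total: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PsychometricFit:
    """Fit the logistic from per-level aggregated counts.

    ``k_comparison[i]`` of ``n_total[i]`` responses at ``levels[i]`` reported
    the comparison as stronger.  Starts from (0, 0); converges when the
    gradient norm drops below ``tol``.
    """
    x = np.asarray(levels, dtype=float)
    k = np.asarray(k_comparison, dtype=float)
    n = np.asarray(n_total, dtype=float)
    keep = n > 0
    x, k, n = x[keep], k[keep], n[keep]
    if np.unique(x).size < 2:
        raise FitDataError("need responses at >= 2 distinct comparison levels")
    if np.any(k < 0) or np.any(k > n):
        raise FitDataError("counts must satisfy 0 <= k <= n")
    ll_null = _null_loglik(k, n)
    counts = {float(xi): (int(ki), int(ni)) for xi, ki, ni in zip(x, k, n)}
    n_trials = int(n.sum())
    if _detect_separation(x, k, n):
        return PsychometricFit(
            beta0=np.nan, beta1=np.nan, loglik_model=np.nan, loglik_null=ll_null,
            converged=False, separation_flag=True, n_trials=n_trials,
            per_level_counts=counts,
        )
    beta = np.zeros(2)
    ll = _binom_loglik(beta, x, k, n)
    X = np.column_stack([np.ones_like(x), x])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (k - n * p)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "IRLS iter %d: beta=(%.6g, %.6g) loglik=%.6g |grad|=%.3g",
                it, beta[0], beta[1], ll, np.linalg.norm(grad),
            )
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = n * p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _binom_loglik(cand, x, k, n)
            if ll_new >= ll - 1e-12:
                beta, ll = cand, ll_new
                break
            scale /= 2.0
        else:
            break
        if np.max(np.abs(beta)) > _BETA_BOUND:
            return PsychometricFit(
                beta0=np.nan, beta1=np.nan, loglik_model=np.nan,
                loglik_null=ll_null, converged=False, separation_flag=True,
                n_trials=n_trials, per_level_counts=counts, n_iter=it,
            )
    else:
        it = max_iter
    # final gradient check in case the loop exited by break
    if not converged:
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        converged = bool(
            np.linalg.norm(X.T @ (k - n * p)) < max(tol, 1e-6)
        )
    return PsychometricFit(
        beta0=float(beta[0]), beta1=float(beta[1]), loglik_model=ll,
        loglik_null=ll_null, converged=converged, separation_flag=False,
        n_trials=n_trials, per_level_counts=counts, n_iter=it,
    )


def fit_psychometric(
    data: pd.DataFrame,
    level_col: str = "comparison_level",
    response_col: str = "response",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PsychometricFit:
    """Fit one participant-by-condition block of clean trials.

    ``data`` holds one row per trial with the binned comparison level and the
    categorical response; missing responses must already be excluded.
    """
    if data[response_col].isna().any():
        raise FitDataError("missing responses must be excluded before fitting")
    y = (data[response_col] == RESPONSE_COMPARISON).to_numpy(dtype=float)
    x = data[level_col].to_numpy(dtype=float)
    levels, inv = np.unique(x, return_inverse=True)
    k = np.bincount(inv, weights=y, minlength=levels.size)
    n = np.bincount(inv, minlength=levels.size).astype(float)
    return fit_counts(levels, k, n, tol=tol, max_iter=max_iter)


def derive(fit: PsychometricFit) -> DerivedMeasures:
    """PSE = -b0/b1, JND = ln(3)/b1, McFadden's R² = 1 - ll_model/ll_null.

    Requires a converged fit with positive slope; a separated or flat fit has
    no finite PSE/JND and raises :class:`SeparationError`.
    """
    if fit.separation_flag or not fit.converged:
        raise SeparationError(
            "fit did not converge (separation or degenerate data); "
            "no derived measures"
        )
    if not fit.beta1 > 0:
        raise SeparationError("non-positive slope: PSE/JND undefined")
    pse = -fit.beta0 / fit.beta1
    jnd = float(np.log(3.0)) / fit.beta1
    if fit.loglik_null == 0.0:
        r2 = 1.0 if fit.loglik_model == 0.0 else np.nan
    else:
        r2 = 1.0 - fit.loglik_model / fit.loglik_null
    return DerivedMeasures(pse=float(pse), jnd=float(jnd), mcfadden_r2=float(r2))


def predict_prob(fit: PsychometricFit, x: float | np.ndarray) -> float | np.ndarray:
    """Fitted probability of reporting the comparison stronger at force x."""
    if fit.separation_flag or not np.isfinite(fit.beta0):
        raise SeparationError("cannot predict from a separated fit")
    eta = fit.beta0 + fit.beta1 * np.asarray(x, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    if np.isscalar(x):
        return float(p)
    return p


FIT_TABLE_COLUMNS = (
    "participant_id", "condition", "beta0", "beta1", "pse", "jnd",
    "mcfadden_r2", "n_trials", "converged", "separation_flag",
)


def fit_table(
    clean_trials: pd.DataFrame,
    level_col: str = "comparison_level",
) -> pd.DataFrame:
    """Fit every participant-by-condition cell of a clean trial table.

    Returns the tidy per-fit table (one row per cell).  Cells whose fit is
    separated or fails to converge keep their row with NaN derived measures
    and the flags set, so downstream code can drop them explicitly.
    """
    rows = []
    for (pid, cond), grp in clean_trials.groupby(
        ["participant_id", "condition"], sort=True
    ):
        fit = fit_psychometric(grp, level_col=level_col)
        row = {
            "participant_id": pid, "condition": cond,
            "beta0": fit.beta0, "beta1": fit.beta1,
            "pse": np.nan, "jnd": np.nan, "mcfadden_r2": np.nan,
            "n_trials": fit.n_trials, "converged": fit.converged,
            "separation_flag": fit.separation_flag,
        }
        if fit.converged and not fit.separation_flag and fit.beta1 > 0:
            d = derive(fit)
            row.update(pse=d.pse, jnd=d.jnd, mcfadden_r2=d.mcfadden_r2)
        rows.append(row)
    return pd.DataFrame(rows, columns=FIT_TABLE_COLUMNS)
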