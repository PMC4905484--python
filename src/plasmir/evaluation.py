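"""Marker evaluation: logistic models, ROC/AUC and operating cutoffs.

For each clinical contrast (all patients vs controls; stage III–IV vs
I–II; stage IV vs I–III) the candidate markers are fitted one at a time
in a univariate logistic model logit(p) = β0 + β1·x on the −ΔΔCt scale,
the winner is picked by AUC (or AIC), and discrimination is summarized
by the empirical ROC curve, the rank-based AUC with a Hanley–McNeil
standard error and 95% CI, and the sensitivity/specificity at the
Youden-optimal cutoff.

Notes on conventions:

* AUC is the probability that a randomly chosen positive outscores a
  randomly chosen negative, with ties counted one half — identical to
  the trapezoidal area under the empirical ROC curve.
* The cutoff maximizes Youden's J = sensitivity + specificity − 1 over
  midpoints between adjacent distinct scores, with the decision rule
  "score ≥ cutoff ⟹ positive"; J-ties break toward higher sensitivity,
  then toward the lower cutoff.  A closest-to-(0,1) criterion is
  available as an alternative.
* Quasi-perfect separation is reported as an error rather than let the
  optimizer diverge silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import LabelError, SearchError, SeparationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------
# AUC machinery
# ---------------------------------------------------------------------

def _check_classes(y: np.ndarray) -> None:
    if not ((y == 0).any() and (y == 1).any()):
        raise LabelError("need both a positive and a negative class")


def auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """Rank-based AUC (concordance probability, ties counted 1/2)."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    _check_classes(y)
    ranks = stats.rankdata(scores)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_se_ci(
    auc_value: float, n_pos: int, n_neg: int
) -> tuple[float, float, float]:
    """Hanley–McNeil standard error and 95% CI for an AUC.

    Uses Q1 = A/(2−A) and Q2 = 2A²/(1+A); the CI is A ± 1.96·SE clipped
    to [0, 1].
    """
    a = float(auc_value)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return se, max(0.0, a - Z95 * se), min(1.0, a + Z95 * se)


def roc_points(scores: Sequence[float], y: Sequence[int]) -> pd.DataFrame:
    """Empirical ROC curve points (1−specificity, sensitivity)."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    _check_classes(y)
    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def youden_cutoff(
    scores: Sequence[float],
    y: Sequence[int],
    criterion: str = "youden",
) -> tuple[float, float, float]:
    """Operating cutoff and its sensitivity/specificity.

    Candidate cutoffs are the midpoints between adjacent distinct
    scores (decision rule: score ≥ cutoff → positive).
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    _check_classes(y)
    distinct = np.unique(scores)
    if len(distinct) == 1:
        cutoffs = np.array([distinct[0]])
    else:
        cutoffs = (distinct[:-1] + distinct[1:]) / 2.0
    pos = scores[y == 1]
    neg = scores[y == 0]
    sens = (pos[None, :] >= cutoffs[:, None]).mean(axis=1)
    spec = (neg[None, :] < cutoffs[:, None]).mean(axis=1)
    if criterion == "youden":
        objective = sens + spec - 1.0
    elif criterion == "closest":
        objective = -np.hypot(1.0 - sens, 1.0 - spec)
    else:
        raise ValueError(f"unknown cutoff criterion: {criterion!r}")
    # maximize objective; tie-break: higher sensitivity, then lower cutoff
    order = np.lexsort((cutoffs, -sens, -objective))
    best = order[0]
    return float(cutoffs[best]), float(sens[best]), float(spec[best])


@dataclass
class RocSummary:
    """Discrimination summary for one score set."""

    points: pd.DataFrame
    auc: float
    se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


def evaluate_scores(
    scores: Sequence[float], y: Sequence[int], cutoff_criterion: str = "youden"
) -> RocSummary:
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    a = auc(scores, y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    se, lo, hi = auc_se_ci(a, n_pos, n_neg)
    cut, sens, spec = youden_cutoff(scores, y, cutoff_criterion)
    return RocSummary(
        points=roc_points(scores, y),
        auc=a, se=se, ci_low=lo, ci_high=hi,
        cutoff=cut, sensitivity=sens, specificity=spec,
        n_pos=n_pos, n_neg=n_neg,
    )


# ---------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Fitted maximum-likelihood logistic model on the relative-level scale."""

    intercept: float
    coef: pd.Series
    converged: bool
    llf: float
    aic: float

    def linear_predictor(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = np.asarray(
            x[self.coef.index] if isinstance(x, pd.DataFrame) else x, float
        )
        if x.ndim == 1:
            x = x[:, None]
        return self.intercept + x @ self.coef.to_numpy()

    def predict_proba(self, x) -> np.ndarray:
        eta = self.linear_predictor(x)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(x, y) -> LogisticModel:
    """Maximum-likelihood logistic fit with explicit separation detection.

    ``x`` is a 1-D/2-D array or DataFrame of marker levels; ``y`` binary
    labels.  Raises :class:`SeparationError` on (quasi-)perfect
    separation and :class:`LabelError` on degenerate labels.
    """
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        xmat = x.to_numpy(float)
    else:
        xmat = np.asarray(x, float)
        if xmat.ndim == 1:
            xmat = xmat[:, None]
        names = [f"x{i}" for i in range(xmat.shape[1])]
    y = np.asarray(y, int)
    _check_classes(y)
    if np.any(np.ptp(xmat, axis=0) == 0):
        raise ValueError("constant predictor column")
    design = sm.add_constant(xmat, has_constant="add")
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError("perfect separation in logistic fit") from exc
    params = np.asarray(res.params, float)
    fitted = np.asarray(res.predict(), float)
    if np.max(np.abs(params)) > 1e4 or np.all(np.abs(fitted - y) < 1e-8):
        raise SeparationError("quasi-perfect separation in logistic fit")
    return LogisticModel(
        intercept=float(params[0]),
        coef=pd.Series(params[1:], index=names),
        converged=bool(res.mle_retvals.get("converged", True)),
        llf=float(res.llf),
        aic=float(res.aic),
    )


class SingleMarkerEvaluator(BaseEstimator):
    """Search candidate markers for the best univariate logistic model.

    ``fit(X, y)`` fits each candidate column alone, ranks them on the
    chosen criterion (``auc`` maximized or ``aic`` minimized) and keeps
    the winner.  ``leaderboard_`` lists every candidate; fit failures
    (e.g. separation) are recorded, not fatal, unless every fit fails.
    """

    def __init__(self, criterion: str = "auc", cutoff_criterion: str = "youden"):
        self.criterion = criterion
        self.cutoff_criterion = cutoff_criterion

    def fit(self, X: pd.DataFrame, y) -> "SingleMarkerEvaluator":
        if X.shape[1] < 1:
            raise SearchError("no candidate markers given")
        if self.criterion not in ("auc", "aic"):
            raise ValueError(f"unknown criterion: {self.criterion!r}")
        y = np.asarray(y, int)
        rows, models = [], {}
        for marker in X.columns:
            try:
                model = fit_logistic(X[[marker]], y)
            except Exception as exc:  # leaderboards record failures
                rows.append(
                    {"marker": marker, "auc": np.nan, "aic": np.nan,
                     "converged": False, "error": type(exc).__name__}
                )
                continue
            score = model.predict_proba(X[[marker]])
            rows.append(
                {"marker": marker, "auc": auc(score, y), "aic": model.aic,
                 "converged": model.converged, "error": ""}
            )
            models[marker] = model
        board = pd.DataFrame(rows)
        if not models:
            raise SearchError("every candidate logistic fit failed")
        ok = board[board["error"] == ""]
        if self.criterion == "auc":
            ok = ok.sort_values(["auc", "marker"], ascending=[False, True])
        else:
            ok = ok.sort_values(["aic", "marker"], ascending=[True, True])
        winner = ok.iloc[0]["marker"]
        self.leaderboard_ = board
        self.best_marker_ = winner
        self.best_model_ = models[winner]
        self.summary_ = evaluate_scores(
            self.best_model_.predict_proba(X[[winner]]), y, self.cutoff_criterion
        )
        return self


def best_single_marker(
    X: pd.DataFrame, y, criterion: str = "auc"
) -> tuple[str, LogisticModel, pd.DataFrame]:
    """Functional wrapper: (winning marker, its model, full leaderboard)."""
    ev = SingleMarkerEvaluator(criterion=criterion).fit(X, y)
    return ev.best_marker_, ev.best_model_, ev.leaderboard_
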