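"""Survival analysis: mean-dichotomized KM/log-rank and Cox regression.

Markers are dichotomized at the mean of the patients' relative levels
(value strictly above the mean → "high"; a value exactly at the mean
falls in the "low" arm).  Overall survival is compared between the two
arms with the Kaplan–Meier estimator and the two-group log-rank test,
and independent prognostic value is assessed with a multivariable
proportional-hazards model using the standard clinical contrasts:

* stage III–IV vs I–II
* CEA > 5 µg/L vs ≤ 5 µg/L
* age ≥ 55 vs < 55 years
* female vs male
* chemotherapy yes vs no
* each marker high vs low

The first-listed level of each contrast is coded 1.  ``risk ratio``
(hazard ratio) = exp(coefficient) with a Wald 95% CI and p-value.
Tied event times are handled with Efron's approximation (the lifelines
default); simulated survival times are continuous, where all tie
methods coincide.  Patients with missing survival or covariate data are
dropped from the survival analyses only, with a report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DataError, DesignError, FitError, GroupError
from .io import SampleTable


def dichotomize_by_mean(levels: pd.Series | Sequence[float]) -> pd.Series:
    """Split patients into low/high arms at the mean relative level.

    ``high`` ⟺ level strictly greater than the mean; boundary values go
    to ``low``.  A degenerate split (every patient on one side) is
    reported as a warning — downstream two-group analyses will refuse it.
    """
    levels = pd.Series(levels, dtype=float)
    if len(levels) < 2:
        raise DataError("dichotomization needs at least 2 patients")
    if not np.isfinite(levels).all():
        raise DataError("non-finite marker levels")
    labels = pd.Series(
        np.where(levels > levels.mean(), "high", "low"), index=levels.index
    )
    if labels.nunique() == 1:
        warnings.warn("degenerate mean split: every patient in one arm",
                      stacklevel=2)
    return labels


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    times: np.ndarray       # distinct event/censor times (months)
    at_risk: np.ndarray     # number at risk entering each time
    survival: np.ndarray    # S(t) just after each time
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events, label: str = "") -> KMCurve:
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise DataError("empty survival data")
    if (times < 0).any():
        raise DataError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or "KM")
    table = kmf.event_table.iloc[1:] if 0 not in times else kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    grid = np.asarray(surv.index, float)
    keep = grid > 0 if 0 not in times else np.ones(len(grid), bool)
    return KMCurve(
        times=grid[keep],
        at_risk=kmf.event_table["at_risk"].to_numpy()[keep],
        survival=surv.to_numpy()[keep],
        label=label,
    )


def _logrank_chi2(
    times: np.ndarray, events: np.ndarray, in_a: np.ndarray
) -> float:
    """Two-group log-rank statistic from hypergeometric moments.

    Kept as a small self-contained routine so permutation replicates are
    cheap; the headline chi-square/p come from lifelines and the two are
    asserted to agree in the test suite.
    """
    order = np.argsort(times, kind="stable")
    t, e, a = times[order], events[order], in_a[order]
    o_minus_e = 0.0
    var = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        if d > 0:
            at_risk = n - i
            at_risk_a = a[i:].sum()
            d_a = (e[i:j] & a[i:j].astype(bool)).sum()
            exp_a = d * at_risk_a / at_risk
            o_minus_e += d_a - exp_a
            if at_risk > 1:
                var += (
                    d * (at_risk_a / at_risk)
                    * (1 - at_risk_a / at_risk)
                    * (at_risk - d) / (at_risk - 1)
                )
        i = j
    return float(o_minus_e**2 / var) if var > 0 else 0.0


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    p_permutation: float | None = None


def logrank(
    times,
    events,
    group_labels,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df).

    With ``n_permutations`` set, a group-label permutation p-value is
    computed in addition — useful at small n where the chi-square
    approximation is rough.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group_labels = np.asarray(group_labels)
    levels = pd.unique(group_labels)
    if len(levels) != 2:
        raise GroupError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    in_a = group_labels == levels[0]
    if in_a.all() or (~in_a).all():
        raise GroupError("one log-rank group is empty")
    res = _ll_logrank(
        times[in_a], times[~in_a], events[in_a], events[~in_a]
    )
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    p_perm = None
    if n_permutations:
        rng = np.random.default_rng(seed)
        observed = _logrank_chi2(times, events, in_a.astype(np.int8))
        labels = in_a.astype(np.int8)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            if _logrank_chi2(times, events, perm) >= observed - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_permutations + 1)
    return LogrankResult(chi_square=chi2, p_value=p, p_permutation=p_perm)


# ---------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------

COX_CONTRASTS = {
    "stage_iii_iv": "Stage (III-IV vs I-II)",
    "cea_gt5": "CEA (>5 ug/L vs <=5 ug/L)",
    "age_ge55": "Age (>=55 vs <55 years)",
    "sex_female": "Sex (female vs male)",
    "chemo_yes": "Chemotherapy (yes vs no)",
}


def build_design(
    samples: SampleTable,
    marker_labels: Mapping[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Binary design matrix for the multivariable Cox model.

    Takes the patient rows of a sample table plus per-marker low/high
    labels and returns ``(design, os_time, os_event, dropped_ids)``.
    Each contrast's first-listed level is coded 1; CEA exactly 5 µg/L
    falls in the ≤ 5 (0) arm.  Patients missing any required field are
    dropped and reported.
    """
    df = samples.df[samples.is_patient].copy()
    marker_labels = dict(marker_labels or {})
    required = ["group", "sex", "age", "cea", "chemotherapy", "os_time", "os_event"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DesignError(f"sample table lacks required column(s): {missing_cols}")
    design = pd.DataFrame(index=df.index)
    design["stage_iii_iv"] = df["group"].isin(["III", "IV"]).astype(int)
    design["cea_gt5"] = (df["cea"] > 5.0).astype(int)
    design["age_ge55"] = (df["age"] >= 55).astype(int)
    design["sex_female"] = (df["sex"] == "female").astype(int)
    design["chemo_yes"] = (df["chemotherapy"] == 1).fillna(False).astype(int)
    for marker, labels in marker_labels.items():
        design[f"{marker}_high"] = (
            labels.reindex(df.index) == "high"
        ).astype(int)
    complete = (
        df[required].notna().all(axis=1)
        & pd.DataFrame(
            {m: labels.reindex(df.index).notna() for m, labels in
             marker_labels.items()} or {"_": pd.Series(True, index=df.index)}
        ).all(axis=1)
    )
    dropped = list(df.index[~complete])
    if complete.sum() == 0:
        raise DesignError("every patient dropped while building the Cox design")
    return (
        design[complete],
        df.loc[complete, "os_time"].astype(float),
        df.loc[complete, "os_event"].astype(int),
        dropped,
    )


@dataclass
class CoxFit:
    """Proportional-hazards fit: risk ratios with Wald CIs and p-values."""

    table: pd.DataFrame  # factor, coef, risk_ratio, ci_low, ci_high, p_value
    n: int
    n_events: int
    ties: str = "efron"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def cox_fit(design: pd.DataFrame, times, events) -> CoxFit:
    """Fit a Cox proportional-hazards model via partial likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() < 1:
        raise FitError("no events observed")
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise FitError(f"constant covariate(s): {constant}")
    frame = design.copy()
    frame["_time"] = times
    frame["_event"] = events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="_time", event_col="_event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise FitError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "factor": summ.index,
            "coef": summ["coef"].to_numpy(),
            "risk_ratio": np.exp(summ["coef"].to_numpy()),
            "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
            "p_value": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return CoxFit(
        table=table, n=len(frame), n_events=int(events.sum()), ties="efron"
    )


def breslow_partial_loglik(
    beta: np.ndarray, x: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Breslow partial log-likelihood (reference implementation).

    Exposed for verification: with untied event times this equals the
    Efron likelihood that the fitter maximizes, so a direct maximizer of
    this function must agree with :func:`cox_fit`.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != len(times):
        x = x.T
    eta = x @ beta
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        at_risk = times >= times[i]
        ll += eta[i] - np.log(np.exp(eta[at_risk]).sum())
    return float(ll)
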