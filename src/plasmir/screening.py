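"""Pairwise group comparisons and marker-category screening.

The discovery phase asks seven questions of the relative-expression
matrix, each a two-sided, two-group comparison of clinical groups:

===========================  =========================  ============
comparison                   sides                      category
===========================  =========================  ============
control vs CRC               {control} vs {I,II,III,IV}  detection
control vs stage I–II        {control} vs {I,II}         early_stage
control vs stage III–IV      {control} vs {III,IV}       late_stage
stage I–II vs III–IV         {I,II} vs {III,IV}          late_stage
control vs stage IV          {control} vs {IV}           metastasis
stage I–III vs IV            {I,II,III} vs {IV}          metastasis
stage II vs III              {II} vs {III}               stage2_vs_3
===========================  =========================  ============

The default test is the two-sided Mann–Whitney (exact enumeration when
the combined n is at most 20 and the pooled values are tie-free, normal
approximation with tie correction otherwise); Student's t is available
by configuration.  No multiplicity correction is applied by default —
each of the 754 assays is screened at the nominal two-sided alpha —
but Benjamini–Hochberg can be switched on.  Rows with alpha ≤ p <
alpha_trend are flagged as "trend" but never auto-selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ComparisonError, ScalingError
from .io import RelativeExpressionMatrix, SampleTable

EXACT_MAX_N = 20

CATEGORIES = ("detection", "early_stage", "late_stage", "metastasis", "stage2_vs_3")


@dataclass(frozen=True)
class ComparisonSpec:
    """One two-group contrast over clinical group labels."""

    name: str
    side_a: frozenset
    side_b: frozenset
    category: str

    def __post_init__(self):
        object.__setattr__(self, "side_a", frozenset(self.side_a))
        object.__setattr__(self, "side_b", frozenset(self.side_b))
        if not self.side_a or not self.side_b:
            raise ValueError(f"{self.name}: both sides must be nonempty")
        if self.side_a & self.side_b:
            raise ValueError(f"{self.name}: sides overlap")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


def default_scheme() -> list[ComparisonSpec]:
    """The seven standard contrasts with their marker categories."""
    c = {"control"}
    return [
        ComparisonSpec("control_vs_crc", c, {"I", "II", "III", "IV"}, "detection"),
        ComparisonSpec("control_vs_stage_i_ii", c, {"I", "II"}, "early_stage"),
        ComparisonSpec("control_vs_stage_iii_iv", c, {"III", "IV"}, "late_stage"),
        ComparisonSpec(
            "stage_i_ii_vs_iii_iv", {"I", "II"}, {"III", "IV"}, "late_stage"
        ),
        ComparisonSpec("control_vs_stage_iv", c, {"IV"}, "metastasis"),
        ComparisonSpec("stage_i_iii_vs_iv", {"I", "II", "III"}, {"IV"}, "metastasis"),
        ComparisonSpec("stage_ii_vs_iii", {"II"}, {"III"}, "stage2_vs_3"),
    ]


def _split_sides(
    expr: RelativeExpressionMatrix, samples: SampleTable, spec: ComparisonSpec
) -> tuple[np.ndarray, np.ndarray]:
    in_matrix = set(expr.sample_ids)
    ids_a = [s for s in samples.ids_in_groups(spec.side_a) if s in in_matrix]
    ids_b = [s for s in samples.ids_in_groups(spec.side_b) if s in in_matrix]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ComparisonError(
            f"{spec.name}: need >= 2 samples per side "
            f"(got {len(ids_a)} vs {len(ids_b)})"
        )
    return (
        expr.values[ids_a].to_numpy(),
        expr.values[ids_b].to_numpy(),
    )


def _mann_whitney_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per row, exact where admissible."""
    n = a.shape[1] + b.shape[1]
    pooled = np.concatenate([a, b], axis=1)
    has_ties = np.array(
        [len(np.unique(row)) < n for row in pooled]
    )
    p = np.empty(a.shape[0])
    exact_rows = ~has_ties if n <= EXACT_MAX_N else np.zeros(a.shape[0], bool)
    if exact_rows.any():
        res = stats.mannwhitneyu(
            a[exact_rows], b[exact_rows], alternative="two-sided",
            method="exact", axis=1,
        )
        p[exact_rows] = np.atleast_1d(res.pvalue)
    rest = ~exact_rows
    if rest.any():
        res = stats.mannwhitneyu(
            a[rest], b[rest], alternative="two-sided",
            method="asymptotic", axis=1,
        )
        p[rest] = np.atleast_1d(res.pvalue)
    return np.minimum(p, 1.0)


def compare_groups(
    expr: RelativeExpressionMatrix,
    samples: SampleTable,
    spec: ComparisonSpec,
    test: str = "mann_whitney",
) -> pd.DataFrame:
    """Per-assay two-sided comparison of relative levels between two sides.

    The effect measure is the median relative level of side_b minus
    side_a; ``direction`` reports which side is higher (``tie`` when the
    medians coincide).
    """
    a, b = _split_sides(expr, samples, spec)
    if test == "mann_whitney":
        p = _mann_whitney_rows(a, b)
    elif test == "t_test":
        p = np.atleast_1d(stats.ttest_ind(a, b, axis=1).pvalue)
    else:
        raise ValueError(f"unknown test: {test!r}")
    effect = np.median(b, axis=1) - np.median(a, axis=1)
    direction = np.where(
        effect > 0, "up_in_b", np.where(effect < 0, "down_in_b", "tie")
    )
    return pd.DataFrame(
        {
            "assay": expr.assay_ids,
            "comparison": spec.name,
            "category": spec.category,
            "test": test,
            "p_value": p,
            "effect": effect,
            "direction": direction,
        }
    )


class MarkerScreen(BaseEstimator):
    """Run a comparison scheme and keep significant / trend candidates.

    Attributes after ``fit``: ``results_`` (all rows), ``candidates_``
    (rows with p below the trend threshold, with ``selected`` and
    ``trend`` flags).
    """

    def __init__(
        self,
        scheme: list[ComparisonSpec] | None = None,
        alpha: float = 0.05,
        alpha_trend: float = 0.06,
        test: str = "mann_whitney",
        correction: str | None = None,
    ):
        self.scheme = scheme
        self.alpha = alpha
        self.alpha_trend = alpha_trend
        self.test = test
        self.correction = correction

    def fit(
        self, expr: RelativeExpressionMatrix, samples: SampleTable
    ) -> "MarkerScreen":
        scheme = self.scheme if self.scheme is not None else default_scheme()
        if not scheme:
            raise ComparisonError("empty comparison scheme")
        frames = [compare_groups(expr, samples, spec, self.test) for spec in scheme]
        results = pd.concat(frames, ignore_index=True)
        decisive = results["p_value"].copy()
        if self.correction == "bh":
            adjusted = np.empty(len(results))
            for name, idx in results.groupby("comparison").groups.items():
                adjusted[np.asarray(idx)] = multipletests(
                    results.loc[idx, "p_value"], method="fdr_bh"
                )[1]
            results["p_adjusted"] = adjusted
            decisive = results["p_adjusted"]
        results["selected"] = decisive < self.alpha
        results["trend"] = (decisive >= self.alpha) & (decisive < self.alpha_trend)
        self.results_ = results
        self.candidates_ = results[results["selected"] | results["trend"]].reset_index(
            drop=True
        )
        return self


def run_marker_screen(
    expr: RelativeExpressionMatrix,
    samples: SampleTable,
    scheme: list[ComparisonSpec] | None = None,
    alpha: float = 0.05,
    alpha_trend: float = 0.06,
    test: str = "mann_whitney",
    correction: str | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`MarkerScreen`; returns the candidate table."""
    screen = MarkerScreen(scheme, alpha, alpha_trend, test, correction).fit(
        expr, samples
    )
    return screen.candidates_


def zscore_for_heatmap(
    expr: RelativeExpressionMatrix, assays: list[str] | None = None
) -> pd.DataFrame:
    """Row-standardize relative levels for heat-map display.

    Each assay row is scaled to mean 0 and *population* standard
    deviation 1 across samples.  Zero-variance rows cannot be scaled.
    """
    values = expr.values if assays is None else expr.values.loc[assays]
    sd = values.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])
        raise ScalingError(f"zero-variance assay row(s): {bad[:5]}")
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return z
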