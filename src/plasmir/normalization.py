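"""Normalization-reference selection and ΔCt/−ΔΔCt quantification.

Circulating-miRNA qPCR has no established endogenous control, so the
discovery phase picks one per array card from the data itself using
three criteria:

1. small expression variation (standard deviation of raw Ct across the
   whole cohort),
2. high RNA yield (low mean raw Ct), and
3. no statistically significant level difference between clinical
   categories (controls vs cancer, and across the five groups).

Criterion (3) is tested with rank-based statistics (Mann–Whitney for
control vs all patients, Kruskal–Wallis across the five groups), which
are robust at ten samples per group; a candidate must *exceed* the alpha
threshold on both to qualify.  The validation phase instead normalizes
against a spiked-in non-human miRNA (cel-miR-39-type), which is just a
ΔCt against a designated assay.

Quantification follows the −ΔΔCt convention: ΔCt = Ct(target) −
Ct(reference) within each sample, ΔΔCt subtracts the baseline-group mean
ΔCt per assay, and the stored relative level is −ΔΔCt so that positive
values mean higher abundance than baseline (one unit ≈ two-fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    EmptyMatrixError,
    NeutralityError,
    NormalizationError,
    SelectionError,
)
from .io import GROUPS, CtMatrix, RelativeExpressionMatrix, SampleTable


# ---------------------------------------------------------------------
# pre-filtering and shortlist
# ---------------------------------------------------------------------

def filter_zero_variance(ct: CtMatrix) -> tuple[CtMatrix, list[str]]:
    """Drop assays whose raw Ct is identical in every well.

    Flat assays (standard deviation exactly zero, typically stuck at the
    detection ceiling) carry no information and would break rank tests.
    Returns the filtered matrix and the list of removed assays.
    """
    if ct.values.shape[1] < 2:
        raise EmptyMatrixError("zero-variance filtering needs at least 2 samples")
    flat = ct.values.nunique(axis=1) == 1
    removed = list(ct.values.index[flat])
    if flat.all():
        raise EmptyMatrixError("every assay has zero variance")
    return ct.subset_assays(ct.values.index[~flat]), removed


def shortlist_references(
    ct: CtMatrix, k: int = 6, max_mean_ct: float = 35.0
) -> pd.DataFrame:
    """Per card, the k lowest-SD assays among high-yield, fully detected ones.

    Eligibility: mean raw Ct ≤ ``max_mean_ct`` (criterion 2) and no
    undetected well — a normalizer that drops out in some samples is
    useless.  Ties in SD break lexicographically by assay name.
    Returns a frame with columns card/assay/sd_ct/mean_ct sorted by SD
    within card.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sd = ct.values.std(axis=1, ddof=1)
    mean = ct.values.mean(axis=1)
    eligible = (mean <= max_mean_ct) & ~ct.undetected.any(axis=1)
    rows = []
    for card in sorted(ct.card.unique()):
        pool = ct.values.index[(ct.card == card) & eligible]
        if len(pool) < k:
            warnings.warn(
                f"card {card}: only {len(pool)} eligible reference candidates "
                f"(requested {k})",
                stacklevel=2,
            )
        ranked = sorted(pool, key=lambda a: (sd[a], a))[:k]
        for assay in ranked:
            rows.append(
                {"card": card, "assay": assay,
                 "sd_ct": float(sd[assay]), "mean_ct": float(mean[assay])}
            )
    return pd.DataFrame(rows, columns=["card", "assay", "sd_ct", "mean_ct"])


def reference_neutrality(
    ct: CtMatrix, samples: SampleTable, assay: str
) -> tuple[float, float]:
    """Criterion-3 p-values for one candidate reference.

    Returns ``(p_cancer, p_overall)``: two-sided Mann–Whitney for
    control vs all cancer patients, and Kruskal–Wallis across all
    clinical groups present.  Rank tests make the result identical on
    the raw-Ct and any monotone (e.g. −ΔΔCt) scale.
    """
    if assay not in ct.values.index:
        raise NeutralityError(f"assay {assay!r} not present")
    collapsed = ct.collapse_duplicates()
    levels = collapsed.values.loc[assay, samples.sample_ids]
    groups = samples.groups
    group_values = [
        levels[groups.index[groups == g]].to_numpy()
        for g in GROUPS if (groups == g).any()
    ]
    present = [g for g in GROUPS if (groups == g).any()]
    if "control" not in present:
        raise NeutralityError("control group absent")
    if len(present) < 2:
        raise NeutralityError("need at least two groups for neutrality testing")
    ctrl = levels[groups.index[groups == "control"]].to_numpy()
    cancer = levels[groups.index[groups != "control"]].to_numpy()
    if len(ctrl) < 2 or len(cancer) < 2:
        raise NeutralityError("both control and cancer sides need >= 2 samples")
    p_cancer = float(
        stats.mannwhitneyu(ctrl, cancer, alternative="two-sided").pvalue
    )
    try:
        p_overall = float(stats.kruskal(*group_values).pvalue)
    except ValueError:
        # all observations identical across groups: maximally neutral
        p_overall = 1.0
    return p_cancer, p_overall


@dataclass
class ReferenceReport:
    """Shortlists with stability/neutrality statistics plus the choice per card."""

    shortlist: pd.DataFrame  # card, assay, sd_ct, mean_ct, p_cancer, p_overall, passed
    chosen: dict[str, str]
    alpha: float = 0.05

    def to_tsv(self, path) -> None:
        self.shortlist.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "chosen": dict(self.chosen),
            "shortlist_size": int(len(self.shortlist)),
        }


class ReferenceSelector(BaseEstimator):
    """Select one normalization reference per array card.

    Parameters
    ----------
    k : int
        Shortlist size per card (lowest SD first).
    max_mean_ct : float
        Yield threshold: mean raw Ct must not exceed this (cycles).
    alpha : float
        Neutrality threshold; both p-values must strictly exceed it.

    Attributes
    ----------
    shortlist_ : DataFrame
        Per-card shortlist with SD, mean Ct and both neutrality p-values.
    chosen_ : dict
        card → selected assay.
    report_ : ReferenceReport
    """

    def __init__(self, k: int = 6, max_mean_ct: float = 35.0, alpha: float = 0.05):
        self.k = k
        self.max_mean_ct = max_mean_ct
        self.alpha = alpha

    def fit(self, ct: CtMatrix, samples: SampleTable) -> "ReferenceSelector":
        shortlist = shortlist_references(ct, k=self.k, max_mean_ct=self.max_mean_ct)
        if shortlist.empty:
            raise SelectionError("no eligible reference candidates on any card")
        p_cancer, p_overall = [], []
        for assay in shortlist["assay"]:
            pc, po = reference_neutrality(ct, samples, assay)
            p_cancer.append(pc)
            p_overall.append(po)
        shortlist = shortlist.assign(p_cancer=p_cancer, p_overall=p_overall)
        shortlist["passed"] = (
            (shortlist["p_cancer"] > self.alpha)
            & (shortlist["p_overall"] > self.alpha)
        )
        chosen: dict[str, str] = {}
        for card, sub in shortlist.groupby("card", sort=True):
            ok = sub[sub["passed"]]
            if ok.empty:
                detail = ", ".join(
                    f"{r.assay}: p_cancer={r.p_cancer:.3g}, p_overall={r.p_overall:.3g}"
                    for r in sub.itertuples()
                )
                raise SelectionError(
                    f"card {card}: no shortlisted assay passes neutrality "
                    f"(alpha={self.alpha}); shortlist: {detail}"
                )
            chosen[str(card)] = ok.iloc[0]["assay"]  # shortlist is SD-sorted
        self.shortlist_ = shortlist
        self.chosen_ = chosen
        self.report_ = ReferenceReport(shortlist, chosen, alpha=self.alpha)
        return self


def select_reference(
    ct: CtMatrix,
    samples: SampleTable,
    k: int = 6,
    max_mean_ct: float = 35.0,
    alpha: float = 0.05,
) -> ReferenceReport:
    """Functional wrapper over :class:`ReferenceSelector`."""
    return ReferenceSelector(k=k, max_mean_ct=max_mean_ct, alpha=alpha).fit(
        ct, samples
    ).report_


# ---------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------

def delta_ct(
    ct: CtMatrix,
    reference: str | Mapping[str, str],
    collapse_duplicates: bool = False,
) -> pd.DataFrame:
    """ΔCt(assay, sample) = Ct(assay, sample) − Ct(reference, sample).

    ``reference`` is either a single assay id (e.g. the spike-in) applied
    to every row, or a card → assay mapping so each card is normalized
    against its own endogenous control.  Technical replicates are
    averaged on the Ct scale first when ``collapse_duplicates`` is set.
    """
    if collapse_duplicates:
        ct = ct.collapse_duplicates()
    elif ct.has_replicates:
        raise NormalizationError(
            "matrix has replicate wells; pass collapse_duplicates=True"
        )
    if isinstance(reference, str):
        ref_of = pd.Series(reference, index=ct.values.index)
    else:
        missing_cards = set(ct.card.unique()) - set(reference)
        if missing_cards:
            raise NormalizationError(
                f"no reference given for card(s): {sorted(missing_cards)}"
            )
        ref_of = ct.card.map(dict(reference))
    for ref in pd.unique(ref_of):
        if ref not in ct.values.index:
            raise NormalizationError(f"reference assay {ref!r} not in matrix")
        undet = ct.undetected.loc[ref]
        if undet.any():
            bad = list(ct.undetected.columns[undet])
            raise NormalizationError(
                f"reference {ref!r} undetected in sample(s): {bad[:5]}"
            )
    dct = ct.values.to_numpy() - ct.values.loc[ref_of].to_numpy()
    out = pd.DataFrame(dct, index=ct.values.index, columns=ct.values.columns)
    out.attrs["reference"] = reference
    return out


def relative_expression(
    dct: pd.DataFrame,
    samples: SampleTable,
    baseline_group: str = "control",
) -> RelativeExpressionMatrix:
    """−ΔΔCt relative levels: baseline-group mean ΔCt minus each ΔCt.

    By construction every assay's mean over baseline samples is zero and
    the reference assay maps to zero everywhere.
    """
    baseline_ids = [
        s for s in samples.ids_in_groups([baseline_group]) if s in dct.columns
    ]
    if not baseline_ids:
        raise NormalizationError(
            f"baseline group {baseline_group!r} has no samples in the matrix"
        )
    baseline_mean = dct[baseline_ids].mean(axis=1)
    values = baseline_mean.to_numpy()[:, None] - dct.to_numpy()
    return RelativeExpressionMatrix(
        values=pd.DataFrame(values, index=dct.index, columns=dct.columns),
        reference_assay=dct.attrs.get("reference", "unknown"),
        baseline_group=baseline_group,
    )


class DeltaDeltaCtNormalizer(BaseEstimator):
    """Transformer from raw Ct to −ΔΔCt relative expression.

    ``fit`` learns the per-assay baseline-group mean ΔCt; ``transform``
    maps a Ct matrix to relative levels using the stored baseline, so a
    normalizer fitted on one cohort can be applied to another measured
    with the same reference.
    """

    def __init__(
        self,
        reference: str | Mapping[str, str] = "",
        baseline_group: str = "control",
        collapse_duplicates: bool = False,
    ):
        self.reference = reference
        self.baseline_group = baseline_group
        self.collapse_duplicates = collapse_duplicates

    def fit(self, ct: CtMatrix, samples: SampleTable) -> "DeltaDeltaCtNormalizer":
        dct = delta_ct(ct, self.reference, self.collapse_duplicates)
        baseline_ids = [
            s for s in samples.ids_in_groups([self.baseline_group])
            if s in dct.columns
        ]
        if not baseline_ids:
            raise NormalizationError(
                f"baseline group {self.baseline_group!r} empty"
            )
        self.baseline_mean_ = dct[baseline_ids].mean(axis=1)
        return self

    def transform(self, ct: CtMatrix) -> RelativeExpressionMatrix:
        dct = delta_ct(ct, self.reference, self.collapse_duplicates)
        dct = dct.loc[self.baseline_mean_.index]
        values = self.baseline_mean_.to_numpy()[:, None] - dct.to_numpy()
        return RelativeExpressionMatrix(
            values=pd.DataFrame(values, index=dct.index, columns=dct.columns),
            reference_assay=self.reference,
            baseline_group=self.baseline_group,
        )

    def fit_transform(
        self, ct: CtMatrix, samples: SampleTable
    ) -> RelativeExpressionMatrix:
        return self.fit(ct, samples).transform(ct)
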