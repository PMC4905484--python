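"""Core data containers and tabular I/O.

The pipeline moves three objects between stages:

* :class:`CtMatrix` — raw qPCR cycle-threshold values, one row per miRNA
  assay and one column per well.  A well normally corresponds to one
  sample; in the validation phase each sample is measured in duplicate
  wells that share a sample id (``sample_of`` keeps the mapping).
* :class:`SampleTable` — per-sample clinical annotation (cohort, disease
  group/stage, sex, age, CEA, treatment flags, overall survival).
* :class:`RelativeExpressionMatrix` — −ΔΔCt relative expression with the
  provenance (reference assay, baseline group) attached.

File formats are deliberately plain: wide or long TSV/CSV, with the qPCR
export convention that an empty cell or the token ``Undetermined`` means
"no amplification before the cycle ceiling".  Such wells are stored *at*
the ceiling (default 40 cycles) and flagged, mirroring common practice;
the ceiling is configurable because instruments differ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

DEFAULT_CEILING = 40.0

GROUPS = ("control", "I", "II", "III", "IV")
STAGES = ("I", "II", "III", "IV")

_GROUP_TOKENS = {
    "control": "control", "ctrl": "control", "healthy": "control",
    "normal": "control", "hc": "control",
    "i": "I", "1": "I", "ii": "II", "2": "II",
    "iii": "III", "3": "III", "iv": "IV", "4": "IV",
}
_COHORT_TOKENS = {
    "discovery": "discovery", "screening": "discovery",
    "validation": "validation",
}
_SEX_TOKENS = {"male": "male", "m": "male", "female": "female", "f": "female"}
_TRUE_TOKENS = {"1", "yes", "y", "true"}
_FALSE_TOKENS = {"0", "no", "n", "false"}
_UNDETERMINED_TOKENS = {"undetermined", "undet", "na", "nan", ""}

_WELL_SEP = "|"


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class CtMatrix:
    """Raw Ct values for a set of miRNA assays across wells.

    Parameters
    ----------
    values
        Float frame, assays × wells.  Higher Ct = less abundant;
        one cycle ≈ a two-fold difference in abundance.
    undetected
        Boolean frame of the same shape; True where the instrument
        reported no amplification (value stored at ``ceiling``).
    card
        Per-assay array card label, one of ``{"A", "B", "none"}``.
    is_internal_control
        Per-assay flag for designated controls (U6/RNU44/RNU48-type
        assays or the spike-in).
    sample_of
        Well → sample-id mapping.  For single-well matrices this is the
        identity; duplicate wells of one sample share its sample id.
    ceiling
        Ct value that encodes "undetected" (cycles).
    """

    values: pd.DataFrame
    undetected: pd.DataFrame | None = None
    card: pd.Series | None = None
    is_internal_control: pd.Series | None = None
    sample_of: pd.Series | None = None
    ceiling: float = DEFAULT_CEILING

    def __post_init__(self) -> None:
        v = self.values.astype(float)
        _check_unique(v.index, "assay")
        _check_unique(v.columns, "well")
        if self.undetected is None:
            self.undetected = v >= self.ceiling
        self.undetected = self.undetected.reindex(
            index=v.index, columns=v.columns
        ).fillna(False).astype(bool)
        # qPCR convention: anything at/over the ceiling, or missing, is
        # "undetected" and stored at the ceiling itself.
        over = (v >= self.ceiling) | v.isna()
        v = v.where(~over, self.ceiling)
        self.undetected = self.undetected | over
        if (v <= 0).any().any():
            raise FormatError("Ct values must be positive cycles")
        self.values = v
        if self.card is None:
            self.card = pd.Series("none", index=v.index)
        self.card = self.card.reindex(v.index).fillna("none").astype(str)
        if self.is_internal_control is None:
            self.is_internal_control = pd.Series(False, index=v.index)
        self.is_internal_control = (
            self.is_internal_control.reindex(v.index).fillna(False).astype(bool)
        )
        self.card.name = None
        self.is_internal_control.name = None
        if self.sample_of is None:
            self.sample_of = pd.Series(list(v.columns), index=v.columns)
        else:
            self.sample_of = self.sample_of.reindex(v.columns).astype(str)
            if self.sample_of.isna().any():
                raise FormatError("sample_of must cover every well")

    # -- basic views -------------------------------------------------
    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def well_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        """Unique sample ids in well order."""
        return list(dict.fromkeys(self.sample_of))

    @property
    def has_replicates(self) -> bool:
        return len(self.sample_ids) < len(self.well_ids)

    @property
    def n_assays(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_assays(self, assays: Iterable[str]) -> "CtMatrix":
        assays = list(assays)
        return CtMatrix(
            values=self.values.loc[assays],
            undetected=self.undetected.loc[assays],
            card=self.card.loc[assays],
            is_internal_control=self.is_internal_control.loc[assays],
            sample_of=self.sample_of.copy(),
            ceiling=self.ceiling,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "CtMatrix":
        keep = set(sample_ids)
        wells = [w for w in self.values.columns if self.sample_of[w] in keep]
        return CtMatrix(
            values=self.values[wells],
            undetected=self.undetected[wells],
            card=self.card.copy(),
            is_internal_control=self.is_internal_control.copy(),
            sample_of=self.sample_of.loc[wells],
            ceiling=self.ceiling,
        )

    def collapse_duplicates(self) -> "CtMatrix":
        """Average technical replicate wells on the Ct scale.

        Collapsing happens *before* any ΔCt arithmetic, matching the
        convention of including the mean cycle threshold of replicated
        measurements in the analysis.  A collapsed well is flagged
        undetected only if its mean lands at the ceiling, i.e. every
        replicate was undetected.
        """
        if not self.has_replicates:
            return self
        order = self.sample_ids
        grouped = self.values.T.groupby(self.sample_of, sort=False).mean().T
        grouped = grouped[order]
        return CtMatrix(
            values=grouped,
            card=self.card.copy(),
            is_internal_control=self.is_internal_control.copy(),
            ceiling=self.ceiling,
        )


@dataclass
class SampleTable:
    """Per-sample clinical annotation.

    Backed by a DataFrame indexed by sample id with normalized columns:
    ``cohort`` ∈ {discovery, validation}, ``group`` ∈ {control, I–IV},
    optional ``sex``, ``age`` (years), ``cea`` (µg/L), ``surgery``,
    ``chemotherapy`` (nullable booleans), ``os_time`` (months) and
    ``os_event`` (1 = dead, 0 = censored).  Controls never carry survival
    fields; missing optional fields stay missing, never imputed.
    """

    df: pd.DataFrame

    OPTIONAL = ("sex", "age", "cea", "surgery", "chemotherapy", "os_time", "os_event")

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ValidationError("sample table requires a sample_id column")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        _check_unique(df.index, "sample")
        for col in ("cohort", "group"):
            if col not in df.columns:
                raise ValidationError(f"sample table requires a {col} column")
        df["cohort"] = [self._token(c, _COHORT_TOKENS, "cohort") for c in df["cohort"]]
        df["group"] = [self._normalize_group(g) for g in df["group"]]
        if "sex" in df.columns:
            df["sex"] = [
                None if _is_missing(s) else self._token(s, _SEX_TOKENS, "sex")
                for s in df["sex"]
            ]
        for col in ("age", "cea", "os_time"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise")
        for col in ("surgery", "chemotherapy", "os_event"):
            if col in df.columns:
                df[col] = [_parse_flag(x, col) for x in df[col]]
                df[col] = df[col].astype("Int64")
        if "os_event" in df.columns:
            bad = df["os_event"].notna() & (
                df["os_time"].isna() if "os_time" in df.columns else True
            )
            if "os_time" not in df.columns:
                if df["os_event"].notna().any():
                    raise ValidationError("os_event present without os_time")
            elif bad.any():
                raise ValidationError(
                    "os_event present without os_time for samples: "
                    + ", ".join(df.index[bad][:5])
                )
        # controls carry no survival information by contract
        ctrl = df["group"] == "control"
        for col in ("os_time", "os_event"):
            if col in df.columns:
                df.loc[ctrl, col] = pd.NA
        if "os_time" in df.columns:
            df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
            if (df["os_time"].dropna() < 0).any():
                raise ValidationError("os_time must be non-negative months")
        self.df = df

    @staticmethod
    def _token(value: object, table: Mapping[str, str], what: str) -> str:
        key = str(value).strip().casefold()
        if key not in table:
            raise ValidationError(f"unknown {what} token: {value!r}")
        return table[key]

    @staticmethod
    def _normalize_group(value: object) -> str:
        key = re.sub(r"^stage\s*", "", str(value).strip().casefold())
        if key not in _GROUP_TOKENS:
            raise ValidationError(f"unknown group token: {value!r}")
        return _GROUP_TOKENS[key]

    # -- views -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    def ids_in_groups(self, groups: Iterable[str]) -> list[str]:
        groups = set(groups)
        return list(self.df.index[self.df["group"].isin(groups)])

    @property
    def is_patient(self) -> pd.Series:
        return self.df["group"] != "control"

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        return SampleTable(self.df.loc[list(sample_ids)].copy())


@dataclass
class RelativeExpressionMatrix:
    """−ΔΔCt relative expression levels (log2-like, unitless).

    Positive values mean higher abundance than the baseline-group mean;
    one unit ≈ a two-fold change.  ``fold_change`` exposes the
    2^(−ΔΔCt) view.
    """

    values: pd.DataFrame
    reference_assay: str | Mapping[str, str]
    baseline_group: str = "control"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "assay")
        _check_unique(self.values.columns, "sample")

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def fold_change(self) -> pd.DataFrame:
        return 2.0 ** self.values


@dataclass
class AlignmentReport:
    dropped_from_ct: list[str] = field(default_factory=list)
    dropped_from_samples: list[str] = field(default_factory=list)


def align(
    ct: CtMatrix, samples: SampleTable
) -> tuple[CtMatrix, SampleTable, AlignmentReport]:
    """Restrict a CtMatrix and SampleTable to their shared samples.

    The Ct file's column order is canonical; the annotation table is
    reordered to match.  Dropped ids on either side are reported.
    """
    ct_ids = ct.sample_ids
    table_ids = set(samples.sample_ids)
    common = [s for s in ct_ids if s in table_ids]
    if not common:
        raise AlignmentError("no sample ids shared between Ct matrix and sample table")
    report = AlignmentReport(
        dropped_from_ct=[s for s in ct_ids if s not in table_ids],
        dropped_from_samples=[s for s in samples.sample_ids if s not in set(ct_ids)],
    )
    return ct.subset_samples(common), samples.subset(common), report


# ---------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------

def _is_missing(x: object) -> bool:
    if isinstance(x, str):
        return x.strip().casefold() in _UNDETERMINED_TOKENS
    try:
        return bool(pd.isna(x))
    except (TypeError, ValueError):
        return False


def _parse_flag(x: object, col: str) -> object:
    if _is_missing(x):
        return pd.NA
    key = str(x).strip().casefold()
    if key in _TRUE_TOKENS:
        return 1
    if key in _FALSE_TOKENS:
        return 0
    try:
        return int(float(key))
    except ValueError as exc:
        raise ValidationError(f"cannot parse {col} value {x!r}") from exc


def _parse_ct_cell(raw: object, row: str, col: str, ceiling: float):
    """Return (value, undetected) for one Ct cell."""
    if _is_missing(raw):
        return ceiling, True
    text = str(raw).strip()
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(
            f"unparsable Ct cell at assay {row!r}, well {col!r}: {raw!r}"
        ) from exc
    if value >= ceiling:
        return ceiling, True
    return value, False


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None and dialect.endswith("csv"):
        return ","
    if dialect is not None and dialect.endswith("tsv"):
        return "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_ct_matrix(
    path: str | Path,
    dialect: str = "wide_tsv",
    ceiling: float = DEFAULT_CEILING,
) -> CtMatrix:
    """Read a Ct table.

    ``wide_tsv``/``wide_csv``: first column ``assay_id``, optional
    ``card`` and ``control`` metadata columns, remaining columns one per
    well.  Replicate wells use headers ``sample|1``, ``sample|2``.
    ``long_tsv``: columns ``assay_id``, ``sample_id``, ``ct`` and an
    optional ``replicate`` column.
    """
    path = Path(path)
    if dialect not in ("wide_tsv", "wide_csv", "long_tsv", "long_csv"):
        raise FormatError(f"unknown dialect: {dialect!r}")
    sep = _sep_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header, "column")  # pandas would silently mangle duplicates
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect.startswith("long"):
        return _ct_from_long(raw, ceiling)
    return _ct_from_wide(raw, ceiling)


def _ct_from_wide(raw: pd.DataFrame, ceiling: float) -> CtMatrix:
    cols = list(raw.columns)
    if not cols or cols[0] != "assay_id":
        raise FormatError("wide Ct table must start with an assay_id column")
    _check_unique(cols[1:], "column")
    meta_cols = [c for c in ("card", "control") if c in cols]
    well_cols = [c for c in cols[1:] if c not in meta_cols]
    assays = raw["assay_id"].astype(str).tolist()
    _check_unique(assays, "assay")
    values = np.empty((len(assays), len(well_cols)))
    undet = np.zeros_like(values, dtype=bool)
    for i, assay in enumerate(assays):
        for j, well in enumerate(well_cols):
            values[i, j], undet[i, j] = _parse_ct_cell(
                raw.iloc[i][well], assay, well, ceiling
            )
    sample_of = pd.Series(
        [w.split(_WELL_SEP, 1)[0] for w in well_cols], index=well_cols
    )
    card = (
        raw["card"].replace("", "none").astype(str).set_axis(assays)
        if "card" in meta_cols else None
    )
    control = (
        raw["control"].map(lambda x: not _is_missing(x) and str(x).strip() not in
                           ("0", "false", "no")).set_axis(assays)
        if "control" in meta_cols else None
    )
    return CtMatrix(
        values=pd.DataFrame(values, index=assays, columns=well_cols),
        undetected=pd.DataFrame(undet, index=assays, columns=well_cols),
        card=card,
        is_internal_control=control,
        sample_of=sample_of,
        ceiling=ceiling,
    )


def _ct_from_long(raw: pd.DataFrame, ceiling: float) -> CtMatrix:
    for col in ("assay_id", "sample_id", "ct"):
        if col not in raw.columns:
            raise FormatError(f"long Ct table requires a {col} column")
    has_rep = "replicate" in raw.columns
    wells = (
        raw["sample_id"] + _WELL_SEP + raw["replicate"].astype(str)
        if has_rep else raw["sample_id"]
    )
    key = pd.DataFrame({"assay": raw["assay_id"], "well": wells})
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise FormatError(
            f"duplicate (assay, well) pair: ({dup['assay']!r}, {dup['well']!r})"
        )
    assays = list(dict.fromkeys(raw["assay_id"]))
    well_ids = list(dict.fromkeys(wells))
    values = pd.DataFrame(np.nan, index=assays, columns=well_ids)
    undet = pd.DataFrame(False, index=assays, columns=well_ids)
    for assay, well, cell in zip(raw["assay_id"], wells, raw["ct"]):
        values.loc[assay, well], undet.loc[assay, well] = _parse_ct_cell(
            cell, assay, well, ceiling
        )
    if values.isna().any().any():
        missing = values.isna().stack()
        assay, well = missing[missing].index[0]
        raise FormatError(f"long Ct table missing entry for ({assay!r}, {well!r})")
    sample_of = pd.Series(
        [w.split(_WELL_SEP, 1)[0] for w in well_ids], index=well_ids
    )
    return CtMatrix(values=values, undetected=undet, sample_of=sample_of,
                    ceiling=ceiling)


def read_sample_table(path: str | Path) -> SampleTable:
    path = Path(path)
    sep = _sep_for(path, None)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan)
    return SampleTable(raw)


# ---------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------

def write_ct_matrix(ct: CtMatrix, path: str | Path, dialect: str = "wide_tsv") -> None:
    """Write a CtMatrix; undetected wells round-trip as ``Undetermined``."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    out = ct.values.copy().astype(object)
    out = out.where(~ct.undetected, "Undetermined")
    if dialect.startswith("wide"):
        meta = pd.DataFrame(
            {
                "assay_id": ct.assay_ids,
                "card": ct.card.to_numpy(),
                "control": ct.is_internal_control.astype(int).to_numpy(),
            },
            index=out.index,
        )
        pd.concat([meta, out], axis=1).to_csv(path, sep=sep, index=False)
    else:
        long = out.stack(future_stack=True).reset_index()
        long.columns = ["assay_id", "well", "ct"]
        long["sample_id"] = [w.split(_WELL_SEP, 1)[0] for w in long["well"]]
        if ct.has_replicates:
            long["replicate"] = [
                w.split(_WELL_SEP, 1)[1] if _WELL_SEP in w else "1"
                for w in long["well"]
            ]
            long = long[["assay_id", "sample_id", "replicate", "ct"]]
        else:
            long = long[["assay_id", "sample_id", "ct"]]
        long.to_csv(path, sep=sep, index=False)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    path = Path(path)
    samples.df.reset_index().to_csv(path, sep=_sep_for(path, None), index=False)


def write_relative_expression(
    expr: RelativeExpressionMatrix, path: str | Path
) -> None:
    path = Path(path)
    frame = expr.values.copy()
    frame.index.name = "assay_id"
    frame.to_csv(path, sep=_sep_for(path, None))
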