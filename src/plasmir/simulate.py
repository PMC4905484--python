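"""Synthetic two-phase plasma-miRNA cohort generator.

Emulates the structure of a two-card TaqMan discovery screen plus a
qRT-PCR validation study so every downstream stage can be scored
against a machine-readable ground truth:

* 754 assays split over cards A and B, baseline mean Ct drawn from
  U(22, 38) cycles and per-assay biological SD from U(0.3, 1.5) cycles;
  a configurable number of flat assays sit at the 40-cycle detection
  ceiling in every sample (they exercise the zero-variance filter).
* A discovery cohort of 10 controls + 10 patients per stage I–IV, and a
  validation cohort of 47 controls + 187 patients (38/50/50/49 by
  stage) whose sex/surgery/chemotherapy composition reproduces the
  study population, including one patient with missing chemotherapy and
  a handful with no survival information.
* Marker effects are planted on the Ct scale (cycles) as group-wise
  shifts — negative shift = fewer cycles = higher abundance, one cycle
  ≈ two-fold — so they propagate through ΔΔCt exactly as real signal.
* Stable endogenous assays (miR-451/miR-877 analogues, SD ≤ 0.2, no
  group shift) are planted on each card for reference selection, and
  the validation run carries a near-constant spike-in (cel-miR-39
  analogue) measured in duplicate wells like every validation assay.
* Overall survival is exponential with log-linear covariates: a stage
  III–IV coefficient plus a coefficient per prognostic marker's arm
  (high vs low latent expression, split at the patient mean).
  Censoring is administrative, uniform over (0, 2 × 28) months so the
  median follow-up is ~28 months.
* CEA is log-normal with a stage shift and is only consumed as a Cox
  covariate.

One seed drives everything through named, order-stable child streams,
so outputs are bitwise reproducible and adding markers does not perturb
unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import STAGES, CtMatrix, SampleTable

GROUP_ORDER = ("control", "I", "II", "III", "IV")

CATEGORY_SET = ("detection", "early_stage", "late_stage", "metastasis", "stage2_vs_3")


@dataclass(frozen=True)
class PlantedMarker:
    """A marker miRNA with a planted per-group Ct shift (cycles).

    Negative shifts mean higher abundance in that group.  ``prognostic_coef``
    is the log-hazard added for patients in the marker's high arm.
    """

    assay: str
    category: str
    shift: Mapping[str, float]
    card: str = "A"
    mean_ct: float = 28.0
    sd: float = 0.8
    prognostic_coef: float = 0.0


@dataclass(frozen=True)
class StableAssay:
    """A planted low-variance, group-neutral endogenous control analogue."""

    assay: str
    card: str
    sd: float
    mean_ct: float = 27.0


def default_markers() -> list[PlantedMarker]:
    return [
        PlantedMarker(
            "mkr-detection-1", "detection",
            {"I": -1.5, "II": -1.5, "III": -1.5, "IV": -1.5},
            card="A", mean_ct=27.0,
        ),
        # the early marker's shift is deliberately smaller than the late
        # marker's, so the stage III-IV vs I-II contrast has a single
        # best discriminator rather than two equally good ones
        PlantedMarker(
            "mkr-early-1", "early_stage", {"I": -1.2, "II": -1.2},
            card="A", mean_ct=28.0,
        ),
        PlantedMarker(
            "mkr-late-1", "late_stage", {"III": -1.8, "IV": -1.8},
            card="B", mean_ct=29.0, prognostic_coef=0.9,
        ),
        PlantedMarker(
            "mkr-metastasis-1", "metastasis", {"IV": -2.5},
            card="A", mean_ct=26.0, prognostic_coef=0.9,
        ),
        PlantedMarker(
            "mkr-stage2v3-1", "stage2_vs_3", {"II": -1.5},
            card="B", mean_ct=28.0,
        ),
    ]


def default_stable_assays() -> list[StableAssay]:
    # three per card, echoing a shortlist in which a couple of low-SD
    # assays per card turn out group-neutral
    return [
        StableAssay("stable-A-1", "A", 0.12, 26.0),
        StableAssay("stable-A-2", "A", 0.16, 27.0),
        StableAssay("stable-A-3", "A", 0.19, 28.0),
        StableAssay("stable-B-1", "B", 0.13, 26.5),
        StableAssay("stable-B-2", "B", 0.17, 27.5),
        StableAssay("stable-B-3", "B", 0.20, 28.5),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_assays: int = 754
    n_flat_assays: int = 30          # stuck at the ceiling in every sample
    discovery_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "control": 10, "I": 10, "II": 10, "III": 10, "IV": 10
        }
    )
    validation_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "control": 47, "I": 38, "II": 50, "III": 50, "IV": 49
        }
    )
    baseline_ct_range: tuple[float, float] = (22.0, 38.0)
    biological_sd_range: tuple[float, float] = (0.3, 1.5)
    technical_sd: float = 0.15       # duplicate-well SD, cycles
    ceiling: float = 40.0
    markers: list[PlantedMarker] = field(default_factory=default_markers)
    stable_assays: list[StableAssay] = field(default_factory=default_stable_assays)
    spike_in: str = "spike-cel-39"
    spike_in_sd: float = 0.08
    spike_in_mean_ct: float = 22.0
    # clinical composition (validation): counts, not probabilities
    male_controls: int = 22
    male_patients: int = 99
    chemo_yes: int = 144
    chemo_missing: int = 1
    surgery_yes: int = 156
    missing_survival: int = 13
    # survival model
    baseline_hazard: float = 0.008   # events per month
    stage_coef: float = 1.1          # log-hazard, stage III-IV vs I-II
    followup_months: float = 28.0    # median administrative follow-up
    weibull_shape: float = 1.0       # 1.0 = exponential
    # CEA model: log-normal, stage-shifted
    cea_log_mean_control: float = np.log(2.0)
    cea_log_stage_step: float = 0.45
    cea_log_sd: float = 0.7

    def validate(self) -> None:
        for name, sizes in (
            ("discovery", self.discovery_sizes),
            ("validation", self.validation_sizes),
        ):
            for g, n in sizes.items():
                if g not in GROUP_ORDER:
                    raise ConfigError(f"{name} sizes: unknown group {g!r}")
                if n < 2:
                    raise ConfigError(f"{name} sizes: group {g} needs >= 2 samples")
        named = (
            [m.assay for m in self.markers]
            + [s.assay for s in self.stable_assays]
        )
        if len(set(named)) != len(named):
            raise ConfigError("planted assay names collide")
        if len(named) + self.n_flat_assays > self.n_assays:
            raise ConfigError("more planted assays than assay slots")
        for m in self.markers:
            if m.category not in CATEGORY_SET:
                raise ConfigError(f"unknown marker category {m.category!r}")
            if not all(np.isfinite(list(m.shift.values()))):
                raise ConfigError(f"non-finite shift for {m.assay}")
            if set(m.shift) - set(STAGES):
                raise ConfigError(f"marker {m.assay}: shifts must target stages")
        for s in self.stable_assays:
            if s.sd > 0.2:
                raise ConfigError(f"stable assay {s.assay}: sd must be <= 0.2")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,))
    )


# stream ids, fixed so adding draws to one stage never shifts another
_S_ASSAYS, _S_DISC_CT, _S_DISC_CLIN, _S_VAL_CT, _S_VAL_CLIN, _S_SURV = range(6)


def _assay_panel(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Per-assay static parameters: card, mean Ct, biological SD, flags."""
    rng = _rng(seed, _S_ASSAYS)
    n = config.n_assays
    n_a = n // 2
    planted = {m.assay: m for m in config.markers}
    stable = {s.assay: s for s in config.stable_assays}
    rows = []
    lo, hi = config.baseline_ct_range
    slo, shi = config.biological_sd_range
    filler_idx = 0
    per_card = {"A": n_a, "B": n - n_a}
    for card, count in per_card.items():
        planted_here = [m for m in config.markers if m.card == card]
        stable_here = [s for s in config.stable_assays if s.card == card]
        n_special = len(planted_here) + len(stable_here)
        n_flat = config.n_flat_assays // 2 if card == "A" else (
            config.n_flat_assays - config.n_flat_assays // 2
        )
        n_filler = count - n_special - n_flat
        if n_filler < 0:
            raise ConfigError(f"card {card}: too many planted assays")
        for m in planted_here:
            rows.append((m.assay, card, m.mean_ct, m.sd, "marker"))
        for s in stable_here:
            rows.append((s.assay, card, s.mean_ct, s.sd, "stable"))
        for _ in range(n_filler):
            filler_idx += 1
            rows.append((
                f"mir-sim-{filler_idx:04d}", card,
                float(rng.uniform(lo, hi)), float(rng.uniform(slo, shi)),
                "filler",
            ))
        for _ in range(n_flat):
            filler_idx += 1
            rows.append((
                f"mir-sim-{filler_idx:04d}", card,
                config.ceiling + 5.0, 0.0, "flat",
            ))
    panel = pd.DataFrame(
        rows, columns=["assay", "card", "mean_ct", "sd", "kind"]
    ).set_index("assay")
    assert len(panel) == n
    return panel


def _group_labels(sizes: Mapping[str, int]) -> list[str]:
    labels = []
    for g in GROUP_ORDER:
        labels.extend([g] * sizes.get(g, 0))
    return labels


def _exact_flags(rng: np.random.Generator, n: int, n_true: int) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[:n_true] = True
    rng.shuffle(flags)
    return flags


def _shift_matrix(
    panel: pd.DataFrame, config: SimulationConfig, groups: list[str]
) -> np.ndarray:
    shift = np.zeros((len(panel), len(groups)))
    marker_pos = {a: i for i, a in enumerate(panel.index)}
    for m in config.markers:
        if m.assay not in marker_pos:
            continue
        row = marker_pos[m.assay]
        for j, g in enumerate(groups):
            shift[row, j] = m.shift.get(g, 0.0)
    return shift


def _latent_expression(
    panel: pd.DataFrame,
    config: SimulationConfig,
    groups: list[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """True per-(assay, sample) Ct before ceiling clipping."""
    mean = panel["mean_ct"].to_numpy()[:, None]
    sd = panel["sd"].to_numpy()[:, None]
    noise = rng.normal(0.0, 1.0, size=(len(panel), len(groups))) * sd
    return mean + _shift_matrix(panel, config, groups) + noise


def _ct_matrix_from_latent(
    latent: np.ndarray,
    panel: pd.DataFrame,
    wells: list[str],
    sample_of: pd.Series,
    config: SimulationConfig,
) -> CtMatrix:
    values = pd.DataFrame(latent, index=panel.index, columns=wells)
    return CtMatrix(
        values=values,
        card=panel["card"].copy(),
        is_internal_control=pd.Series(
            panel["kind"].isin(["stable"]).to_numpy()
            | (panel.index == config.spike_in),
            index=panel.index,
        ),
        sample_of=sample_of,
        ceiling=config.ceiling,
    )


def planted_truth(config: SimulationConfig) -> pd.DataFrame:
    """Canonical listing of every planted marker effect."""
    config.validate()
    rows = []
    for m in config.markers:
        row = {"assay": m.assay, "category": m.category,
               "prognostic_coef": m.prognostic_coef}
        for g in STAGES:
            row[f"shift_{g}"] = float(m.shift.get(g, 0.0))
        rows.append(row)
    columns = ["assay", "category", "prognostic_coef"] + [
        f"shift_{g}" for g in STAGES
    ]
    return pd.DataFrame(rows, columns=columns)


def _clinical_frame(
    ids: list[str],
    groups: list[str],
    cohort: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    male_controls: int,
    male_patients: int,
    surgery_yes: int,
    chemo_yes: int,
    chemo_missing: int,
) -> pd.DataFrame:
    df = pd.DataFrame({"sample_id": ids, "cohort": cohort, "group": groups})
    is_patient = df["group"] != "control"
    n_ctrl = int((~is_patient).sum())
    n_pat = int(is_patient.sum())
    sex = np.empty(len(df), dtype=object)
    sex[~is_patient] = np.where(
        _exact_flags(rng, n_ctrl, male_controls), "male", "female"
    )
    sex[is_patient.to_numpy()] = np.where(
        _exact_flags(rng, n_pat, male_patients), "male", "female"
    )
    df["sex"] = sex
    age = np.where(
        is_patient,
        rng.normal(55.0, 7.8, len(df)),
        rng.normal(54.0, 6.3, len(df)),
    )
    df["age"] = np.round(np.clip(age, 25, 90), 1)
    stage_idx = df["group"].map({"control": 0, "I": 1, "II": 2, "III": 3, "IV": 4})
    cea_mu = config.cea_log_mean_control + config.cea_log_stage_step * stage_idx
    df["cea"] = np.round(
        np.exp(rng.normal(cea_mu, config.cea_log_sd, len(df))), 2
    )
    surgery = pd.array([pd.NA] * len(df), dtype="Int64")
    chemo = pd.array([pd.NA] * len(df), dtype="Int64")
    pat_idx = np.flatnonzero(is_patient.to_numpy())
    surgery[pat_idx] = _exact_flags(rng, n_pat, surgery_yes).astype(int)
    # exact composition: chemo_yes "yes", chemo_missing unknown, rest "no"
    known = _exact_flags(rng, n_pat, n_pat - chemo_missing)
    chemo_vals = pd.array([pd.NA] * n_pat, dtype="Int64")
    chemo_vals[known] = _exact_flags(
        rng, n_pat - chemo_missing, chemo_yes
    ).astype(int)
    chemo[pat_idx] = chemo_vals
    df["surgery"] = surgery
    df["chemotherapy"] = chemo
    return df


def simulate_discovery(
    config: SimulationConfig | None = None, seed: int = 0
) -> tuple[CtMatrix, SampleTable, pd.DataFrame]:
    """Discovery cohort: one well per sample, both cards, no spike-in."""
    config = config or SimulationConfig()
    config.validate()
    panel = _assay_panel(config, seed)
    groups = _group_labels(config.discovery_sizes)
    counters: dict[str, int] = {}
    ids = []
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        tag = "CTRL" if g == "control" else g
        ids.append(f"D-{tag}-{counters[g]:02d}")
    rng_ct = _rng(seed, _S_DISC_CT)
    latent = _latent_expression(panel, config, groups, rng_ct)
    ct = _ct_matrix_from_latent(
        latent, panel, ids, pd.Series(ids, index=ids), config
    )
    rng_clin = _rng(seed, _S_DISC_CLIN)
    n_pat = sum(v for g, v in config.discovery_sizes.items() if g != "control")
    n_ctrl = config.discovery_sizes.get("control", 0)
    clin = _clinical_frame(
        ids, groups, "discovery", config, rng_clin,
        male_controls=n_ctrl // 2,
        male_patients=n_pat // 2,
        surgery_yes=round(0.825 * n_pat),
        chemo_yes=round(0.775 * n_pat),
        chemo_missing=0,
    )
    return ct, SampleTable(clin), planted_truth(config)


def _survival_draw(
    groups: np.ndarray,
    high_arm: Mapping[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(os_time months, os_event) under the configured hazard model."""
    coef_by_marker = {
        m.assay: m.prognostic_coef for m in config.markers if m.prognostic_coef
    }
    log_hr = np.where(np.isin(groups, ["III", "IV"]), config.stage_coef, 0.0)
    for assay, coef in coef_by_marker.items():
        log_hr = log_hr + coef * high_arm[assay]
    rate = config.baseline_hazard * np.exp(log_hr)
    n = len(groups)
    u = rng.uniform(size=n)
    if config.weibull_shape == 1.0:
        death = -np.log(u) / np.maximum(rate, 1e-12)
    else:
        death = (-np.log(u) / np.maximum(rate, 1e-12)) ** (
            1.0 / config.weibull_shape
        )
    censor = rng.uniform(0.0, 2.0 * config.followup_months, size=n)
    event = (death <= censor).astype(int)
    time = np.round(np.minimum(death, censor), 2)
    # a death rounded to 0 months is still a valid (tiny) survival time
    time = np.maximum(time, 0.01)
    return time, event


def simulate_validation(
    config: SimulationConfig | None = None,
    seed: int = 0,
    assays: list[str] | None = None,
) -> tuple[CtMatrix, SampleTable, pd.DataFrame]:
    """Validation cohort: duplicate wells, spike-in, CEA and survival.

    ``assays`` restricts the measured panel; the default is every
    planted marker plus the first stable assay of card A (the
    endogenous-control analogue carried into validation) and the
    spike-in.
    """
    config = config or SimulationConfig()
    config.validate()
    panel = _assay_panel(config, seed)
    if assays is None:
        assays = [m.assay for m in config.markers]
        card_a_stable = [s.assay for s in config.stable_assays if s.card == "A"]
        if card_a_stable:
            assays = assays + [card_a_stable[0]]
    missing = [a for a in assays if a not in panel.index and a != config.spike_in]
    if missing:
        raise ConfigError(f"validation assays not in panel: {missing}")
    spike_row = pd.DataFrame(
        {"card": "none", "mean_ct": config.spike_in_mean_ct,
         "sd": config.spike_in_sd, "kind": "spike"},
        index=[config.spike_in],
    )
    # prognostic markers drive survival whether or not they are measured,
    # so their latent abundance is always generated
    prognostic = [m.assay for m in config.markers if m.prognostic_coef]
    latent_assays = list(dict.fromkeys(
        [a for a in assays if a != config.spike_in]
        + [a for a in prognostic if a not in assays]
    ))
    sub_panel = pd.concat([panel.loc[latent_assays], spike_row])
    measured = [a for a in assays if a != config.spike_in] + [config.spike_in]

    groups = _group_labels(config.validation_sizes)
    counters: dict[str, int] = {}
    ids = []
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        tag = "CTRL" if g == "control" else g
        ids.append(f"V-{tag}-{counters[g]:02d}")

    rng_ct = _rng(seed, _S_VAL_CT)
    latent = _latent_expression(sub_panel, config, groups, rng_ct)
    # duplicate wells: latent sample value + independent technical noise
    wells, well_cols = [], []
    for rep in (1, 2):
        well_cols.append([f"{s}|{rep}" for s in ids])
    tech = rng_ct.normal(
        0.0, config.technical_sd, size=(2, len(sub_panel), len(ids))
    )
    values = np.concatenate([latent + tech[0], latent + tech[1]], axis=1)
    all_wells = well_cols[0] + well_cols[1]
    # interleave replicate wells per sample for a realistic plate layout
    order = [w for pair in zip(well_cols[0], well_cols[1]) for w in pair]
    frame = pd.DataFrame(
        values, index=sub_panel.index, columns=all_wells
    ).loc[measured, order]
    sample_of = pd.Series([w.split("|", 1)[0] for w in order], index=order)
    ct = CtMatrix(
        values=frame,
        card=sub_panel.loc[measured, "card"].copy(),
        is_internal_control=pd.Series(
            sub_panel.loc[measured, "kind"].isin(["stable", "spike"]).to_numpy(),
            index=measured,
        ),
        sample_of=sample_of,
        ceiling=config.ceiling,
    )

    rng_clin = _rng(seed, _S_VAL_CLIN)
    clin = _clinical_frame(
        ids, groups, "validation", config, rng_clin,
        male_controls=config.male_controls,
        male_patients=config.male_patients,
        surgery_yes=config.surgery_yes,
        chemo_yes=config.chemo_yes,
        chemo_missing=config.chemo_missing,
    )

    # survival depends on the *latent* marker abundance (shift + biological
    # noise), so the dichotomized analysis sees the same signal the wells do
    rng_surv = _rng(seed, _S_SURV)
    groups_arr = np.asarray(groups)
    is_patient = groups_arr != "control"
    high_arm: dict[str, np.ndarray] = {}
    for m in config.markers:
        if not m.prognostic_coef:
            continue
        row = list(sub_panel.index).index(m.assay)
        abundance = -(latent[row] - sub_panel["mean_ct"].iloc[row])
        pat_mean = abundance[is_patient].mean()
        high_arm[m.assay] = ((abundance > pat_mean) & is_patient).astype(int)
    time, event = _survival_draw(
        groups_arr[is_patient], {k: v[is_patient] for k, v in high_arm.items()},
        config, rng_surv,
    )
    os_time = np.full(len(ids), np.nan)
    os_event = pd.array([pd.NA] * len(ids), dtype="Int64")
    pat_idx = np.flatnonzero(is_patient)
    os_time[pat_idx] = time
    os_event[pat_idx] = pd.array(event, dtype="Int64")
    if config.missing_survival:
        gone = rng_surv.choice(
            pat_idx, size=config.missing_survival, replace=False
        )
        os_time[gone] = np.nan
        os_event[gone] = pd.NA
    clin["os_time"] = os_time
    clin["os_event"] = os_event
    return ct, SampleTable(clin), planted_truth(config)


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON/YAML-serializable view of a configuration."""
    d = asdict(config)
    d["markers"] = [
        {**asdict(m), "shift": dict(m.shift)} for m in config.markers
    ]
    d["stable_assays"] = [asdict(s) for s in config.stable_assays]
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    if "markers" in d:
        d["markers"] = [PlantedMarker(**m) for m in d["markers"]]
    if "stable_assays" in d:
        d["stable_assays"] = [StableAssay(**s) for s in d["stable_assays"]]
    for key in ("baseline_ct_range", "biological_sd_range"):
        if key in d:
            d[key] = tuple(d[key])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg
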