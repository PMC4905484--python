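"""End-to-end orchestration of the two study phases.

``run_discovery_phase`` chains zero-variance filtering → per-card
reference selection → ΔCt → −ΔΔCt → the seven-comparison marker screen,
and writes every artifact (reference report, relative expression,
candidate table, z-scored heat-map matrix) plus a JSON manifest with a
config hash so reruns are verifiably identical.

``run_validation_phase`` takes the candidate assays into the validation
cohort: spike-in ΔCt with duplicate-well averaging, the same seven group
comparisons, a best-single-marker logistic/ROC evaluation for each of
the three clinical contrasts (patients vs controls, stage III–IV vs
I–II, stage IV vs I–III), mean-dichotomized KM/log-rank per candidate,
and a multivariable Cox model over the standard clinical contrasts plus
the markers that show univariate survival signal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import PlasmirError
from .evaluation import SingleMarkerEvaluator
from .io import (
    CtMatrix,
    SampleTable,
    align,
    write_ct_matrix,
    write_relative_expression,
    write_sample_table,
)
from .normalization import (
    DeltaDeltaCtNormalizer,
    ReferenceSelector,
    filter_zero_variance,
)
from .screening import MarkerScreen, default_scheme, zscore_for_heatmap
from .simulate import (
    SimulationConfig,
    config_to_dict,
    simulate_discovery,
    simulate_validation,
)
from .survival import (
    build_design,
    cox_fit,
    dichotomize_by_mean,
    km_curve,
    logrank,
)

# the three clinical contrasts evaluated with logistic/ROC models
EVALUATION_CONTRASTS = {
    "crc_vs_control": ({"I", "II", "III", "IV"}, {"control"}),
    "stage_iii_iv_vs_i_ii": ({"III", "IV"}, {"I", "II"}),
    "stage_iv_vs_i_iii": ({"IV"}, {"I", "II", "III"}),
}


@dataclass
class RunConfig:
    """Reproducible configuration for a pipeline run."""

    out_dir: str = "plasmir-run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    alpha_trend: float = 0.06
    test: str = "mann_whitney"
    reference_k: int = 6
    reference_max_mean_ct: float = 35.0
    reference_alpha: float = 0.05
    evaluation_criterion: str = "auc"
    cutoff_criterion: str = "youden"
    logrank_permutations: int | None = None
    cox_marker_alpha: float = 0.05

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in self.__dict__.items() if k != "simulation"
        }
        d["simulation"] = config_to_dict(self.simulation)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, out: Path, phase: str,
                    outputs: list[str], extra: dict) -> None:
    manifest = {
        "phase": phase,
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "plasmir_version": __version__,
        "numpy_version": np.__version__,
        "outputs": sorted(outputs),
        **extra,
    }
    (out / f"manifest_{phase}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


@dataclass
class DiscoveryResult:
    reference_report: object
    expression: object
    candidates: pd.DataFrame
    removed_flat: list[str]


def run_discovery_phase(
    cfg: RunConfig,
    ct: CtMatrix | None = None,
    samples: SampleTable | None = None,
) -> DiscoveryResult:
    """Discovery phase on given tables, or on a simulated cohort."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    if ct is None or samples is None:
        ct, samples, truth = simulate_discovery(cfg.simulation, cfg.seed)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        write_ct_matrix(ct, out / "discovery_ct.tsv")
        write_sample_table(samples, out / "discovery_samples.tsv")
        outputs += ["truth.tsv", "discovery_ct.tsv", "discovery_samples.tsv"]
    ct, samples, _ = align(ct, samples)

    ct_f, removed = filter_zero_variance(ct)
    selector = ReferenceSelector(
        k=cfg.reference_k,
        max_mean_ct=cfg.reference_max_mean_ct,
        alpha=cfg.reference_alpha,
    ).fit(ct_f, samples)
    report = selector.report_
    report.to_tsv(out / "reference_report.tsv")
    (out / "reference_report.json").write_text(
        json.dumps(report.summary(), indent=2, sort_keys=True) + "\n"
    )
    outputs += ["reference_report.tsv", "reference_report.json"]

    expr = DeltaDeltaCtNormalizer(
        reference=selector.chosen_, baseline_group="control"
    ).fit_transform(ct_f, samples)
    write_relative_expression(expr, out / "relative_expression.tsv")
    outputs.append("relative_expression.tsv")

    screen = MarkerScreen(
        scheme=default_scheme(),
        alpha=cfg.alpha,
        alpha_trend=cfg.alpha_trend,
        test=cfg.test,
    ).fit(expr, samples)
    candidates = screen.candidates_
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    outputs.append("candidates.tsv")

    selected_assays = sorted(candidates.loc[candidates["selected"], "assay"].unique())
    if selected_assays:
        z = zscore_for_heatmap(expr, selected_assays)
        z.index.name = "assay_id"
        z.to_csv(out / "heatmap_z.tsv", sep="\t")
        outputs.append("heatmap_z.tsv")

    _write_manifest(
        cfg, out, "discovery", outputs,
        {
            "zero_variance_removed": len(removed),
            "chosen_references": selector.chosen_,
            "n_candidates": int(candidates["selected"].sum()),
            "test": cfg.test, "alpha": cfg.alpha,
        },
    )
    return DiscoveryResult(report, expr, candidates, removed)


@dataclass
class ValidationResult:
    expression: object
    comparisons: pd.DataFrame
    evaluations: dict
    survival_univariate: pd.DataFrame
    cox: object


def run_validation_phase(
    cfg: RunConfig,
    candidates: list[str] | None = None,
    ct: CtMatrix | None = None,
    samples: SampleTable | None = None,
) -> ValidationResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    if ct is None or samples is None:
        ct, samples, truth = simulate_validation(
            cfg.simulation, cfg.seed, assays=candidates
        )
        write_ct_matrix(ct, out / "validation_ct.tsv")
        write_sample_table(samples, out / "validation_samples.tsv")
        outputs += ["validation_ct.tsv", "validation_samples.tsv"]
    ct, samples, _ = align(ct, samples)
    spike = cfg.simulation.spike_in
    if spike not in ct.values.index:
        raise PlasmirError(f"spike-in assay {spike!r} missing from validation run")

    expr = DeltaDeltaCtNormalizer(
        reference=spike, baseline_group="control", collapse_duplicates=True
    ).fit_transform(ct, samples)
    expr.values.drop(index=spike, inplace=True)
    write_relative_expression(expr, out / "validation_expression.tsv")
    outputs.append("validation_expression.tsv")

    if candidates is None:
        candidates = [a for a in expr.assay_ids]
    candidates = [a for a in candidates if a in expr.assay_ids]
    if not candidates:
        raise PlasmirError("no candidate assays present in validation matrix")

    screen = MarkerScreen(
        scheme=default_scheme(), alpha=cfg.alpha,
        alpha_trend=cfg.alpha_trend, test=cfg.test,
    ).fit(expr, samples)
    screen.results_.to_csv(out / "validation_comparisons.tsv", sep="\t", index=False)
    outputs.append("validation_comparisons.tsv")

    # logistic/ROC evaluation per clinical contrast
    levels = expr.values.T  # samples × assays
    groups = samples.groups
    evaluations: dict[str, dict] = {}
    for name, (pos, neg) in EVALUATION_CONTRASTS.items():
        mask = groups.isin(pos | neg)
        y = groups[mask].isin(pos).astype(int).to_numpy()
        X = levels.loc[mask.index[mask], candidates]
        ev = SingleMarkerEvaluator(
            criterion=cfg.evaluation_criterion,
            cutoff_criterion=cfg.cutoff_criterion,
        ).fit(X, y)
        ev.leaderboard_.to_csv(
            out / f"leaderboard_{name}.tsv", sep="\t", index=False
        )
        outputs.append(f"leaderboard_{name}.tsv")
        evaluations[name] = {
            "best_marker": ev.best_marker_,
            "model": {
                "intercept": ev.best_model_.intercept,
                "coef": float(ev.best_model_.coef.iloc[0]),
            },
            **ev.summary_.to_dict(),
        }
    (out / "evaluation.json").write_text(
        json.dumps(evaluations, indent=2, sort_keys=True) + "\n"
    )
    outputs.append("evaluation.json")

    # mean-dichotomized KM / log-rank per candidate (patients only)
    pat = samples.df[samples.is_patient]
    has_os = pat["os_time"].notna() & pat["os_event"].notna()
    surv_ids = list(pat.index[has_os])
    rows = []
    marker_arms: dict[str, pd.Series] = {}
    for assay in candidates:
        arm = dichotomize_by_mean(expr.values.loc[assay, pat.index])
        marker_arms[assay] = arm
        arm_s = arm.loc[surv_ids]
        times = pat.loc[surv_ids, "os_time"].astype(float).to_numpy()
        events = pat.loc[surv_ids, "os_event"].astype(int).to_numpy()
        if arm_s.nunique() < 2:
            rows.append({"assay": assay, "chi_square": np.nan, "p_value": np.nan,
                         "n_high": int((arm_s == "high").sum()),
                         "n_low": int((arm_s == "low").sum())})
            continue
        for level in ("low", "high"):
            curve = km_curve(
                times[arm_s == level], events[arm_s == level],
                label=f"{assay}:{level}",
            )
            pd.DataFrame(
                {"time": curve.times, "at_risk": curve.at_risk,
                 "survival": curve.survival}
            ).to_csv(out / f"km_{assay}_{level}.tsv", sep="\t", index=False)
            outputs.append(f"km_{assay}_{level}.tsv")
        lr = logrank(
            times, events, arm_s.to_numpy(),
            n_permutations=cfg.logrank_permutations, seed=cfg.seed,
        )
        rows.append({"assay": assay, "chi_square": lr.chi_square,
                     "p_value": lr.p_value,
                     "n_high": int((arm_s == "high").sum()),
                     "n_low": int((arm_s == "low").sum())})
    survival_uni = pd.DataFrame(rows)
    survival_uni.to_csv(out / "survival_univariate.tsv", sep="\t", index=False)
    outputs.append("survival_univariate.tsv")

    # multivariable Cox: clinical contrasts + markers with univariate signal
    keep_markers = [
        r["assay"] for r in rows
        if np.isfinite(r.get("p_value", np.nan)) and r["p_value"] < cfg.cox_marker_alpha
    ]
    design, times, events, dropped = build_design(
        samples, {m: marker_arms[m] for m in keep_markers}
    )
    fit = cox_fit(design, times, events)
    fit.to_tsv(out / "cox_fit.tsv")
    outputs.append("cox_fit.tsv")

    _write_manifest(
        cfg, out, "validation", outputs,
        {
            "candidates": list(candidates),
            "cox_markers": keep_markers,
            "cox_dropped_patients": len(dropped),
            "contrast_winners": {
                k: v["best_marker"] for k, v in evaluations.items()
            },
        },
    )
    return ValidationResult(expr, screen.results_, evaluations, survival_uni, fit)


def run_all(cfg: RunConfig) -> tuple[DiscoveryResult, ValidationResult]:
    """Simulate-discover-validate with one configuration and seed."""
    disc = run_discovery_phase(cfg)
    planted = set(
        a for a in disc.candidates.loc[disc.candidates["selected"], "assay"]
    )
    # carry forward the discovery candidates that the generator can measure
    measurable = [m.assay for m in cfg.simulation.markers]
    carried = [a for a in measurable if a in planted] or measurable
    stable_a = [s.assay for s in cfg.simulation.stable_assays if s.card == "A"]
    val = run_validation_phase(cfg, candidates=carried + stable_a[:1])
    return disc, val
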