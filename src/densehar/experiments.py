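"""Config-driven experiment orchestration.

Five experiments mirror the study design, each runnable end-to-end on the
bundled synthetic cohorts (or on recordings loaded from files):

- ``architectures``: CNN vs GRU vs ConvRec vs ReConv, LOPO-CV on the young
  cohort, fold-ensemble transfer to the old cohort.
- ``frequency``: the same pipeline after downsampling both cohorts to each of
  50/25/20/15/10 Hz.
- ``location``: thigh-only, lower-back-only and combined sensor channels.
- ``window_length``: one LOPO run whose held-out recordings are re-predicted
  in 200-frame (4 s) and 3000-frame (1 min) chunks.
- ``combined``: young-only training evaluated on the old cohort versus
  pooled-cohort LOPO training, with metrics split by cohort tag.

Every experiment is reproducible from (spec, seed); summaries are written as
CSV plus a JSON bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    compute_metrics,
    ensemble_predict,
    metrics_to_csv,
    paired_f1_test,
    per_participant_weighted_f1,
)
from .io import downsample, select_channels, window_recording
from .models import ModelConfig, reduced_family_preset, reduced_gru_preset
from .synthetic import (
    SyntheticRecording,
    default_profiles,
    desk_profiles,
    generate_cohort,
)
from .training import (
    FoldResult,
    TrainingConfig,
    concatenate_fold_results,
    lopo_cv,
    pool_cohorts,
)

EXPERIMENT_NAMES = ("architectures", "frequency", "location", "window_length", "combined")

DEFAULT_FACTORS = {
    "architectures": {"families": ["cnn", "gru", "convrec", "reconv"]},
    "frequency": {"rates": [50, 25, 20, 15, 10]},
    "location": {"sites": ["both", "thigh", "lower_back"]},
    "window_length": {"window_lens": [200, 3000]},
    "combined": {},
}


@dataclass(frozen=True)
class ExperimentSpec:
    """What to run, at what scale, with which factor levels."""

    name: str
    seed: int = 0
    output_dir: str | Path | None = None
    cohort_source: str = "synthetic"
    factors: dict = field(default_factory=dict)
    scale: str = "desk"  # "desk" (8+6 participants x 5 min) or "full" (22+18, study durations)
    young_participants: int | None = None  # override the scale's cohort sizes
    old_participants: int | None = None
    duration_min: float | None = None
    max_epochs: int = 6
    patience: int = 2
    batch_size: int = 32
    window_len: int = 200

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(
                f"unknown experiment {self.name!r}; expected one of {EXPERIMENT_NAMES}"
            )
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")


@dataclass
class LevelResult:
    """Reports for one factor level: young LOPO + old-cohort ensemble."""

    level: str
    young_report: object
    old_report: object
    young_participant_f1: list[float]
    old_participant_f1: list[float]
    folds: list[FoldResult]


def _training_config(spec: ExperimentSpec) -> TrainingConfig:
    return TrainingConfig(
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        batch_size=spec.batch_size,
        seed=spec.seed,
        window_len=spec.window_len,
    )


def build_cohorts(
    spec: ExperimentSpec,
) -> tuple[list[SyntheticRecording], list[SyntheticRecording]]:
    if spec.cohort_source != "synthetic":
        raise NotImplementedError(
            "file-backed cohorts are loaded via densehar.io.read_recording and "
            "passed to the library functions directly"
        )
    if spec.scale == "full":
        young_profile, old_profile, models = default_profiles()
    else:
        young_profile, old_profile, models = desk_profiles(
            young_participants=spec.young_participants or 8,
            old_participants=spec.old_participants or 6,
            duration_min=spec.duration_min or 5.0,
        )
    young = generate_cohort(young_profile, models, seed=spec.seed)
    old = generate_cohort(old_profile, models, seed=spec.seed + 1)
    return young, old


def _downsample_recording(rec: SyntheticRecording, rate: float) -> SyntheticRecording:
    if rate >= rec.rate:
        return rec
    signal, labels = downsample(rec.signal, rec.labels, rate)
    return SyntheticRecording(
        participant_id=rec.participant_id, cohort=rec.cohort,
        signal=signal, labels=labels, rate=rate, seed=rec.seed,
    )


def evaluate_old_cohort(
    folds: Sequence[FoldResult],
    old: Sequence[SyntheticRecording],
    site: str = "both",
) -> tuple[object, list[float]]:
    """Majority-vote the fold models over each old-cohort recording; return
    the concatenated-report and per-participant weighted F1s."""
    models = [f.model for f in folds]
    preds, truths, per_f1 = [], [], []
    for rec in old:
        signal = select_channels(rec.signal, site) if site != "both" else rec.signal
        fused, _ = ensemble_predict(models, signal)
        preds.append(fused)
        truths.append(rec.labels.labels)
        per_f1.append(compute_metrics(fused, rec.labels.labels).weighted["f1"])
    report = compute_metrics(
        np.concatenate(preds), np.concatenate(truths),
        label_names=old[0].labels.label_map,
    )
    return report, per_f1


def run_level(
    young: Sequence[SyntheticRecording],
    old: Sequence[SyntheticRecording],
    config: ModelConfig,
    tcfg: TrainingConfig,
    level: str,
    site: str = "both",
    rate: float | None = None,
) -> LevelResult:
    """LOPO on the young cohort, then fold-ensemble transfer to the old."""
    if rate is not None:
        young = [_downsample_recording(r, rate) for r in young]
        old = [_downsample_recording(r, rate) for r in old]
    folds = lopo_cv(young, config, tcfg, site=site)
    pred, truth, _ = concatenate_fold_results(folds)
    young_report = compute_metrics(pred, truth, label_names=young[0].labels.label_map)
    young_f1 = per_participant_weighted_f1(folds)
    old_report, old_f1 = evaluate_old_cohort(folds, old, site=site)
    return LevelResult(level, young_report, old_report, young_f1, old_f1, folds)


def repredict_folds(
    folds: Sequence[FoldResult],
    cohort: Sequence[SyntheticRecording],
    window_len: int,
    site: str = "both",
) -> list[FoldResult]:
    """Re-predict each fold's held-out recording in ``window_len`` chunks
    (the final remainder chunk kept), without retraining."""
    by_id = {rec.participant_id: rec for rec in cohort}
    out = []
    for fold in folds:
        rec = by_id[fold.held_out_participant]
        signal = select_channels(rec.signal, site) if site != "both" else rec.signal
        pieces = [
            fold.model.predict(sig)
            for sig, _ in window_recording(signal, rec.labels, window_len)
        ]
        probs = np.concatenate([p.probabilities for p in pieces], axis=0)
        from .models import FramePredictions

        out.append(replace_fold(fold, FramePredictions(probabilities=probs)))
    return out


def replace_fold(fold: FoldResult, predictions) -> FoldResult:
    return FoldResult(
        held_out_participant=fold.held_out_participant,
        model=fold.model,
        predictions=predictions,
        truth=fold.truth,
        train_participants=fold.train_participants,
    )


# ---------------------------------------------------------------------------
# the five experiments
# ---------------------------------------------------------------------------

def run_experiment(spec: ExperimentSpec) -> dict:
    """Execute one experiment; returns {summary, levels, tests} and writes
    CSV/JSON reports when ``spec.output_dir`` is set."""
    factors = {**DEFAULT_FACTORS[spec.name], **spec.factors}
    young, old = build_cohorts(spec)
    tcfg = _training_config(spec)
    levels: list[LevelResult] = []

    if spec.name == "architectures":
        for family in factors["families"]:
            config = reduced_family_preset(family)
            levels.append(run_level(young, old, config, tcfg, level=family))
    elif spec.name == "frequency":
        for rate in factors["rates"]:
            config = reduced_gru_preset()
            levels.append(
                run_level(young, old, config, tcfg, level=f"{rate}Hz", rate=float(rate))
            )
    elif spec.name == "location":
        for site in factors["sites"]:
            channels = 6 if site == "both" else 3
            config = reduced_gru_preset(input_channels=channels)
            levels.append(run_level(young, old, config, tcfg, level=site, site=site))
    elif spec.name == "window_length":
        base = run_level(young, old, reduced_gru_preset(), tcfg, level="trained")
        for L in factors["window_lens"]:
            folds = repredict_folds(base.folds, young, int(L))
            pred, truth, _ = concatenate_fold_results(folds)
            report = compute_metrics(pred, truth, label_names=young[0].labels.label_map)
            levels.append(
                LevelResult(
                    f"T{L}", report, base.old_report,
                    per_participant_weighted_f1(folds), base.old_participant_f1, folds,
                )
            )
    elif spec.name == "combined":
        young_only = run_level(young, old, reduced_gru_preset(), tcfg, level="young_only")
        levels.append(young_only)
        combined = pool_cohorts(young, old)
        folds = lopo_cv(combined, reduced_gru_preset(), tcfg)
        by_cohort: dict[str, list[FoldResult]] = {}
        rec_by_id = {r.participant_id: r for r in combined}
        for f in folds:
            by_cohort.setdefault(rec_by_id[f.held_out_participant].cohort, []).append(f)
        for cohort_name, cohort_folds in sorted(by_cohort.items()):
            pred, truth, _ = concatenate_fold_results(cohort_folds)
            report = compute_metrics(
                pred, truth, label_names=combined[0].labels.label_map
            )
            f1s = per_participant_weighted_f1(cohort_folds)
            levels.append(
                LevelResult(f"combined_{cohort_name}", report, report, f1s, f1s, cohort_folds)
            )

    tests = _paired_tests(spec.name, levels)
    summary = _summarise(spec.name, levels)
    bundle = {"spec": spec, "summary": summary, "levels": levels, "tests": tests}
    if spec.output_dir is not None:
        _write_bundle(spec, bundle)
    return bundle


def _paired_tests(name: str, levels: list[LevelResult]) -> dict[str, dict]:
    """Paired t-tests of each level against the first, on per-participant
    weighted F1 (young LOPO participants, matched across levels)."""
    tests: dict[str, dict] = {}
    if len(levels) < 2:
        return tests
    ref = levels[0]
    for lev in levels[1:]:
        if len(lev.young_participant_f1) != len(ref.young_participant_f1):
            continue  # different participant sets (e.g. combined-cohort splits)
        res = paired_f1_test(ref.young_participant_f1, lev.young_participant_f1)
        tests[f"{ref.level}_vs_{lev.level}"] = {
            "t_statistic": res.t_statistic,
            "p_value": res.p_value,
            "significant": res.significant,
            "degenerate": res.degenerate,
        }
    return tests


def _summarise(name: str, levels: list[LevelResult]) -> pd.DataFrame:
    rows = []
    for lev in levels:
        for cohort, report, f1s in (
            ("young", lev.young_report, lev.young_participant_f1),
            ("old", lev.old_report, lev.old_participant_f1),
        ):
            rows.append(
                {
                    "experiment": name,
                    "level": lev.level,
                    "cohort": cohort,
                    "weighted_f1": report.weighted["f1"],
                    "macro_f1": report.macro["f1"],
                    "accuracy": report.accuracy,
                    "weighted_precision": report.weighted["precision"],
                    "weighted_recall": report.weighted["recall"],
                    "participant_f1_mean": float(np.mean(f1s)),
                    "participant_f1_sd": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def _write_bundle(spec: ExperimentSpec, bundle: dict) -> None:
    out = Path(spec.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["summary"].to_csv(out / f"{spec.name}_summary.csv", index=False,
                             float_format="%.6f")
    for lev in bundle["levels"]:
        metrics_to_csv(lev.young_report, out / f"{spec.name}_{lev.level}_young.csv")
        metrics_to_csv(lev.old_report, out / f"{spec.name}_{lev.level}_old.csv")
    payload = {
        "name": spec.name,
        "seed": spec.seed,
        "scale": spec.scale,
        "tests": bundle["tests"],
        "levels": {
            lev.level: {
                "young_weighted_f1": lev.young_report.weighted["f1"],
                "old_weighted_f1": lev.old_report.weighted["f1"],
            }
            for lev in bundle["levels"]
        },
    }
    (out / f"{spec.name}_summary.json").write_text(json.dumps(payload, indent=2))
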