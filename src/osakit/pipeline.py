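"""End-to-end orchestration: simulate -> extract -> measure -> analyze.

Every stage writes its outputs to disk (cohort CSV, per-vowel formant CSV,
per-subject measurement CSV, statistical report as CSV + Markdown) so each
stage can be re-run from its on-disk inputs, and the whole bundle is
byte-identical for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acoustics, cohort, craniofacial, landmarks, stats, vowels

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("osakit.pipeline")

MATCHED_PRESETS = {
    # matched-group covariate filters, by sex
    "female-age-bmi": {"age": (41.0, 55.0), "bmi": (25.0, float("inf"))},
    "male-age-bmi": {"age": (float("-inf"), 46.0), "bmi": (25.0, 30.0)},
}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    sex: str = "female"
    cohort_size: int = 129
    features: str = "all"  # feature block for the cohort copula
    vowels: tuple[str, ...] = ("a", "e", "i", "o", "u")
    f0: float = 200.0
    noise_snr_db: float = 30.0
    n_landmark_subjects: int = 10
    matched_preset: str | None = "female-age-bmi"
    out_dir: str = "osakit-output"

    def __post_init__(self) -> None:
        if self.cohort_size < 2:
            raise ValueError("cohort_size must be >= 2")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.matched_preset is not None and self.matched_preset not in MATCHED_PRESETS:
            raise ValueError(f"unknown matched preset {self.matched_preset!r}")
        for v in self.vowels:
            if v not in "aeiou":
                raise ValueError(f"unknown vowel {v!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "vowels" in raw:
            raw["vowels"] = tuple(raw["vowels"])
        return cls(**raw)


def _stage_cohort(config: PipelineConfig, out: Path) -> pd.DataFrame:
    features = config.features
    if config.sex == "male" and features in ("speech", "all"):
        features = "craniofacial"  # no male speech marginals are published
    spec = cohort.build_reference_spec(
        config.sex, features=features, n=config.cohort_size, seed=config.seed
    )
    records = cohort.generate_cohort(spec)
    cohort.write_cohort_csv(records, out / "cohort.csv")
    log.info("cohort stage: %d subjects -> cohort.csv", len(records))
    return cohort.read_cohort_csv(out / "cohort.csv")


def _stage_vowels(config: PipelineConfig, out: Path) -> pd.DataFrame:
    rows = []
    for i, v in enumerate(config.vowels):
        seed = int(np.random.SeedSequence([config.seed, 1, i]).generate_state(1)[0] % (2**31))
        spec = vowels.table_spec(v, f0=config.f0,
                                 noise_snr_db=config.noise_snr_db, seed=seed)
        x, fs = vowels.synthesize_vowel(spec)
        wav_path = out / f"vowel_{v}.wav"
        vowels.write_wav(wav_path, x, fs)
        est, report = acoustics.analyze_vowel(x, fs, vowel=v)
        log.info("acoustic stage /%s/: source=%s exceeded=%s", v, est.source,
                 report.exceeded)
        rows.append({
            "vowel": v, "F1": est.F1, "F2": est.F2, "F3": est.F3,
            "BW1": est.BW1, "BW2": est.BW2, "BW3": est.BW3,
            "source": est.source, "flags": ";".join(est.flags),
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "formants.csv", index=False)
    return df


def _stage_landmarks(config: PipelineConfig, cohort_df: pd.DataFrame, out: Path) -> pd.DataFrame:
    rows = []
    n = min(config.n_landmark_subjects, len(cohort_df))
    for i in range(n):
        subj = cohort_df.iloc[i]
        target_p = craniofacial.CraniofacialMeasurements(
            cervicomental_contour_ratio=float(subj.get("cervicomental_ratio", 0.6)),
            face_width_ratio=float("nan"),
            trs_angle=float(subj.get("trs_angle", 113.0)),
        )
        target_f = craniofacial.CraniofacialMeasurements(
            cervicomental_contour_ratio=float("nan"),
            face_width_ratio=float(subj.get("face_width_ratio", 1.4)),
            trs_angle=float("nan"),
        )
        gt_p = landmarks.generate_landmarks("profile", target_p, seed=config.seed + i)
        gt_f = landmarks.generate_landmarks("frontal", target_f, seed=config.seed + i)
        craniofacial.write_landmarks_csv(gt_p.landmark_set, out / f"profile_{i:03d}.csv")
        craniofacial.write_landmarks_csv(gt_f.landmark_set, out / f"frontal_{i:03d}.csv")
        m = craniofacial.measure(profile=gt_p.landmark_set, frontal=gt_f.landmark_set)
        rows.append({
            "subject_id": subj["subject_id"],
            "cervicomental_ratio": m.cervicomental_contour_ratio,
            "face_width_ratio": m.face_width_ratio,
            "trs_angle": m.trs_angle,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "measurements.csv", index=False)
    log.info("landmark stage: %d subjects measured", n)
    return df


def _stage_stats(config: PipelineConfig, cohort_df: pd.DataFrame, out: Path) -> dict:
    clinical = ["ahi", "weight", "height", "age", "bmi", "cervical_perimeter"]
    feature_vars = [
        c for c in cohort_df.columns
        if c not in clinical + ["subject_id", "sex", "group"]
    ]
    report: dict[str, pd.DataFrame] = {}

    if feature_vars:
        results = stats.correlation_table(cohort_df, feature_vars, clinical)
        report["correlations"] = stats.render_correlation_table(results)

    labels = stats.assign_severity(cohort_df["ahi"].to_numpy())
    control = cohort_df[labels == "control"]
    osa = cohort_df[labels == "osa"]
    contrasts = []
    if len(control) >= 3 and len(osa) >= 3:
        for var in clinical + feature_vars:
            contrasts.append(
                stats.mann_whitney(control[var], osa[var], variable=var,
                                   group_names=("control", "osa"))
            )
        report["contrasts"] = stats.render_contrast_table(contrasts)

    if config.matched_preset is not None:
        spec = stats.MatchedSubsetSpec(filters=MATCHED_PRESETS[config.matched_preset])
        try:
            _, _, verification = stats.build_matched_subset(cohort_df, spec)
            report["matched_verification"] = verification
        except ValueError as exc:
            log.warning("matched-subset stage skipped: %s", exc)

    report["descriptives"] = stats.render_descriptive_table(cohort_df, clinical)

    md_parts = []
    for name, df in report.items():
        df.to_csv(out / f"report_{name}.csv")
        md_parts.append(f"## {name}\n\n{df.to_markdown()}\n")
    (out / "report.md").write_text("\n".join(md_parts))
    log.info("stats stage: %s", ", ".join(report))
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns {stage: outputs} and writes the bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "cohort"
    try:
        cohort_df = bundle["cohort"] = _stage_cohort(config, out)
        stage = "acoustics"
        bundle["formants"] = _stage_vowels(config, out)
        stage = "landmarks"
        bundle["measurements"] = _stage_landmarks(config, cohort_df, out)
        stage = "stats"
        bundle["report"] = _stage_stats(config, cohort_df, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
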