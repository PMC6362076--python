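"""End-to-end orchestration: simulate/load -> score -> threshold -> describe ->
stability -> recovery, with every artifact written to an output directory and
the numeric results assembled into a single serializable report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    DEFAULT_LOF_FEATURES,
    CohortSpec,
    generate_cohort,
    read_features,
    read_labels,
    summarize_cohort,
)
from .lof import score_features
from .stability import half_sample_stability, omit_and_recompute, recovery_metrics
from .thresholding import (
    feature_correlation_matrix,
    flag_anomalies,
    percentile_cutoff,
    suggest_threshold_region,
    two_sd_outlier_counts,
)

logger = logging.getLogger(__name__)

#: literature anchors for context only — never used in any computation
PREVALENCE_ANCHORS = {
    "developmental_disabilities_pct": 13.0,
    "asd_pct_range": (1.5, 2.0),
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on; seeds are mandatory for any
    stochastic stage so runs are reproducible end to end."""

    cohort_spec: CohortSpec | None = None
    features_path: str | None = None
    labels_path: str | None = None
    feature_columns: tuple[str, ...] = DEFAULT_LOF_FEATURES
    k: int = 20
    percentile: float = 95.0
    use_knee: bool = False
    knee_window: tuple[float, float] = (85.0, 99.0)
    knee_flatness_tol: float = 1.0
    stability_reps: int = 1000
    stability_seed: int = 0
    secondary_cutoff: float | None = None
    run_stability: bool = True
    histogram_bins: int = 40
    out_dir: str = "lofscreen_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.cohort_spec is None) == (self.features_path is None):
            raise ConfigError(
                "exactly one of cohort_spec / features_path must be given"
            )
        if self.features_path is not None and not Path(self.features_path).exists():
            raise ConfigError(f"features file not found: {self.features_path}")
        if self.labels_path is not None and not Path(self.labels_path).exists():
            raise ConfigError(f"labels file not found: {self.labels_path}")
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if not 0.0 < self.percentile < 100.0:
            raise ConfigError(f"percentile must lie in (0, 100), got {self.percentile}")
        if self.stability_reps < 1:
            raise ConfigError("stability_reps must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort_spec is not None:
            d["cohort_spec"] = json.loads(self.cohort_spec.to_json())
        d["feature_columns"] = list(self.feature_columns)
        d["knee_window"] = list(self.knee_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("cohort_spec") is not None:
            d["cohort_spec"] = CohortSpec.from_json(json.dumps(d["cohort_spec"]))
        for key in ("feature_columns", "knee_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class AnalysisReport:
    """All numeric results of one pipeline run; round-trips through JSON."""

    config: dict
    cohort_summary: dict | None
    threshold: dict
    removal_check: dict
    half_sample: dict | None
    recovery: dict | None
    prevalence_context: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def export_histogram(scores, *, bin_count: int | None = None,
                     bin_width: float | None = None) -> pd.DataFrame:
    """Histogram of a score vector as a bin-edge/count table (counts sum to n)."""
    arr = np.asarray(scores, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty score vector")
    if bin_width is not None:
        edges = np.arange(arr.min(), arr.max() + bin_width, bin_width)
        if edges[-1] <= arr.max():
            edges = np.append(edges, edges[-1] + bin_width)
    else:
        edges = np.histogram_bin_edges(arr, bins=bin_count or 40)
    counts, edges = np.histogram(arr, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def prevalence_context(flagged_fraction: float) -> dict:
    """Compare the flagged percentage with literature prevalence anchors."""
    pct = 100.0 * flagged_fraction
    lo, hi = PREVALENCE_ANCHORS["asd_pct_range"]
    dd = PREVALENCE_ANCHORS["developmental_disabilities_pct"]
    return {
        "flagged_pct": pct,
        "developmental_disabilities_pct": dd,
        "asd_pct_range": [lo, hi],
        "between_asd_and_dd": bool(hi <= pct <= dd),
    }


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run every configured stage, writing artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("resolved config: %s", json.dumps(config.to_dict(), sort_keys=True))

    # --- stage: simulate or load -----------------------------------------
    labels = None
    cohort_summary = None
    if config.cohort_spec is not None:
        cohort = generate_cohort(config.cohort_spec)
        cohort.write_csv(out / "cohort.csv", out / "labels.csv")
        features = cohort.features
        labels = cohort.labels
        cohort_summary = summarize_cohort(cohort)
    else:
        features = read_features(config.features_path)
        if config.labels_path is not None:
            labels = read_labels(config.labels_path)

    feature_cols = [c for c in config.feature_columns if c in features.columns]
    missing = set(config.feature_columns) - set(feature_cols)
    if missing:
        raise ConfigError(f"feature columns not in table: {sorted(missing)}")
    X = features[feature_cols]

    # --- stage: score ------------------------------------------------------
    scores = score_features(X, config.k).as_series()
    scores.to_csv(out / "scores.csv")

    # --- stage: threshold --------------------------------------------------
    percentile = config.percentile
    knee = None
    if config.use_knee:
        knee = suggest_threshold_region(
            scores, search_window=config.knee_window,
            flatness_tol=config.knee_flatness_tol,
            fallback_percentile=config.percentile,
        )
        percentile = knee.percentile
    cutoff = percentile_cutoff(scores, percentile)
    decision = flag_anomalies(
        scores, cutoff,
        method="bump_knee" if config.use_knee else "fixed_percentile",
        percentile=percentile,
    )
    threshold_block = decision.to_dict()
    if knee is not None:
        threshold_block["knee"] = {
            "knee_found": knee.knee_found, "diagnostics": knee.diagnostics,
        }
    (out / "threshold.json").write_text(json.dumps(threshold_block, indent=2))
    pd.Series(decision.flagged_ids, name="subject_id").to_csv(
        out / "flagged_ids.csv", index=False
    )

    # --- stage: describe ---------------------------------------------------
    export_histogram(scores, bin_count=config.histogram_bins).to_csv(
        out / "score_histogram.csv", index=False
    )
    two_sd_outlier_counts(X).to_frame().to_csv(out / "two_sd_counts.csv")
    feature_correlation_matrix(X).to_csv(out / "correlation_matrix.csv")

    # --- stage: omit-and-recompute ----------------------------------------
    removal = omit_and_recompute(X, decision.flagged_ids, config.k, cutoff)

    # --- stage: half-sample stability --------------------------------------
    half_block = None
    if config.run_stability:
        report = half_sample_stability(
            X, config.k, cutoff,
            secondary_cutoff=config.secondary_cutoff,
            n_reps=config.stability_reps,
            seed=config.stability_seed,
            full_scores=scores,
            percentile=percentile,
        )
        report.per_rep.to_csv(out / "half_sample_reps.csv")
        half_block = report.to_dict()

    # --- stage: recovery ----------------------------------------------------
    recovery_block = None
    if labels is not None:
        recovery_block = recovery_metrics(decision.flagged_ids, labels).to_dict()

    report = AnalysisReport(
        config=config.to_dict(),
        cohort_summary=cohort_summary,
        threshold=threshold_block,
        removal_check=removal.to_dict(),
        half_sample=half_block,
        recovery=recovery_block,
        prevalence_context=prevalence_context(decision.flagged_fraction),
    )
    (out / "report.json").write_text(report.to_json())
    return report
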