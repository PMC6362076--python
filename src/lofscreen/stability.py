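"""Validation protocols for the anomaly calls.

Two checks probe whether a flagged set is a real low-density tail or an
artifact of the detector's own percentile construction:

* omit-and-recompute — remove the flagged subjects, re-standardize and
  re-score the remainder, and count how many now exceed the ORIGINAL cutoff.
  A separated atypical tail leaves few new exceedances; a pure percentile
  artifact regenerates a fresh ~5%-sized set.
* half-sample resampling — many random 50% subsamples, each re-standardized
  and re-scored; per replicate the protocol records (a) the percentage of
  within-half anomalies that are also full-sample anomalies, (b) the Pearson
  correlation between half-sample and full-sample scores over the sampled
  subjects, and (c) the percentage of within-half anomalies whose full-sample
  score reaches a relaxed secondary cutoff.

When hidden labels exist (synthetic cohorts), ``recovery_metrics`` reports
precision/recall/F1 of the flagged set against the atypical labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lof import score_features


@dataclass
class RemovalCheck:
    original_cutoff: float
    n_removed: int
    new_anomaly_ids: list
    recomputed_scores: pd.Series

    @property
    def n_new(self) -> int:
        return len(self.new_anomaly_ids)

    def to_dict(self) -> dict:
        return {
            "original_cutoff": self.original_cutoff,
            "n_removed": self.n_removed,
            "n_new": self.n_new,
            "new_anomaly_ids": list(self.new_anomaly_ids),
        }


@dataclass
class HalfSampleReport:
    n_reps: int
    seed: int
    primary_cutoff: float
    secondary_cutoff: float
    overlap_mean_pct: float
    score_correlation_mean: float
    secondary_fraction_mean_pct: float
    n_reps_without_anomalies: int
    per_rep: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "seed": self.seed,
            "primary_cutoff": self.primary_cutoff,
            "secondary_cutoff": self.secondary_cutoff,
            "overlap_mean_pct": self.overlap_mean_pct,
            "score_correlation_mean": self.score_correlation_mean,
            "secondary_fraction_mean_pct": self.secondary_fraction_mean_pct,
            "n_reps_without_anomalies": self.n_reps_without_anomalies,
        }


@dataclass
class RecoveryMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


def omit_and_recompute(
    features: pd.DataFrame,
    flagged_ids,
    k: int,
    cutoff: float,
    *,
    standardize_first: bool = True,
) -> RemovalCheck:
    """Drop the flagged subjects, re-score the rest, count new exceedances.

    Standardization is refit on the reduced table (same policy as the
    original scoring); exceedance is judged against the ORIGINAL cutoff with
    the same strict ``>`` rule.
    """
    flagged = pd.Index(flagged_ids)
    unknown = flagged.difference(features.index)
    if len(unknown) > 0:
        raise KeyError(f"flagged ids not in the feature table: {list(unknown)[:5]}")
    reduced = features.drop(index=flagged)
    if len(reduced) <= k:
        raise ValueError(
            f"reduced sample (n={len(reduced)}) too small for k={k}"
        )
    result = score_features(reduced, k, standardize_first=standardize_first)
    scores = result.as_series()
    new_ids = list(scores.index[scores.to_numpy() > cutoff])
    return RemovalCheck(
        original_cutoff=float(cutoff),
        n_removed=len(flagged),
        new_anomaly_ids=new_ids,
        recomputed_scores=scores,
    )


def half_sample_stability(
    features: pd.DataFrame,
    k: int,
    primary_cutoff: float,
    *,
    secondary_cutoff: float | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    full_scores: pd.Series | None = None,
    percentile: float = 95.0,
    corr_method: str = "pearson",
    standardize_first: bool = True,
) -> HalfSampleReport:
    """Half-sample resampling stability of LOF scores and anomaly calls.

    Each replicate draws floor(n/2) subjects without replacement (one seed
    sequence per run, spawned per-replicate substreams), refits
    standardization within the half and re-scores. ``secondary_cutoff``
    defaults to the full-sample score percentile at ``percentile - 2.5``,
    a mild relaxation of the primary cutoff. Replicates with zero within-half
    anomalies are excluded from the overlap/secondary means and counted in
    ``n_reps_without_anomalies``.
    """
    n = len(features)
    if n < 2 * k + 2:
        raise ValueError(f"need n >= 2k+2 = {2 * k + 2} subjects, got {n}")
    if corr_method not in ("pearson", "spearman"):
        raise ValueError(f"unknown corr_method {corr_method!r}")

    if full_scores is None:
        full_scores = score_features(
            features, k, standardize_first=standardize_first
        ).as_series()
    full_scores = full_scores.reindex(features.index)
    if secondary_cutoff is None:
        secondary_cutoff = float(
            np.percentile(full_scores.to_numpy(), percentile - 2.5)
        )
    full_flagged = set(full_scores.index[full_scores.to_numpy() > primary_cutoff])

    half = n // 2
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    records = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        take = rng.choice(n, size=half, replace=False)
        sub = features.iloc[np.sort(take)]
        half_scores = score_features(
            sub, k, standardize_first=standardize_first
        ).as_series()
        full_sub = full_scores.loc[half_scores.index]

        if corr_method == "pearson":
            corr = float(np.corrcoef(half_scores, full_sub)[0, 1])
        else:
            corr = float(half_scores.corr(full_sub, method="spearman"))

        anomalies = half_scores.index[half_scores.to_numpy() > primary_cutoff]
        n_anom = len(anomalies)
        if n_anom > 0:
            overlap = 100.0 * sum(a in full_flagged for a in anomalies) / n_anom
            secondary = (
                100.0
                * (full_scores.loc[anomalies].to_numpy() >= secondary_cutoff).sum()
                / n_anom
            )
        else:
            overlap = np.nan
            secondary = np.nan
        records.append(
            {
                "rep": rep,
                "n_half_anomalies": n_anom,
                "overlap_pct": overlap,
                "score_correlation": corr,
                "secondary_fraction_pct": secondary,
            }
        )

    per_rep = pd.DataFrame.from_records(records).set_index("rep")
    empty = int((per_rep["n_half_anomalies"] == 0).sum())
    return HalfSampleReport(
        n_reps=n_reps,
        seed=seed,
        primary_cutoff=float(primary_cutoff),
        secondary_cutoff=float(secondary_cutoff),
        overlap_mean_pct=float(per_rep["overlap_pct"].mean()),
        score_correlation_mean=float(per_rep["score_correlation"].mean()),
        secondary_fraction_mean_pct=float(per_rep["secondary_fraction_pct"].mean()),
        n_reps_without_anomalies=empty,
        per_rep=per_rep,
    )


def recovery_metrics(flagged_ids, labels: pd.Series) -> RecoveryMetrics:
    """Precision/recall/F1 of the flagged set against hidden atypical labels.

    Empty flagged set: recall 0 and, by convention, precision 0.
    """
    flagged = set(flagged_ids)
    known = set(labels.index)
    unknown = flagged - known
    if unknown:
        raise KeyError(f"flagged ids without labels: {sorted(unknown)[:5]}")
    positive = set(labels.index[labels == "atypical"])
    tp = len(flagged & positive)
    fp = len(flagged - positive)
    fn = len(positive - flagged)
    tn = len(known) - tp - fp - fn
    precision = tp / (tp + fp) if flagged else 0.0
    recall = tp / (tp + fn) if positive else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return RecoveryMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn, precision=precision, recall=recall, f1=f1
    )
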