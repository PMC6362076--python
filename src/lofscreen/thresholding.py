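"""Turning a score vector into anomaly calls, plus descriptive views.

The primary rule is a fixed percentile: the cutoff is the linear-interpolation
quantile (sorted x_1..x_n, the q-quantile at position 1 + q(n-1)) and a
subject is flagged iff its score is STRICTLY above the cutoff — ties at the
cutoff are never anomalies. A qualitative alternative is the "bump-to-knee"
heuristic: scan the right tail of the score density for the point where the
central bump gives way to a flat, low-density regime, the region where
genuine anomalies are expected to live.

Two descriptive companions mirror classic univariate practice: per-variable
counts of subjects outside two standard deviations, and the pairwise Pearson
correlation matrix of the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ThresholdDecision:
    method: str  # "fixed_percentile" | "bump_knee"
    percentile: float
    cutoff: float
    flagged_ids: list
    n_total: int

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_ids)

    @property
    def flagged_fraction(self) -> float:
        return self.n_flagged / self.n_total

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "percentile": self.percentile,
            "cutoff": self.cutoff,
            "n_total": self.n_total,
            "n_flagged": self.n_flagged,
            "flagged_fraction": self.flagged_fraction,
            "flagged_ids": list(self.flagged_ids),
        }


@dataclass
class ThresholdSuggestion:
    """Outcome of the knee scan: a percentile plus diagnostics."""

    percentile: float
    knee_found: bool
    diagnostics: dict = field(default_factory=dict)


def _as_score_series(scores) -> pd.Series:
    if isinstance(scores, pd.Series):
        s = scores.astype(float)
    else:
        arr = np.asarray(scores, dtype=float).ravel()
        s = pd.Series(arr, index=pd.RangeIndex(len(arr)))
    if len(s) == 0:
        raise ValueError("empty score vector")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    return s


def percentile_cutoff(scores, p: float) -> float:
    """Linear-interpolation percentile of the scores, p in (0, 100)."""
    s = _as_score_series(scores)
    if not 0.0 < p < 100.0:
        raise ValueError(f"percentile must lie in (0, 100), got {p}")
    return float(np.percentile(s.to_numpy(), p, method="linear"))


def flag_anomalies(
    scores, cutoff: float, *, method: str = "fixed_percentile",
    percentile: float = float("nan"),
) -> ThresholdDecision:
    """Flag subjects with score strictly above ``cutoff``."""
    s = _as_score_series(scores)
    flagged = s.index[s.to_numpy() > cutoff]
    return ThresholdDecision(
        method=method,
        percentile=float(percentile),
        cutoff=float(cutoff),
        flagged_ids=list(flagged),
        n_total=len(s),
    )


def flag_at_percentile(scores, p: float) -> ThresholdDecision:
    """Convenience: percentile cutoff followed by strict flagging."""
    cutoff = percentile_cutoff(scores, p)
    return flag_anomalies(scores, cutoff, method="fixed_percentile", percentile=p)


def suggest_threshold_region(
    scores,
    search_window: tuple[float, float] = (85.0, 99.0),
    flatness_tol: float = 1.0,
    *,
    run_length: int = 4,
    grid_step: float = 0.5,
    density_drop: float = 0.5,
    fallback_percentile: float = 95.0,
) -> ThresholdSuggestion:
    """Locate the percentile where the score density turns from bump to flat tail.

    A Gaussian KDE of the scores (robust Silverman bandwidth, so the heavy
    tail does not smear the bulk) is evaluated at the quantiles of a
    percentile grid over ``search_window``. Scanning rightward, the
    suggestion is the smallest grid percentile opening a run of
    ``run_length`` consecutive steps whose relative density slope per score
    unit, scaled by the IQR (|df| / (f dx) * IQR, a dimensionless steepness),
    stays below ``flatness_tol`` AND whose density has already dropped below
    ``density_drop`` times the modal density — the second condition is what
    separates a genuine low-density tail from a distribution that is simply
    flat everywhere. With no such knee the configured fallback percentile is
    returned, marked ``knee_found=False``.

    All quantities compared are ratios, so the suggestion is invariant to
    positive rescaling of the scores. Requires >= 200 scores; below that the
    tail is too sparsely populated and ``fixed_percentile`` should be used.
    """
    s = _as_score_series(scores).to_numpy()
    if len(s) < 200:
        raise ValueError(
            "knee detection needs >= 200 scores; use a fixed percentile instead"
        )
    lo, hi = search_window
    if not 0.0 < lo < hi < 100.0:
        raise ValueError(f"invalid search window {search_window}")

    # Silverman-style robust bandwidth: min(SD, IQR/1.34); the plain SD is
    # inflated by the very tail being scanned, which would smear the bulk
    sd = s.std(ddof=1)
    if sd == 0.0:
        return ThresholdSuggestion(
            percentile=float(fallback_percentile), knee_found=False,
            diagnostics={"reason": "degenerate (constant) score distribution"},
        )
    iqr = np.subtract(*np.percentile(s, [75, 25]))
    scale = min(sd, iqr / 1.34) or sd
    kde = stats.gaussian_kde(s, bw_method=0.9 * scale / sd * len(s) ** (-1 / 5))
    mode_grid = np.linspace(s.min(), s.max(), 512)
    f_mode = float(kde(mode_grid).max())

    pgrid = np.arange(lo, hi + grid_step / 2, grid_step)
    xq = np.percentile(s, pgrid, method="linear")
    f = kde(xq)

    dx = np.maximum(np.diff(xq), 1e-300)
    rel_slope = np.abs(np.diff(f)) / np.maximum(f[:-1], 1e-300) / dx * iqr
    low_density = f[:-1] < density_drop * f_mode
    ok = (rel_slope < flatness_tol) & low_density

    for i in range(len(ok) - run_length + 1):
        if ok[i : i + run_length].all():
            return ThresholdSuggestion(
                percentile=float(pgrid[i]),
                knee_found=True,
                diagnostics={
                    "mode_density": f_mode,
                    "density_at_knee": float(f[i]),
                    "relative_slope_at_knee": float(rel_slope[i]),
                },
            )
    return ThresholdSuggestion(
        percentile=float(fallback_percentile),
        knee_found=False,
        diagnostics={"reason": "no knee found in search window",
                     "mode_density": f_mode},
    )


@dataclass
class TwoSDReport:
    """Per-variable and any-variable |z| > 2 exceedance counts."""

    per_variable: dict  # name -> {"count", "fraction", "zero_variance", "ids"}
    n_any_variable: int
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: {
                    "count": rec["count"],
                    "fraction": rec["fraction"],
                    "zero_variance": rec["zero_variance"],
                }
                for name, rec in self.per_variable.items()
            }
        ).T


def two_sd_outlier_counts(features: pd.DataFrame) -> TwoSDReport:
    """Count subjects more than two SDs from each variable's mean.

    Computed on raw-feature z-scores, as a genuinely univariate alternative
    to the multivariate LOF view. Zero-variance variables report 0 with a
    flag rather than an error.
    """
    per: dict = {}
    any_mask = np.zeros(len(features), dtype=bool)
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0.0:
            per[name] = {
                "count": 0, "fraction": 0.0, "zero_variance": True, "ids": [],
            }
            continue
        z = (col - col.mean()) / sd
        mask = np.abs(z) > 2.0
        any_mask |= mask
        per[name] = {
            "count": int(mask.sum()),
            "fraction": float(mask.mean()),
            "zero_variance": False,
            "ids": list(features.index[mask]),
        }
    return TwoSDReport(
        per_variable=per, n_any_variable=int(any_mask.sum()), n_total=len(features)
    )


def feature_correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations; zero-variance columns yield NaN entries."""
    if len(features) < 3:
        raise ValueError("correlation matrix needs at least 3 subjects")
    for name in features.columns:
        if not np.issubdtype(features[name].dtype, np.number):
            raise TypeError(f"non-numeric column: {name!r}")
    return features.corr(method="pearson")
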