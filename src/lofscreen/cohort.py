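"""Synthetic toddler behavioral cohorts.

Generates labeled feature tables emulating a community screening sample of
toddlers (17-25 months): a parent-rated reciprocal-social-behavior total
(vrRSB-like), four repetitive-behavior subscales (RBS-EC-like), an expressive
vocabulary count (MCDI-like words produced), age in months and sex. The bulk
of the cohort is a "typical" population with correlated continuous/count
dimensions and age-linked vocabulary; a small atypical subpopulation deviates
upward on the social/repetitive scales by a right-skewed, subject- and
scale-specific severity (mean shift = the configured effect size), with
vocabulary decoupled from age. The atypical labels are hidden from the
scoring pipeline
(written to a separate file) so anomaly detection can be evaluated blind.

The generator is a latent-Gaussian copula: a correlated multivariate-normal
latent drives the continuous scale totals (linear maps to plausible scale
ranges, floored at zero) and, through its normal CDF, an overdispersed
negative-binomial vocabulary marginal. It makes no claim of item-level
psychometric realism; it preserves the correlation structure the downstream
density-based analysis exploits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

TYPICAL = "typical"
ATYPICAL = "atypical"

#: columns of the generated feature table, in order
FEATURE_COLUMNS = (
    "social_atypicality",
    "repetitive_motor",
    "ritual_routine",
    "restricted_interests",
    "self_directed",
    "vocabulary_count",
    "age_months",
    "sex",
)

#: default columns entering the LOF distance computation (sex excluded:
#: a binary code distorts Euclidean density estimates)
DEFAULT_LOF_FEATURES = (
    "social_atypicality",
    "repetitive_motor",
    "ritual_routine",
    "restricted_interests",
    "self_directed",
    "vocabulary_count",
    "age_months",
)

#: (mean, SD) of each continuous scale total in the typical group
SCALE_MARGINALS = {
    "social_atypicality": (20.0, 5.0),
    "repetitive_motor": (8.0, 2.5),
    "ritual_routine": (7.0, 2.5),
    "restricted_interests": (6.0, 2.0),
    "self_directed": (5.0, 2.0),
}

#: typical-group vocabulary marginal: negative binomial, heavily overdispersed
VOCAB_MEAN = 150.0
VOCAB_DISPERSION = 3.0

#: latent correlation among the four repetitive subscales
REPETITIVE_INTERCORRELATION = 0.5


class CohortValidationError(ValueError):
    """Invalid cohort specification; ``field`` names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; identical specs yield identical cohorts."""

    n_subjects: int
    seed: int
    age_range_months: tuple[float, float] = (17.0, 25.0)
    contamination_rate: float = 0.05
    effect_size_sd: float = 3.0
    typical_correlation: float = 0.4
    vocab_age_correlation: float = 0.5
    atypical_dispersion: float = 1.5
    severity_shape: float = 0.7
    atypical_vocab_ratio: float = 0.5

    def __post_init__(self):
        if not isinstance(self.n_subjects, (int, np.integer)) or self.n_subjects < 2:
            raise CohortValidationError("n_subjects", "must be an integer >= 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise CohortValidationError("seed", "must be an integer")
        lo, hi = self.age_range_months
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise CohortValidationError(
                "age_range_months", "must be a nonempty interval (lo < hi)"
            )
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise CohortValidationError("contamination_rate", "must lie in [0, 1]")
        if not self.effect_size_sd >= 0.0:
            raise CohortValidationError("effect_size_sd", "must be nonnegative")
        if not -1.0 < self.typical_correlation < 1.0:
            raise CohortValidationError("typical_correlation", "must lie in (-1, 1)")
        if not -1.0 < self.vocab_age_correlation < 1.0:
            raise CohortValidationError("vocab_age_correlation", "must lie in (-1, 1)")
        if not self.atypical_dispersion > 0.0:
            raise CohortValidationError("atypical_dispersion", "must be positive")
        if not self.severity_shape > 0.0:
            raise CohortValidationError("severity_shape", "must be positive")
        if not self.atypical_vocab_ratio > 0.0:
            raise CohortValidationError("atypical_vocab_ratio", "must be positive")
        try:
            np.linalg.cholesky(_latent_correlation(self.typical_correlation))
        except np.linalg.LinAlgError:
            raise CohortValidationError(
                "typical_correlation",
                "latent correlation matrix is not positive definite",
            ) from None

    @property
    def n_atypical(self) -> int:
        # half-up rounding: a fixed-count design, not per-subject Bernoulli
        return int(math.floor(self.contamination_rate * self.n_subjects + 0.5))

    def to_json(self) -> str:
        d = asdict(self)
        d["age_range_months"] = list(self.age_range_months)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        if "age_range_months" in d:
            d["age_range_months"] = tuple(d["age_range_months"])
        return cls(**d)


def _latent_correlation(typical_correlation: float) -> np.ndarray:
    """5x5 latent correlation: social (index 0) vs four repetitive subscales."""
    r = np.full((5, 5), REPETITIVE_INTERCORRELATION)
    r[0, 1:] = r[1:, 0] = typical_correlation
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SyntheticCohort:
    """A generated cohort: features indexed by subject id, hidden labels, spec."""

    features: pd.DataFrame
    labels: pd.Series
    spec: CohortSpec

    @property
    def subject_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    def write_csv(self, features_path, labels_path) -> None:
        """Write features and labels to separate CSVs (scoring can run blind)."""
        self.features.to_csv(features_path, index_label="subject_id")
        self.labels.rename("label").to_csv(labels_path, index_label="subject_id")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from ``spec``. Fully seeded: same spec, same table.

    Typical subjects come from a correlated latent MVN mapped onto scale
    ranges; vocabulary is a negative-binomial count tied to age through a
    Gaussian copula at ``vocab_age_correlation``. The fixed-count atypical
    subgroup deviates upward on every social/repetitive scale by a severity
    drawn per subject and scale from Gamma(``severity_shape``) scaled so the
    mean shift is exactly ``effect_size_sd`` typical-group SDs — a
    right-skewed severity continuum (many milder cases, few severe ones) with
    heterogeneous per-child profiles, so the subgroup is a diffuse
    low-density tail rather than a second tight cluster. Atypical baseline
    scatter is additionally inflated by ``atypical_dispersion``, and atypical
    vocabulary is decoupled from age (copula correlation 0) with its mean
    scaled by ``atypical_vocab_ratio``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_atyp = spec.n_atypical

    # fixed draw order keeps output bitwise reproducible
    u_age = rng.random(n)
    sex = rng.integers(0, 2, size=n)
    z_latent = rng.standard_normal((n, 5))
    eps_vocab = rng.standard_normal(n)
    severity = rng.gamma(
        spec.severity_shape, 1.0 / spec.severity_shape, size=(n, 5)
    )  # mean 1 per subject-scale draw
    atypical_positions = rng.permutation(n)[:n_atyp]

    is_atyp = np.zeros(n, dtype=bool)
    is_atyp[atypical_positions] = True

    lo, hi = spec.age_range_months
    age = lo + (hi - lo) * u_age

    chol = np.linalg.cholesky(_latent_correlation(spec.typical_correlation))
    z = z_latent @ chol.T
    z[is_atyp] *= spec.atypical_dispersion

    cols: dict[str, np.ndarray] = {}
    for j, (name, (mu, sd)) in enumerate(SCALE_MARGINALS.items()):
        vals = mu + sd * z[:, j]
        vals[is_atyp] += spec.effect_size_sd * sd * severity[is_atyp, j]
        np.clip(vals, 0.0, None, out=vals)
        cols[name] = vals

    # vocabulary: Gaussian copula against the age latent, NB marginal
    z_age = stats.norm.ppf(np.clip(u_age, 1e-12, 1.0 - 1e-12))
    rho = spec.vocab_age_correlation
    z_vocab = rho * z_age + math.sqrt(1.0 - rho * rho) * eps_vocab
    z_vocab[is_atyp] = eps_vocab[is_atyp]  # age-decoupled
    u_vocab = stats.norm.cdf(z_vocab)
    mean_vocab = np.where(
        is_atyp, VOCAB_MEAN * spec.atypical_vocab_ratio, VOCAB_MEAN
    )
    r = VOCAB_DISPERSION
    p = r / (r + mean_vocab)
    cols["vocabulary_count"] = stats.nbinom.ppf(u_vocab, r, p).astype(np.int64)

    cols["age_months"] = age
    cols["sex"] = sex

    subject_ids = [f"S{i:05d}" for i in range(n)]
    features = pd.DataFrame(cols, index=pd.Index(subject_ids, name="subject_id"))
    features = features[list(FEATURE_COLUMNS)]
    labels = pd.Series(
        np.where(is_atyp, ATYPICAL, TYPICAL),
        index=features.index,
        name="label",
    )
    return SyntheticCohort(features=features, labels=labels, spec=spec)


def summarize_cohort(cohort: SyntheticCohort) -> dict:
    """Per-group feature means/SDs, label counts and vocabulary-age correlation.

    Empty groups are absent from the summary, never reported as zeros.
    """
    if cohort.n_subjects == 0:
        raise ValueError("cannot summarize an empty cohort")
    numeric = cohort.features.drop(columns=["sex"])
    groups: dict[str, dict] = {}
    for label in (TYPICAL, ATYPICAL):
        mask = cohort.labels == label
        if not mask.any():
            continue
        block = numeric.loc[mask]
        corr = np.nan
        if len(block) >= 3:
            corr = float(
                np.corrcoef(block["vocabulary_count"], block["age_months"])[0, 1]
            )
        groups[label] = {
            "n": int(mask.sum()),
            "feature_means": block.mean().to_dict(),
            "feature_sds": block.std(ddof=1).to_dict(),
            "vocabulary_age_correlation": corr,
        }
    return {
        "n_subjects": cohort.n_subjects,
        "label_counts": cohort.labels.value_counts().to_dict(),
        "groups": groups,
    }


def read_features(path) -> pd.DataFrame:
    """Read a feature table written by :meth:`SyntheticCohort.write_csv`."""
    return pd.read_csv(path, index_col="subject_id")


def read_labels(path) -> pd.Series:
    """Read the subject_id,label CSV companion file."""
    return pd.read_csv(path, index_col="subject_id")["label"]
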