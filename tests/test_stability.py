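"""Stability protocols: omit-and-recompute, half-sample resampling, recovery."""

import numpy as np
import pandas as pd
import pytest

from lofscreen import (
    CohortSpec,
    flag_at_percentile,
    generate_cohort,
    half_sample_stability,
    omit_and_recompute,
    recovery_metrics,
    score_features,
)

K = 20  # default neighborhood size


class TestOmitAndRecompute:
    def test_empty_removal_is_a_no_op(self, reference_features, reference_scores,
                                      reference_decision):
        check = omit_and_recompute(
            reference_features, [], K, reference_decision.cutoff
        )
        assert check.n_removed == 0
        assert np.allclose(check.recomputed_scores, reference_scores, atol=1e-12)
        assert check.n_new == reference_decision.n_flagged

    def test_new_anomalies_disjoint_from_removed(self, reference_features,
                                                 reference_decision):
        check = omit_and_recompute(
            reference_features, reference_decision.flagged_ids,
            K, reference_decision.cutoff,
        )
        assert set(check.new_anomaly_ids).isdisjoint(reference_decision.flagged_ids)

    def test_unknown_id_errors(self, reference_features):
        with pytest.raises(KeyError):
            omit_and_recompute(reference_features, ["nope"], K, 1.0)

    def test_reduced_sample_too_small_for_k(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            omit_and_recompute(df, list(df.index[:4]), k=9, cutoff=1.0)

    def test_contamination_free_percentile_tail_regenerates(self):
        """Without a separated subgroup the flagged 5% are density
        fluctuations, so removal regenerates a fresh tail: strictly more new
        exceedances than in the matched contaminated cohort."""
        results = {}
        for rate in (0.0, 0.05):
            cohort = generate_cohort(
                CohortSpec(n_subjects=1570, seed=42, contamination_rate=rate)
            )
            X = cohort.features.drop(columns=["sex"])
            scores = score_features(X, K).as_series()
            dec = flag_at_percentile(scores, 95)
            results[rate] = omit_and_recompute(
                X, dec.flagged_ids, K, dec.cutoff
            ).n_new
        assert results[0.0] > results[0.05]


@pytest.fixture(scope="module")
def small_report(reference_features, reference_scores, reference_decision):
    return half_sample_stability(
        reference_features, K, reference_decision.cutoff,
        n_reps=50, seed=11, full_scores=reference_scores,
    )


class TestHalfSampleStability:
    def test_identical_seed_reproduces_report(self, reference_features,
                                              reference_scores,
                                              reference_decision):
        kwargs = dict(n_reps=8, seed=5, full_scores=reference_scores)
        a = half_sample_stability(reference_features, K,
                                  reference_decision.cutoff, **kwargs)
        b = half_sample_stability(reference_features, K,
                                  reference_decision.cutoff, **kwargs)
        assert a.to_dict() == b.to_dict()
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)

    def test_equal_cutoffs_make_secondary_match_overlap_on_tie_free_scores(
        self, reference_features, reference_scores, reference_decision
    ):
        """With secondary == primary cutoff the secondary fraction uses >= on
        the full-sample scores while the overlap uses the flagged set (>);
        tie-free continuous scores make the two per-rep quantities equal."""
        report = half_sample_stability(
            reference_features, K, reference_decision.cutoff,
            secondary_cutoff=reference_decision.cutoff,
            n_reps=10, seed=3, full_scores=reference_scores,
        )
        ok = report.per_rep.dropna()
        assert np.allclose(ok["overlap_pct"], ok["secondary_fraction_pct"])

    def test_secondary_fraction_monotone_in_secondary_cutoff(
        self, reference_features, reference_scores, reference_decision
    ):
        fractions = []
        for sc in [1.0, 1.15, reference_decision.cutoff, 2.0]:
            rep = half_sample_stability(
                reference_features, K, reference_decision.cutoff,
                secondary_cutoff=sc, n_reps=10, seed=7,
                full_scores=reference_scores,
            )
            fractions.append(rep.secondary_fraction_mean_pct)
        assert all(a >= b - 1e-9 for a, b in zip(fractions, fractions[1:]))

    def test_relaxed_secondary_cutoff_dominates_overlap(self, small_report):
        assert small_report.secondary_cutoff <= small_report.primary_cutoff
        assert (
            small_report.secondary_fraction_mean_pct
            >= small_report.overlap_mean_pct
        )

    def test_default_secondary_cutoff_relaxes_primary(self, small_report,
                                                      reference_scores):
        assert small_report.secondary_cutoff == pytest.approx(
            np.percentile(reference_scores, 92.5)
        )

    def test_precondition_on_sample_size(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            half_sample_stability(df, k=10, primary_cutoff=1.2, n_reps=2, seed=0)


class TestRecoveryMetrics:
    def test_perfect_flagging(self):
        labels = pd.Series(["atypical", "typical", "atypical"],
                           index=["a", "b", "c"])
        m = recovery_metrics(["a", "c"], labels)
        assert m.precision == 1.0 and m.recall == 1.0 and m.f1 == 1.0

    def test_empty_flag_set_convention(self):
        labels = pd.Series(["atypical", "typical"], index=["a", "b"])
        m = recovery_metrics([], labels)
        assert m.precision == 0.0 and m.recall == 0.0

    def test_confusion_counts_consistent(self):
        labels = pd.Series(["atypical"] * 3 + ["typical"] * 7,
                           index=[f"s{i}" for i in range(10)])
        m = recovery_metrics(["s0", "s1", "s5"], labels)
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 1, 6)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)

    def test_unknown_subject_errors(self):
        labels = pd.Series(["typical"], index=["a"])
        with pytest.raises(KeyError):
            recovery_metrics(["zz"], labels)


def test_recall_nondecreasing_in_effect_size():
    """Stronger atypical shifts are easier to recover on matched seeds."""
    recalls = []
    for effect in (1.0, 2.0, 3.0):
        cohort = generate_cohort(
            CohortSpec(n_subjects=800, seed=19, effect_size_sd=effect)
        )
        X = cohort.features.drop(columns=["sex"])
        dec = flag_at_percentile(score_features(X, K).as_series(), 95)
        recalls.append(recovery_metrics(dec.flagged_ids, cohort.labels).recall)
    assert recalls == sorted(recalls)
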