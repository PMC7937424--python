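import numpy as np
import pandas as pd
import pytest

import _oracles
from adrenomics import (
    CohortSpec,
    DegenerateError,
    GroupSummary,
    SchemaError,
    chi_square_2x2,
    generate_cohort_table,
    roc_with_youden,
    select_features,
    t_from_summary,
    two_sample_t,
)
from adrenomics.cohort_stats import feature_roc_table
from adrenomics.texture import FEATURE_NAMES


class TestTTests:
    def test_identical_samples_give_null_result(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_pooled_variance_degenerate(self):
        with pytest.raises(DegenerateError):
            two_sample_t([5.0, 5.0], [5.0, 5.0])

    def test_summary_matches_raw(self, rng):
        """t_from_summary is algebraically identical to the raw-sample test."""
        for _ in range(20):
            x = rng.normal(3, 2, size=rng.integers(3, 20))
            y = rng.normal(1, 1, size=rng.integers(3, 20))
            raw = two_sample_t(x, y)
            summ = t_from_summary(
                GroupSummary(x.mean(), x.std(ddof=1), x.size),
                GroupSummary(y.mean(), y.std(ddof=1), y.size),
            )
            assert summ.t == pytest.approx(raw.t, abs=1e-12)
            assert summ.p == pytest.approx(raw.p, abs=1e-12)
            assert summ.df == raw.df

    def test_equal_means_zero_t(self):
        res = t_from_summary(GroupSummary(5.0, 1.0, 10), GroupSummary(5.0, 2.0, 8))
        assert res.t == pytest.approx(0.0)

    def test_welch_flag(self):
        a, b = GroupSummary(10.0, 1.0, 10), GroupSummary(8.0, 5.0, 10)
        assert t_from_summary(a, b, pooled=False).df < a.n + b.n - 2

    @pytest.mark.parametrize(
        "a,b,printed",
        [
            ((33.4, 4.7, 10), (20.2, 9.2, 9), 0.001),  # mean densitometry, ACC vs adenoma
            ((62.3, 35.2, 10), (25.9, 1.4, 11), 0.003),  # diameter, ACC vs AI
            ((56.6, 42.4, 9), (25.9, 1.4, 11), 0.027),  # diameter, adenoma vs AI
        ],
    )
    def test_reference_summaries_reproduce_printed_p(self, a, b, printed):
        res = t_from_summary(GroupSummary(*a), GroupSummary(*b))
        assert round(res.p, 3) == printed


class TestChiSquare:
    def test_balanced_table_null(self):
        stat, p = chi_square_2x2([[5, 5], [5, 5]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        stat, p = chi_square_2x2([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert p < 0.001

    def test_transpose_invariance(self, rng):
        t = rng.integers(1, 30, size=(2, 2))
        assert chi_square_2x2(t)[0] == pytest.approx(chi_square_2x2(t.T)[0])

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestSelectFeatures:
    def test_alpha_zero_selects_nothing(self):
        t = generate_cohort_table(CohortSpec(seed=0, clinical=False, phases=("unenhanced",)))
        assert select_features(t, alpha=0.0).empty

    def test_missing_columns_schema_error(self):
        bad = pd.DataFrame({"group": ["ACC", "AI"], "phase": ["unenhanced"] * 2})
        with pytest.raises(SchemaError):
            select_features(bad, alpha=0.05)

    def test_strongly_shifted_feature_detected(self):
        """A 3-pooled-SD shift on one feature should be picked up essentially always."""
        hits = 0
        for seed in range(20):
            t = generate_cohort_table(
                CohortSpec(separation=0.0, seed=seed, clinical=False, phases=("unenhanced",))
            )
            sd = t[FEATURE_NAMES[0]].std()
            t.loc[t["group"] == "ACC", FEATURE_NAMES[0]] += 3 * sd
            sel = select_features(t, alpha=0.05)
            hits += FEATURE_NAMES[0] in set(sel["feature"])
        assert hits >= 19

    def test_pairwise_mode_is_stricter(self):
        t = generate_cohort_table(CohortSpec(separation=3.0, seed=1, clinical=False, phases=("unenhanced",)))
        pooled = select_features(t, alpha=0.05, comparator="pooled")
        pairwise = select_features(t, alpha=0.05, comparator="pairwise")
        assert set(map(tuple, pairwise[["feature", "phase"]].values)) <= set(
            map(tuple, pooled[["feature", "phase"]].values)
        )


class TestRoc:
    def test_perfect_separation_midpoint_cutoff(self):
        roc = roc_with_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_cutoff == pytest.approx(6.5)
        assert roc.youden_sensitivity == 1.0
        assert roc.youden_specificity == 1.0

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_with_youden(scores, labels)
            assert roc.auc == pytest.approx(_oracles.brute_auc(scores, labels), abs=1e-12)

    def test_orientation_gives_auc_at_least_half(self, rng):
        scores = rng.normal(size=40)
        labels = scores < -0.2  # positives have LOW scores
        roc = roc_with_youden(scores, labels)
        assert roc.auc >= 0.5
        assert roc.positive_direction == "<"

    def test_curve_is_monotone_step_function(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        roc = roc_with_youden(scores, labels)
        fpr = (1 - roc.specificity)[::-1]
        tpr = roc.sensitivity[::-1]
        assert np.all(np.diff(fpr) >= -1e-12)
        assert np.all(np.diff(tpr) >= -1e-12)

    def test_youden_cutoff_maximizes_j(self, rng):
        scores = rng.normal(size=25)
        labels = scores + rng.normal(scale=0.8, size=25) > 0
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        roc = roc_with_youden(scores, labels)
        j = roc.sensitivity + roc.specificity - 1
        pos = scores[labels]
        neg = scores[~labels]
        if roc.positive_direction == ">":
            sens = (pos > roc.youden_cutoff).mean()
            spec = (neg <= roc.youden_cutoff).mean()
        else:
            sens = (pos < roc.youden_cutoff).mean()
            spec = (neg >= roc.youden_cutoff).mean()
        assert sens + spec - 1 == pytest.approx(j.max())

    def test_single_class_degenerate(self):
        with pytest.raises(DegenerateError):
            roc_with_youden([1, 2, 3], [1, 1, 1])

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        a = roc_with_youden(scores, labels).auc
        b = roc_with_youden(np.exp(scores), labels).auc
        assert a == pytest.approx(b)


class TestFeatureRocTable:
    def test_one_row_per_phase_and_feature(self):
        t = generate_cohort_table(CohortSpec(seed=2, clinical=False))
        out = feature_roc_table(t)
        assert len(out) == 3 * len(FEATURE_NAMES)
        assert set(out.columns) >= {"phase", "feature", "t", "p", "auc", "youden_cutoff", "selected"}
        assert ((out["auc"] >= 0.5) & (out["auc"] <= 1.0)).all()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
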