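import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from drrforge.core import DataError, DegenerateLabelsError
from drrforge.evaluation import (
    DegenerateVarianceError,
    auc_mann_whitney,
    conspicuity_scorer,
    delong_test,
    delong_variance,
    evaluate_cohort,
    get_scorer,
    make_null_scorer,
    paired_t_test,
    roi_mean_scorer,
)
from drrforge.phantom import generate_cohort


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAucMannWhitney:
    def test_perfect_separation(self):
        r = auc_mann_whitney([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        assert auc_mann_whitney([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_worked_pair_example(self):
        # pos {0.9, 0.8}, neg {0.85, 0.7}: 3 of 4 pairs concordant
        r = auc_mann_whitney([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc_mann_whitney([0.1, 0.2], [1, 1])

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 1)  # coarse values force ties
            r = auc_mann_whitney(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_roc_curve_consistency(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.normal(size=40)
        r = auc_mann_whitney(scores, labels)
        assert r.fpr[0] == 0.0 and r.tpr[0] == 0.0
        assert r.fpr[-1] == 1.0 and r.tpr[-1] == 1.0
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-12)

    @given(
        st.lists(st.integers(-500, 500), min_size=6, max_size=30),
        st.floats(0.1, 3.0),
        st.floats(-2, 2),
    )
    def test_invariant_under_increasing_transform(self, raw, a, b):
        # coarse score grid keeps exp() strictly increasing in float arithmetic
        scores = np.asarray(raw, dtype=float) / 100.0
        labels = [i % 2 for i in range(len(scores))]
        base = auc_mann_whitney(scores, labels).auc
        transformed = auc_mann_whitney(np.exp(a * scores) + b, labels).auc
        assert transformed == pytest.approx(base, abs=1e-12)


class TestDeLong:
    LABELS = np.array([0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
    A = np.array([0.1, 0.2, 0.35, 0.4, 0.5, 0.15, 0.3, 0.45, 0.6, 0.55, 0.25, 0.7])
    B = np.array([0.2, 0.1, 0.30, 0.5, 0.4, 0.25, 0.2, 0.35, 0.5, 0.65, 0.45, 0.6])

    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        r = delong_test(scores, scores, labels)
        assert r.z == 0.0 and r.p == 1.0

    def test_matches_proc_reference(self):
        """Frozen oracle values from an independent statistical implementation."""
        r = delong_test(self.A, self.B, self.LABELS)
        assert r.auc1 == pytest.approx(0.857142857143, abs=1e-10)
        assert r.auc2 == pytest.approx(0.900000000000, abs=1e-10)
        assert r.z == pytest.approx(-0.353553390593, abs=1e-9)
        assert r.p == pytest.approx(0.723673609832, abs=1e-9)
        assert delong_variance(self.A, self.LABELS) == pytest.approx(0.015510204082, abs=1e-10)

    def test_antisymmetric_in_arguments(self):
        fwd = delong_test(self.A, self.B, self.LABELS)
        rev = delong_test(self.B, self.A, self.LABELS)
        assert rev.z == pytest.approx(-fwd.z, abs=1e-12)
        assert rev.p == pytest.approx(fwd.p, abs=1e-12)

    def test_internal_auc_matches_mann_whitney(self):
        r = delong_test(self.A, self.B, self.LABELS)
        assert r.auc1 == pytest.approx(auc_mann_whitney(self.A, self.LABELS).auc, abs=1e-15)
        assert r.auc2 == pytest.approx(auc_mann_whitney(self.B, self.LABELS).auc, abs=1e-15)

    def test_degenerate_variance_with_distinct_aucs(self):
        with pytest.raises(DegenerateVarianceError):
            delong_test([0.0, 1.0], [1.0, 0.0], [0, 1])

    def test_variance_close_to_bootstrap(self, rng):
        """DeLong single-AUC variance tracks a bootstrap estimate (n=30)."""
        from scipy.stats import rankdata

        n = 30
        labels = np.array([1] * 15 + [0] * 15)
        scores = np.where(labels == 1, rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n))
        v_delong = delong_variance(scores, labels)

        reps = 20000
        idx = rng.integers(0, n, size=(reps, n))
        s = scores[idx]
        l = labels[idx]
        m = l.sum(axis=1)
        keep = (m > 0) & (m < n)
        ranks = rankdata(s[keep], axis=1)
        m = m[keep]
        aucs = ((ranks * l[keep]).sum(axis=1) - m * (m + 1) / 2) / (m * (n - m))
        v_boot = aucs.var(ddof=1)
        assert v_delong == pytest.approx(v_boot, rel=0.25)


class TestPairedT:
    def test_identical_vectors_null(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_zero_mean_difference(self):
        r = paired_t_test([1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_closed_form_example(self):
        # d = (1, 2, 3): mean 2, sd 1, t = 2*sqrt(3), df = 2
        r = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert r.df == 2
        assert r.p == pytest.approx(0.0742, abs=5e-4)

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_rel

        x, y = rng.normal(size=(2, 12))
        ours = paired_t_test(x, y)
        ref = ttest_rel(x, y)
        assert ours.t == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_nonzero_difference_flags_zero_p(self):
        r = paired_t_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert r.p == 0.0 and np.isinf(r.t)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            paired_t_test([1.0], [2.0])


class TestEvaluateCohort:
    def test_degenerate_prevalence_surfaces_label_error(self):
        cases = generate_cohort(6, 0.0, seed=1, shape=(24, 24, 24))
        with pytest.raises(DegenerateLabelsError):
            evaluate_cohort(cases, techniques=("mean",), seed=1)

    def test_null_scorer_auc_near_chance(self):
        cases = generate_cohort(200, 0.5, seed=11, shape=(24, 24, 24))
        report = evaluate_cohort(
            cases,
            techniques=("beer_lambert", "softmip", "wedge", "point_source"),
            scorer=make_null_scorer(seed=11),
            seed=11,
        )
        for t in report.techniques:
            assert 0.4 < report.auc(t) < 0.6

    def test_nan_scorer_excludes_case(self, caplog):
        cases = generate_cohort(6, 0.5, seed=2, shape=(24, 24, 24))
        calls = {"n": 0}

        def flaky(img):
            calls["n"] += 1
            return float("nan") if calls["n"] == 1 else float(np.mean(img))

        report = evaluate_cohort(cases, techniques=("mean",), scorer=flaky, seed=2)
        assert len(report.case_ids) == 5

    def test_report_round_trip(self, tmp_path):
        cases = generate_cohort(10, 0.5, seed=3, shape=(24, 24, 24))
        report = evaluate_cohort(cases, techniques=("mean", "mip"), seed=3)
        report.to_json(tmp_path / "report.json")
        report.to_csv(tmp_path / "report.csv")
        import json

        payload = json.loads((tmp_path / "report.json").read_text())
        assert set(payload["techniques"]) == {"mean", "mip"}
        assert any(d["technique_a"] == d["technique_b"] and d["p"] == 1.0 for d in payload["delong"])
        frame = report.scores_frame()
        assert list(frame.columns) == ["case_id", "label", "mean", "mip"]


class TestScorers:
    def test_get_scorer_names(self):
        assert get_scorer("conspicuity") is conspicuity_scorer
        assert get_scorer("roi-mean") is roi_mean_scorer
        with pytest.raises(DataError):
            get_scorer("cnn")

    def test_null_scorer_is_seeded(self):
        a, b = make_null_scorer(1), make_null_scorer(1)
        img = np.zeros((8, 8))
        assert [a(img) for _ in range(3)] == [b(img) for _ in range(3)]

    def test_conspicuity_responds_to_unilateral_blob(self):
        img = np.full((224, 224), 0.4)
        base = conspicuity_scorer(img)
        img2 = img.copy()
        img2[108:118, 58:68] += 0.1  # blob inside the left lung field
        assert conspicuity_scorer(img2) > base + 0.05
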