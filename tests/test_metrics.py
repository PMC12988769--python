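"""QWK, counting metrics, ROC/PR, and the patient-level bootstrap."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score, mean_absolute_error

from klgrade.metrics import (
    basic_metrics,
    bootstrap_ci,
    confusion_matrix,
    evaluate_predictions,
    qwk,
    roc_pr_curves,
)


def qwk_oracle(y_true, y_pred, n=5):
    """Brute-force QWK via explicit O and E matrices, elementwise loops."""
    O = np.zeros((n, n))
    for t, p in zip(y_true, y_pred):
        O[t, p] += 1
    total = O.sum()
    row, col = O.sum(axis=1), O.sum(axis=0)
    E = np.outer(row, col) / total
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            w = (i - j) ** 2 / (n - 1) ** 2
            num += w * O[i, j]
            den += w * E[i, j]
    return 1.0 - num / den


class TestQwk:
    def test_perfect_agreement(self, rng):
        y = rng.integers(0, 5, size=50)
        assert qwk(y, y) == 1.0

    def test_reversed_grades_match_hand_formula(self):
        y_true = np.array([0, 1, 2, 3, 4])
        y_pred = np.array([4, 3, 2, 1, 0])
        assert abs(qwk(y_true, y_pred) - qwk_oracle(y_true, y_pred)) < 1e-12

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            t = rng.integers(0, 5, size=n)
            p = rng.integers(0, 5, size=n)
            if len(np.unique(t)) < 2 and len(np.unique(p)) < 2:
                continue
            assert abs(qwk(t, p) - qwk_oracle(t, p)) < 1e-12

    def test_matches_sklearn_quadratic_kappa(self, rng):
        t = rng.integers(0, 5, size=200)
        p = rng.integers(0, 5, size=200)
        ours = qwk(t, p)
        theirs = cohen_kappa_score(t, p, weights="quadratic", labels=range(5))
        assert abs(ours - theirs) < 1e-10

    def test_permutation_null_near_zero(self, rng):
        t = rng.integers(0, 5, size=10_000)
        p = rng.permutation(t)
        assert abs(qwk(t, p)) < 0.05

    def test_relabeling_invariance(self, rng):
        t = rng.integers(0, 5, size=100)
        p = rng.integers(0, 5, size=100)
        assert abs(qwk(t, p) - qwk(4 - t, 4 - p)) < 1e-12

    def test_degenerate_diagonal_returns_one(self):
        assert qwk([2, 2, 2], [2, 2, 2]) == 1.0

    def test_constant_disagreement_scores_zero(self):
        # marginals degenerate on different classes: observed weighted
        # disagreement equals the chance-expected one
        assert qwk([2, 2], [3, 3]) == 0.0


class TestBasicMetrics:
    def test_perfect_predictions(self, rng):
        y = rng.integers(0, 5, size=40)
        m = basic_metrics(y, y)
        assert m["accuracy"] == 1.0 and m["mae"] == 0.0 and m["macro_f1"] == 1.0

    def test_all_off_by_one(self):
        y = np.array([0, 1, 2, 3])
        m = basic_metrics(y, y + 1)
        assert m["accuracy"] == 0.0 and m["mae"] == 1.0

    def test_three_class_fixture_matches_hand_counts(self):
        # confusion: true 0 -> (2 as 0, 1 as 1); true 1 -> (1 as 1);
        # true 2 -> (1 as 1, 2 as 2)
        t = [0, 0, 0, 1, 2, 2, 2]
        p = [0, 0, 1, 1, 1, 2, 2]
        m = basic_metrics(t, p, n_classes=3)
        per = m["per_class"].set_index("grade")
        assert per.loc[0, "precision"] == 1.0 and abs(per.loc[0, "recall"] - 2 / 3) < 1e-12
        assert abs(per.loc[1, "precision"] - 1 / 3) < 1e-12 and per.loc[1, "recall"] == 1.0
        assert per.loc[2, "precision"] == 1.0 and abs(per.loc[2, "recall"] - 2 / 3) < 1e-12
        f0 = 2 * (1.0 * 2 / 3) / (1.0 + 2 / 3)
        f1 = 2 * (1 / 3 * 1.0) / (1 / 3 + 1.0)
        f2 = f0
        assert abs(m["macro_f1"] - np.mean([f0, f1, f2])) < 1e-12

    def test_agrees_with_sklearn(self, rng):
        t = rng.integers(0, 5, size=300)
        p = rng.integers(0, 5, size=300)
        m = basic_metrics(t, p)
        assert abs(m["macro_f1"] - f1_score(t, p, average="macro")) < 1e-12
        assert abs(m["mae"] - mean_absolute_error(t, p)) < 1e-12

    def test_absent_class_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            m = basic_metrics([0, 1, 1], [0, 1, 0], n_classes=5)
        assert 0.0 < m["macro_f1"] <= 1.0


class TestRocPr:
    def test_perfect_separation_auc_one(self):
        labels = np.array([0] * 20 + [1] * 20)
        scores = np.concatenate([np.linspace(0, 0.4, 20), np.linspace(0.6, 1, 20)])
        out = roc_pr_curves(scores, labels, "binary")
        assert out["roc_auc"] == 1.0

    def test_uninformative_scores_auc_half(self, rng):
        labels = rng.integers(0, 2, size=10_000)
        scores = rng.uniform(size=10_000)
        out = roc_pr_curves(scores, labels, "binary")
        assert abs(out["roc_auc"] - 0.5) < 0.03

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=500)
        scores = rng.uniform(size=500)
        a = roc_pr_curves(scores, labels, "binary")["roc_auc"]
        b = roc_pr_curves(np.exp(3 * scores), labels, "binary")["roc_auc"]
        assert abs(a - b) < 1e-12

    def test_ovr_macro_excludes_empty_class(self, rng):
        y = rng.integers(0, 3, size=100)  # classes 3, 4 never occur
        scores = rng.dirichlet(np.ones(5), size=100)
        with pytest.warns(UserWarning, match="excluded"):
            out = roc_pr_curves(scores, y, "ovr")
        assert set(out["per_class"]) == {0, 1, 2}
        assert np.isfinite(out["macro_auc"])


def prediction_table(rng, n_patients=30, bilateral=True, perfect=False):
    rows = []
    for i in range(n_patients):
        n_img = 2 if bilateral else 1
        for j in range(n_img):
            t = int(rng.integers(0, 5))
            p = t if perfect else int(np.clip(t + rng.integers(-1, 2), 0, 4))
            rows.append(dict(patient_id=f"p{i}", true_grade=t, pred_grade=p))
    return pd.DataFrame(rows)


class TestBootstrap:
    def test_deterministic_under_seed(self, rng):
        table = prediction_table(rng)
        a = bootstrap_ci(table, lambda t, p: float(np.mean(t == p)), B=200, seed=9)
        b = bootstrap_ci(table, lambda t, p: float(np.mean(t == p)), B=200, seed=9)
        assert a == b

    def test_identical_contributions_zero_width(self, rng):
        table = prediction_table(rng, perfect=True)
        lo, hi = bootstrap_ci(table, lambda t, p: float(np.mean(t == p)), B=100,
                              seed=0)
        assert lo == hi == 1.0

    def test_patient_retention_rule(self, rng):
        """Every resample carries 2x the resampled patient count of images."""
        table = prediction_table(rng, n_patients=20, bilateral=True)
        sizes = []

        def spy(t, p):
            sizes.append(len(t))
            return 0.0

        bootstrap_ci(table, spy, B=50, seed=3)
        assert all(s == 40 for s in sizes)

    def test_single_patient_degenerate(self, rng):
        table = prediction_table(rng, n_patients=1)
        with pytest.warns(UserWarning, match="single patient"):
            lo, hi = bootstrap_ci(table, lambda t, p: float(np.mean(t == p)), B=10,
                                  seed=0)
        assert lo == hi

    def test_width_shrinks_with_patient_count(self, rng):
        widths = []
        for n in (50, 200, 800):
            table = prediction_table(rng, n_patients=n)
            lo, hi = bootstrap_ci(table, lambda t, p: float(np.mean(t == p)),
                                  B=300, seed=1)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        # rough 1/sqrt(n) scaling: 16x patients -> about 4x narrower
        assert widths[0] / widths[2] > 2.0


class TestEvaluatePredictions:
    def test_full_report_fields(self, rng):
        table = prediction_table(rng, n_patients=40)
        probs = rng.dirichlet(np.ones(5), size=len(table))
        for c in range(5):
            table[f"p{c}"] = probs[:, c]
        table["p_ge2"] = probs[:, 2:].sum(axis=1)
        report = evaluate_predictions(table, B=100, seed=2)
        d = report.to_dict()
        assert -1 <= d["qwk"] <= 1 and 0 <= d["accuracy"] <= 1
        assert set(d["ci"]) == {"qwk", "accuracy", "macro_f1", "mae"}
        assert 0 <= d["kl_ge2_roc_auc"] <= 1
        assert len(d["confusion"]) == 5
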