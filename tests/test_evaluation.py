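"""ROC/AUC against brute-force oracles; Youden cutoffs; metrics; bootstrap."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specdx.evaluation import (
    auc,
    bootstrap_ci,
    diagnostic_metrics,
    roc_curve,
    youden_cutoffs,
    youden_index,
)

# --- independent oracles ----------------------------------------------------


def mann_whitney_auc(scores, labels) -> float:
    """Pairwise comparison statistic with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def roc_points_by_enumeration(scores, labels) -> set[tuple[float, float]]:
    """(FPR, TPR) at every cutoff 'call positive iff score >= t', plus (0,0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    points = {(0.0, 0.0)}
    for t in np.unique(scores):
        calls = scores >= t
        tpr = (calls & (labels == 1)).sum() / n_pos
        fpr = (calls & (labels == 0)).sum() / n_neg
        points.add((round(fpr, 12), round(tpr, 12)))
    return points


def _random_instance(rng, n, tie_prone=False):
    labels = np.zeros(n, dtype=int)
    labels[: n // 2 or 1] = 1
    rng.shuffle(labels)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    if tie_prone:
        scores = rng.integers(0, 4, size=n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, labels


# --- ROC / AUC ---------------------------------------------------------------


class TestROC:
    def test_perfect_separation_passes_through_top_left(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc(curve) == 1.0
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))

    def test_constant_scores_give_diagonal(self):
        curve = roc_curve([0.5] * 10, [1, 0] * 5)
        assert auc(curve) == pytest.approx(0.5)

    def test_endpoints(self):
        curve = roc_curve(np.random.default_rng(0).normal(size=20), [0, 1] * 10)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("n,tie_prone", [(20, False), (20, True), (15, True)])
    def test_curve_matches_all_cutoffs_enumeration(self, n, tie_prone):
        rng = np.random.default_rng(n + tie_prone)
        scores, labels = _random_instance(rng, n, tie_prone)
        curve = roc_curve(scores, labels)
        got = {(round(f, 12), round(t, 12)) for f, t in zip(curve.fpr, curve.tpr)}
        assert got == roc_points_by_enumeration(scores, labels)

    def test_auc_equals_mann_whitney_exhaustively(self):
        """All label patterns at n=8 with tie-prone integer scores."""
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 3, size=8).astype(float)
        for bits in itertools.product([0, 1], repeat=8):
            if sum(bits) in (0, 8):
                continue
            labels = np.array(bits)
            assert auc(roc_curve(scores, labels)) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mann_whitney_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng, 30, tie_prone=bool(seed % 2))
        assert auc(roc_curve(scores, labels)) == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12
        )


class TestYouden:
    def test_published_cutoff_arithmetic(self):
        assert youden_index(0.937, 0.981) == pytest.approx(0.918, abs=1e-12)
        assert youden_index(0.921, 0.981) == pytest.approx(0.902, abs=1e-12)

    def test_diagonal_curve_has_zero_max_j(self):
        curve = roc_curve([0.5] * 10, [1, 0] * 5)
        table = youden_cutoffs(curve)
        assert table["youden_j"].max() == pytest.approx(0.0)

    def test_table_sorted_by_j_descending(self):
        rng = np.random.default_rng(2)
        scores, labels = _random_instance(rng, 40)
        table = youden_cutoffs(roc_curve(scores, labels))
        assert (table["youden_j"].diff().dropna() <= 1e-12).all()
        best = table.iloc[0]
        assert best["youden_j"] == pytest.approx(
            (table["sensitivity"] + table["specificity"] - 1).max()
        )

    @given(st.integers(0, 2**31 - 1))
    def test_j_invariant_under_monotone_score_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng, 25, tie_prone=True)
        j1 = youden_cutoffs(roc_curve(scores, labels))["youden_j"].max()
        j2 = youden_cutoffs(roc_curve(np.exp(2.0 * scores), labels))["youden_j"].max()
        assert j1 == pytest.approx(j2, abs=1e-12)


# --- diagnostic metrics ------------------------------------------------------


class TestDiagnosticMetrics:
    def test_validation_confusion_matrix_reproduces_published_metrics(self):
        calls = [1] * 17 + [0] * 2 + [0] * 21
        labels = [1] * 17 + [1] * 2 + [0] * 21
        m = diagnostic_metrics(calls, labels)
        assert (m.tp, m.fp, m.fn, m.tn) == (17, 0, 2, 21)
        pct = m.as_percentages()
        assert pct["accuracy"] == 95.00
        assert pct["ppv"] == 100.00
        assert pct["npv"] == 91.30

    def test_27_of_40_accuracy(self):
        calls = [1] * 27 + [0] * 13
        labels = [1] * 40
        m = diagnostic_metrics(calls, labels)
        assert m.as_percentages()["accuracy"] == 67.50

    def test_all_correct(self):
        m = diagnostic_metrics([1, 0, 1], [1, 0, 1])
        assert m.accuracy == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_undefined_ppv_flagged_not_nan(self):
        m = diagnostic_metrics([0, 0], [1, 0])
        assert m.ppv is None
        assert "ppv" in m.undefined

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics([], [])

    def test_binary_label_strings_accepted(self):
        m = diagnostic_metrics(["IAC", "NON_IAC"], ["IAC", "IAC"])
        assert (m.tp, m.fn) == (1, 1)

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    def test_accuracy_is_prevalence_weighted_sens_spec(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        calls = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        labels = [1] * (tp + fn) + [0] * (fp + tn)
        m = diagnostic_metrics(calls, labels)
        prev = (tp + fn) / m.n
        assert m.accuracy == pytest.approx(
            prev * m.sensitivity + (1 - prev) * m.specificity
        )


# --- bootstrap ---------------------------------------------------------------


class TestBootstrap:
    def test_constant_statistic_gives_zero_width_interval(self):
        lo, hi, redrawn = bootstrap_ci(lambda idx: 0.7, n_units=20, b=200, seed=1)
        assert (lo, hi) == (0.7, 0.7)
        assert redrawn == 0

    def test_proportion_interval_stays_in_unit_range(self):
        rng = np.random.default_rng(4)
        outcomes = rng.integers(0, 2, size=25)

        def stat(idx):
            return float(outcomes[idx].mean())

        lo, hi, _ = bootstrap_ci(stat, n_units=25, b=500, seed=2)
        assert 0.0 <= lo <= hi <= 1.0

    def test_seeded_determinism_and_seed_stability(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=20)
        labels = np.array([1, 0] * 10)

        def stat(idx):
            if len(set(labels[idx])) < 2:
                return None
            return auc(roc_curve(scores[idx], labels[idx]))

        a = bootstrap_ci(stat, n_units=20, b=1000, seed=3)
        b = bootstrap_ci(stat, n_units=20, b=1000, seed=3)
        assert a == b
        c = bootstrap_ci(stat, n_units=20, b=1000, seed=4)
        # different seeds: overlapping intervals of comparable width
        assert max(a[0], c[0]) <= min(a[1], c[1])
        wa, wc = a[1] - a[0], c[1] - c[0]
        assert abs(wa - wc) <= 0.2 * max(wa, wc)

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda idx: 0.0, n_units=5, b=50)
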