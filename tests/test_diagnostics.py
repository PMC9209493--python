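"""ROC/AUC, the diagnostic metric panel with NA conventions, ICC and
Bland-Altman."""

import math

import numpy as np
import pytest

from apvpipe.diagnostics import (
    ConfusionCounts,
    LabelError,
    balanced_auc,
    bland_altman,
    confusion_at_threshold,
    diagnostic_report,
    evaluate_scores,
    icc_oneway,
    roc_curve,
    youden_threshold,
)

from oracles import oracle_auc


class TestROC:
    def test_perfect_separation_auc_one(self):
        curve = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_all_tied_scores_auc_half(self):
        curve = roc_curve([5.0] * 8, [0, 1, 0, 1, 0, 1, 0, 1])
        assert curve.auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 5, size=10).astype(float)
            labels = rng.integers(0, 2, size=10)
            if labels.sum() in (0, 10):
                continue
            curve = roc_curve(scores, labels)
            assert curve.auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, size=20)
        labels[0], labels[1] = 0, 1
        a = roc_curve(scores, labels).auc
        b = roc_curve(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(LabelError):
            roc_curve([1.0, 2.0], [1, 1])

    def test_curve_monotone_along_sweep(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        curve = roc_curve(scores, labels)
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert (np.diff(curve.fpr) >= 0).all()


class TestConfusion:
    def test_threshold_below_min_no_negative_calls(self):
        c = confusion_at_threshold([1.0, 2.0, 3.0], [0, 1, 1], -10.0)
        assert c.fn == 0 and c.tn == 0

    def test_threshold_above_max_no_positive_calls(self):
        c = confusion_at_threshold([1.0, 2.0, 3.0], [0, 1, 1], 10.0)
        assert c.tp == 0 and c.fp == 0

    def test_hand_counted_fixture_with_tie_positive(self):
        scores = [0.1, 0.4, 0.4, 0.9, 0.2]
        labels = [0, 0, 1, 1, 1]
        c = confusion_at_threshold(scores, labels, 0.4)  # ties call positive
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)


class TestDiagnosticReport:
    def test_external_cohort_implied_counts_panel(self):
        # 53 controls + 11 patients at sens 5/11, spec 47/53
        rep = diagnostic_report(ConfusionCounts(tp=5, fp=6, tn=47, fn=6))
        assert rep.accuracy == pytest.approx(0.8125, abs=1e-4)
        assert rep.npv == pytest.approx(0.8868, abs=1e-4)
        assert rep.lr_pos == pytest.approx(4.0151, abs=1e-3)
        assert rep.lr_neg == pytest.approx(0.6151, abs=1e-4)
        assert rep.youden == pytest.approx(0.3413, abs=1e-4)
        assert rep.dor == pytest.approx(6.5278, abs=1e-4)

    def test_zero_division_yields_na_flag_not_exception(self):
        rep = diagnostic_report(ConfusionCounts(tp=5, fp=0, tn=10, fn=1))
        assert "lr_pos" in rep.na_flags
        assert math.isnan(rep.lr_pos)
        assert rep.to_series()["LR+"] == "NA"

    def test_perfect_classifier(self):
        rep = diagnostic_report(ConfusionCounts(tp=7, fp=0, tn=9, fn=0))
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.youden == pytest.approx(1.0)
        assert rep.accuracy == 1.0

    def test_dor_equals_lr_ratio_when_defined(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            rep = diagnostic_report(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert rep.dor == pytest.approx(rep.lr_pos / rep.lr_neg, rel=1e-12)

    def test_label_swap_exchanges_sens_spec_and_ppv_npv(self):
        a = diagnostic_report(ConfusionCounts(tp=8, fp=3, tn=20, fn=5))
        b = diagnostic_report(ConfusionCounts(tp=20, fp=5, tn=8, fn=3))
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)
        assert a.ppv == pytest.approx(b.npv)
        assert a.npv == pytest.approx(b.ppv)


class TestBalancedAUC:
    def test_hold_out_convention_values(self):
        assert balanced_auc(0.9741, 0.9831) == pytest.approx(0.9786)
        assert balanced_auc(1.0, 1.0) == 1.0
        assert balanced_auc(0.4545, 0.8868) == pytest.approx(0.67065)

    def test_equals_one_threshold_trapezoid_auc(self, rng):
        sens, spec = 0.7, 0.9
        # one operating point (1-spec, sens): trapezoid over (0,0) -> point -> (1,1)
        fpr = [0.0, 1 - spec, 1.0]
        tpr = [0.0, sens, 1.0]
        assert balanced_auc(sens, spec) == pytest.approx(np.trapezoid(tpr, fpr))


class TestYouden:
    def test_separable_scores_pick_smallest_maximizer(self):
        curve = roc_curve([1.0, 2.0, 8.0, 9.0], [0, 0, 1, 1])
        # J = 1 at thresholds 8 (and any gap value); smallest wins
        assert youden_threshold(curve) == pytest.approx(8.0)

    def test_matches_exhaustive_sweep_oracle(self, rng):
        scores = rng.normal(size=10)
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        curve = roc_curve(scores, labels)
        best_j, best_t = -2.0, None
        for t in sorted(np.unique(scores))[::-1]:
            pos = scores >= t
            sens = (pos & (labels == 1)).sum() / labels.sum()
            spec = (~pos & (labels == 0)).sum() / (labels == 0).sum()
            j = sens + spec - 1
            if j > best_j - 1e-12:
                if j > best_j + 1e-12 or (best_t is not None and t < best_t):
                    best_j, best_t = max(j, best_j), t
        assert youden_threshold(curve) == pytest.approx(best_t)


class TestICC:
    def test_duplicated_measurements_icc_one(self, rng):
        x = rng.normal(size=10)
        res = icc_oneway(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)

    def test_small_table_matches_hand_anova(self):
        x = np.array([[1.0, 2.0], [3.0, 3.0], [5.0, 4.0], [7.0, 9.0]])
        n, k = x.shape
        grand = x.mean()
        msb = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msw = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        res = icc_oneway(x)
        assert res.icc == pytest.approx(expected, abs=1e-12)
        assert res.msb == pytest.approx(msb)
        assert res.msw == pytest.approx(msw)

    def test_independent_noise_icc_near_zero(self, rng):
        x = rng.normal(size=(500, 2))
        assert icc_oneway(x).icc == pytest.approx(0.0, abs=0.1)

    def test_matches_pingouin_reference(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2.0
        res = icc_oneway(x)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert res.icc == pytest.approx(icc1, abs=1e-6)

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            icc_oneway(x)


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0
        assert res.lower == res.upper == 0.0

    def test_constant_offset(self):
        res = bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(1.0)
        assert res.upper - res.lower == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        a = rng.normal(size=30)
        b = a + rng.normal(0.2, 0.1, size=30)
        res = bland_altman(a, b)
        d = a - b
        assert res.bias == pytest.approx(d.mean())
        assert res.upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert res.lower <= res.bias <= res.upper


def test_evaluate_scores_combines_auc_and_threshold(rng):
    scores = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
    labels = np.array([0] * 20 + [1] * 20)
    rep = evaluate_scores(scores, labels, threshold=1.0)
    assert rep.auc == pytest.approx(roc_curve(scores, labels).auc)
    assert rep.threshold == 1.0
    assert 0.0 <= rep.accuracy <= 1.0
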