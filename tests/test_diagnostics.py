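"""2x2 diagnostics: confusion tables, odds ratios, ROC, threshold choice."""

import numpy as np
import pytest
from scipy import stats

from ibioscore.diagnostics import (
    ConfusionTable,
    confusion_at_threshold,
    odds_ratio,
    reconstruct_table,
    roc_curve,
    round_half_up,
    select_threshold,
)


def rank_auc(scores, labels):
    """Independent AUC oracle: tie-corrected Mann-Whitney rank statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ranks = stats.rankdata(scores)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestConfusion:
    def test_perfect_separation(self):
        t = confusion_at_threshold([5, 3], [True, False], 4, strict=True)
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 0, 0, 1)

    def test_non_strict_boundary(self):
        t = confusion_at_threshold([9, 8], [True, False], 9, strict=False)
        assert (t.tp, t.tn) == (1, 1)
        assert (t.fn, t.fp) == (0, 0)

    def test_strict_vs_nonstrict_at_the_threshold_value(self):
        t = confusion_at_threshold([4, 4], [True, False], 4, strict=True)
        assert (t.tp, t.fp) == (0, 0)
        t = confusion_at_threshold([4, 4], [True, False], 4, strict=False)
        assert (t.tp, t.fp) == (1, 1)

    def test_matches_per_subject_loop_oracle(self, rng):
        scores = rng.integers(0, 18, size=50)
        labels = rng.random(50) < 0.6
        labels[0], labels[1] = True, False
        for threshold in range(-1, 18):
            for strict in (True, False):
                t = confusion_at_threshold(scores, labels, threshold, strict)
                tp = fn = fp = tn = 0
                for s, y in zip(scores, labels):
                    call = s > threshold if strict else s >= threshold
                    if call and y:
                        tp += 1
                    elif not call and y:
                        fn += 1
                    elif call:
                        fp += 1
                    else:
                        tn += 1
                assert (t.tp, t.fn, t.fp, t.tn) == (tp, fn, fp, tn)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            confusion_at_threshold([1, 2], [True, True], 1, True)


class TestOddsRatio:
    def test_symmetric_table_gives_unit_or(self):
        s = odds_ratio(ConfusionTable(10, 10, 10, 10))
        assert s.odds_ratio == pytest.approx(1.0)
        assert s.ci_low < 1.0 < s.ci_high
        assert s.p_value == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = odds_ratio(ConfusionTable(12, 5, 7, 20))
        b = odds_ratio(ConfusionTable(36, 15, 21, 60))
        assert a.odds_ratio == pytest.approx(b.odds_ratio)

    def test_agrees_with_statsmodels_on_integer_tables(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        for _ in range(25):
            tp, fn, fp, tn = rng.integers(1, 60, size=4)
            ours = odds_ratio(ConfusionTable(tp, fn, fp, tn))
            ref = sm.stats.Table2x2(
                np.array([[tp, fn], [fp, tn]]), shift_zeros=False
            )
            assert ours.odds_ratio == pytest.approx(ref.oddsratio)
            lo, hi = ref.oddsratio_confint(0.05)
            assert ours.ci_low == pytest.approx(lo)
            assert ours.ci_high == pytest.approx(hi)

    def test_zero_cell_gets_haldane_correction_and_flag(self):
        s = odds_ratio(ConfusionTable(10, 0, 0, 10))
        assert s.haldane_corrected
        assert np.isfinite(s.odds_ratio)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            odds_ratio(ConfusionTable(0, 0, 5, 5))

    def test_fisher_exact_available_for_small_integer_cells(self):
        s = odds_ratio(ConfusionTable(8, 2, 1, 9), p_method="fisher")
        assert s.p_value == pytest.approx(
            stats.fisher_exact([[8, 2], [1, 9]])[1]
        )


class TestReconstruction:
    def test_published_presence_operating_point(self):
        t = reconstruct_table(0.879, 0.500, 166, 39)
        assert (t.tp, t.fn, t.fp, t.tn) == pytest.approx(
            (145.914, 20.086, 19.5, 19.5)
        )
        assert t.reconstructed
        assert round_half_up(odds_ratio(t).odds_ratio) == 7.3

    def test_published_severity_operating_point_rounds_half_up(self):
        t = reconstruct_table(0.500, 0.840, 72, 144)
        s = odds_ratio(t)
        assert s.odds_ratio == pytest.approx(5.25)
        assert round_half_up(s.odds_ratio) == 5.3

    def test_initial_severity_operating_point(self):
        t = reconstruct_table(0.438, 0.798, 93, 112)
        assert round_half_up(odds_ratio(t).odds_ratio) == 3.1

    def test_perfect_test(self):
        t = reconstruct_table(1.0, 1.0, 10, 10)
        assert (t.tp, t.fn, t.fp, t.tn) == (10, 0, 0, 10)

    def test_rates_round_trip_exactly(self, rng):
        for _ in range(50):
            sens, spec = rng.random(2)
            n_pos, n_neg = rng.integers(1, 500, size=2)
            t = reconstruct_table(sens, spec, int(n_pos), int(n_neg))
            assert t.sensitivity == pytest.approx(sens, abs=1e-12)
            assert t.specificity == pytest.approx(spec, abs=1e-12)
            assert t.n_pos == n_pos and t.n_neg == n_neg


class TestROC:
    def test_perfect_separation_has_unit_auc(self):
        c = roc_curve([1, 2, 3, 10, 11], [False, False, False, True, True])
        assert c.auc == pytest.approx(1.0)

    def test_null_scores_give_half_auc(self):
        rng = np.random.default_rng(2022)
        scores = rng.integers(0, 18, size=2000)
        labels = rng.random(2000) < 0.5
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_curve_is_monotone_with_anchors(self, rng):
        scores = rng.integers(0, 18, size=80)
        labels = rng.random(80) < 0.4
        c = roc_curve(scores, labels)
        assert c.fpr[0] == 0.0 and c.tpr[0] == 0.0
        assert c.fpr[-1] == 1.0 and c.tpr[-1] == 1.0
        assert np.all(np.diff(c.fpr) >= 0)
        assert np.all(np.diff(c.tpr) >= 0)

    def test_trapezoid_auc_equals_rank_statistic(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            scores = rng.integers(0, 18, size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or (~labels).all():
                continue
            c = roc_curve(scores, labels)
            assert abs(c.auc - rank_auc(scores, labels)) < 1e-12


class TestThresholdSelection:
    def test_perfect_separation_selects_the_separating_threshold(self):
        c = roc_curve([1, 2, 3, 10, 11], [False, False, False, True, True])
        # non-strict calls: >= 10 is the lowest threshold with J = 1
        assert select_threshold(c, "youden") == 10

    def test_youden_picks_the_larger_j(self):
        scores = [0, 0, 0, 1, 1, 2, 2, 2]
        labels = [False, False, False, False, True, True, True, False]
        c = roc_curve(scores, labels)
        j = {int(t): c.tpr[i] - c.fpr[i]
             for i, t in enumerate(c.thresholds) if np.isfinite(t)}
        best = max(j.values())
        assert j[select_threshold(c, "youden")] == pytest.approx(best)

    def test_ties_break_toward_the_higher_threshold(self):
        # thresholds 1 and 2 have identical J; pick 2 (fewer positives)
        scores = [0, 1, 2, 0, 1, 2]
        labels = [False, False, True, False, False, True]
        c = roc_curve(scores, labels)
        assert select_threshold(c, "youden") == 2

    def test_constrained_selection_respects_the_floor(self):
        scores = [0, 1, 2, 3, 4, 5, 6, 7]
        labels = [False, False, False, True, False, True, True, True]
        c = roc_curve(scores, labels)
        thr = select_threshold(c, "min_sensitivity", floor=0.75)
        t = confusion_at_threshold(scores, labels, thr, strict=False)
        assert t.sensitivity >= 0.75

    def test_sensitivity_first_selection_recovers_published_threshold(self):
        """On the default-seed initial preset, requiring the published
        presence sensitivity (87.9%) and maximising specificity selects a
        threshold in the published neighbourhood {3, 4, 5}."""
        from ibioscore.ibio import ibio_total
        from ibioscore.simulate import SimulationConfig, generate_cohort

        records, _ = generate_cohort(SimulationConfig(preset="initial"))
        scores = [ibio_total(r).total for r in records]
        labels = [r.gs_category().presence for r in records]
        c = roc_curve(scores, labels)
        assert select_threshold(c, "min_sensitivity", floor=0.879) in (3, 4, 5)

    def test_infeasible_floor_reports_best_achievable(self):
        c = roc_curve([0, 1], [False, True])
        with pytest.raises(ValueError, match="best achievable"):
            select_threshold(c, "min_sensitivity", floor=1.5)


@pytest.mark.parametrize(
    "x,expected", [(5.25, 5.3), (7.264, 7.3), (3.05, 3.1), (0.84 * 144 / 23.04 / (36 / 36), 5.3)]
)
def test_display_rounding_is_half_up(x, expected):
    assert round_half_up(x) == expected
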