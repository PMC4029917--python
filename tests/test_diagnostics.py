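"""Diagnostic-test evaluation: confusion counts, metrics, ROC, cutoffs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xreact import (
    ClassSizeError,
    ConfusionCounts,
    confusion_at_cutoff,
    mann_whitney_auc,
    max_efficiency_cutoff,
    metrics,
    predict,
    roc_curve,
)
from conftest import random_score_table


def table(rows):
    return pd.DataFrame(rows, columns=["score", "label"])


POS, NEG = "cross-reactive", "non-cross-reactive"


class TestConfusion:
    def test_cutoff_zero_predicts_everything_positive(self):
        t = table([(0.2, POS), (0.4, NEG), (0.9, POS)])
        c = confusion_at_cutoff(t, 0.0)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 0, 0)

    def test_forced_split(self):
        t = table([(0.9, POS), (0.7, POS), (0.5, NEG), (0.3, NEG)])
        c = confusion_at_cutoff(t, 0.6)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_cutoff_above_max_predicts_nothing(self):
        t = table([(0.9, POS), (0.5, NEG)])
        c = confusion_at_cutoff(t, 0.95)
        assert c.tp == 0 and c.fp == 0

    def test_score_at_cutoff_is_positive(self):
        c = confusion_at_cutoff(table([(0.6, POS)]), 0.6)
        assert c.tp == 1

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValueError, match="non-binary"):
            confusion_at_cutoff(table([(0.5, "maybe")]), 0.5)


class TestMetrics:
    # Published confusion rows for the bath-salts assays at their tabulated
    # cutoffs; expected ratios are hand arithmetic on the printed counts.
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,sens,spec,eff",
        [
            (6, 2, 25, 2, 6 / 8, 25 / 27, 31 / 35),   # mephedrone assay, cutoff 0.680
            (5, 0, 30, 0, 1.0, 1.0, 1.0),             # MDPV assay, cutoff 0.630
            (2, 0, 26, 1, 2 / 3, 1.0, 28 / 29),       # mephentermine assay, cutoff 0.840
            (3, 7, 19, 0, 1.0, 19 / 26, 22 / 29),     # mephentermine assay, cutoff 0.420
            (27, 21, 44, 3, 27 / 30, 44 / 65, 71 / 95),  # JWH-018 ELISA, cutoff 0.673
            (3, 0, 92, 0, 1.0, 1.0, 1.0),             # JWH-250 ELISA, cutoff 0.875
            (13, 0, 6, 4, 13 / 17, 1.0, 19 / 23),     # MKT-1030, cutoff 0.673
            (15, 0, 3, 4, 15 / 19, 1.0, 18 / 22),     # MKT-1032, cutoff 0.673
            (23, 0, 4, 8, 23 / 31, 1.0, 27 / 35),     # Neogen cannabinoids, cutoff 0.673
        ],
    )
    def test_published_count_rows(self, tp, fp, tn, fn, sens, spec, eff):
        m = metrics(ConfusionCounts(tp, fp, tn, fn, cutoff=0.5))
        assert m.sensitivity == pytest.approx(sens)
        assert m.specificity == pytest.approx(spec)
        assert m.efficiency == pytest.approx(eff)
        assert not m.undefined

    def test_degenerate_all_wrong(self):
        m = metrics(ConfusionCounts(0, 3, 0, 2, cutoff=0.5))
        assert m.efficiency == 0.0

    def test_zero_denominators_flagged_not_zeroed(self):
        m = metrics(ConfusionCounts(0, 2, 3, 0, cutoff=0.5))
        assert math.isnan(m.sensitivity) and "sensitivity" in m.undefined
        assert m.specificity == pytest.approx(0.6)

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_efficiency_identity(self, tp, fp, tn, fn):
        # efficiency == (sens*P + spec*N) / (P + N) wherever defined
        P, N = tp + fn, tn + fp
        if P == 0 or N == 0:
            return
        m = metrics(ConfusionCounts(tp, fp, tn, fn, cutoff=0.5))
        assert m.efficiency == pytest.approx(
            (m.sensitivity * P + m.specificity * N) / (P + N)
        )


class TestRocCurve:
    def test_perfect_separation_gives_auc_one(self):
        t = table([(0.9, POS)] * 5 + [(0.1, NEG)] * 5)
        assert roc_curve(t).auc == 1.0

    def test_all_ties_give_auc_half(self):
        t = table([(0.5, POS)] * 5 + [(0.5, NEG)] * 5)
        assert roc_curve(t).auc == 0.5

    def test_curve_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            curve = roc_curve(random_score_table(rng, ties=True))
            assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
            assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
            assert np.all(np.diff(curve.fpr) >= 0)
            assert np.all(np.diff(curve.tpr) >= 0)

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(5)
        for i in range(200):
            t = random_score_table(
                rng,
                n_pos=int(rng.integers(5, 15)),
                n_neg=int(rng.integers(5, 15)),
                ties=bool(i % 2),
            )
            scores = t["score"].to_numpy()
            pos = (t["label"] == POS).to_numpy()
            wins = ties = 0
            for p in scores[pos]:
                for n in scores[~pos]:
                    wins += p > n
                    ties += p == n
            expected = (wins + 0.5 * ties) / (pos.sum() * (~pos).sum())
            assert roc_curve(t).auc == pytest.approx(expected)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        t = random_score_table(rng, ties=True)
        base = roc_curve(t).auc
        for f in [np.sqrt, lambda s: s**3, lambda s: np.log1p(10 * s)]:
            t2 = t.copy()
            t2["score"] = f(t2["score"].to_numpy())
            assert roc_curve(t2).auc == pytest.approx(base)

    def test_points_reproduce_confusion_counts(self):
        rng = np.random.default_rng(13)
        t = random_score_table(rng, ties=True)
        curve = roc_curve(t)
        for thr, fpr, tpr in zip(curve.thresholds, curve.fpr, curve.tpr):
            c = confusion_at_cutoff(t, thr)
            assert c.tp / c.n_positive == pytest.approx(tpr)
            assert c.fp / c.n_negative == pytest.approx(fpr)

    def test_class_size_guard_names_both_sizes(self):
        t = table([(0.9, POS)] * 4 + [(0.1, NEG)] * 10)
        with pytest.raises(ClassSizeError) as exc:
            roc_curve(t)
        assert exc.value.n_positive == 4 and exc.value.n_negative == 10


class TestMaxEfficiencyCutoff:
    def test_perfect_separation_picks_high_specificity_cutoff(self):
        t = table([(0.9, POS)] * 5 + [(0.1, NEG)] * 5)
        res = max_efficiency_cutoff(t)
        assert res.metrics.efficiency == 1.0
        # the only perfectly separating candidate is the midpoint
        assert res.cutoff == pytest.approx(0.5)
        assert res.metrics.specificity == 1.0

    def test_guard_refuses_four_positives(self):
        t = table([(0.9, POS)] * 4 + [(0.1, NEG)] * 6)
        with pytest.raises(ClassSizeError):
            max_efficiency_cutoff(t)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        for i in range(200):
            t = random_score_table(
                rng,
                n_pos=int(rng.integers(5, 12)),
                n_neg=int(rng.integers(5, 12)),
                ties=bool(i % 2),
            )
            res = max_efficiency_cutoff(t)
            # oracle: evaluate efficiency on a dense grid plus all candidates
            scores = np.unique(t["score"].to_numpy())
            grid = np.concatenate(
                [scores, (scores[:-1] + scores[1:]) / 2, [scores[0] - 1, scores[-1] + 1]]
            )
            best = max(
                (metrics(confusion_at_cutoff(t, c)).efficiency for c in grid)
            )
            assert res.metrics.efficiency == pytest.approx(best)


class TestPredict:
    def test_cutoff_splits_predictions(self):
        untested = pd.DataFrame({"compound_id": ["a", "b"], "score": [0.85, 0.455]})
        out = predict(untested, 0.673, assay_name="x", key_set_id="public166")
        got = dict(zip(out["compound_id"], out["predicted"]))
        assert got == {"a": POS, "b": NEG}
        assert set(out["cutoff"]) == {0.673}
        assert set(out["key_set_id"]) == {"public166"}

    def test_empty_input_gives_empty_output(self):
        out = predict(pd.DataFrame({"compound_id": [], "score": []}), 0.5)
        assert len(out) == 0
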