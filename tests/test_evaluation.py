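"""AUC against an independent pair-counting oracle; strata, bins, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicecnn.evaluation import (
    UndefinedAUCError,
    aggregate_folds,
    format_auc,
    inclusion_bin_auc,
    roc_auc,
    roc_curve_points,
    stratified_report,
)


def pair_counting_auc(scores, labels):
    """Independent oracle: enumerate every (positive, negative) pair,
    crediting 1 for a correct ordering and 1/2 for a tie."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_inverted_and_worked_example(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0
        # 4 (pos, neg) pairs, 3 correctly ordered
        assert roc_auc([0.8, 0.6, 0.55, 0.4], [1, 0, 1, 0]) == 0.75

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force plenty of ties
            scores = np.round(rng.random(n), 1)
            assert abs(roc_auc(scores, labels) - pair_counting_auc(scores, labels)) < 1e-12

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(20):
            labels = rng.integers(0, 2, 100)
            labels[:2] = [0, 1]
            scores = rng.normal(size=100)
            assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=30), st.data())
    def test_invariant_under_monotone_transform(self, scores, data):
        labels = data.draw(st.lists(st.sampled_from([0, 1]), min_size=len(scores),
                                    max_size=len(scores)))
        if sum(labels) in (0, len(labels)):
            labels[0] = 1 - labels[0]
        # quantize so the affine map cannot collapse near-identical floats
        scores = np.round(np.array(scores), 3)
        a = roc_auc(scores, labels)
        # strictly increasing affine map preserves the ordering and all ties
        b = roc_auc(10.0 * scores + 3.0, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_roc_curve_endpoints(self):
        pts = roc_curve_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert pts.iloc[0]["fpr"] == 0.0 and pts.iloc[0]["tpr"] == 0.0
        assert pts.iloc[-1]["fpr"] == 1.0 and pts.iloc[-1]["tpr"] == 1.0


class TestAggregate:
    def test_zero_variance_and_hand_example(self):
        assert aggregate_folds([0.9] * 5) == (pytest.approx(0.9), pytest.approx(0.0))
        mean, se = aggregate_folds([0.8, 0.9])
        assert mean == pytest.approx(0.85)
        assert se == pytest.approx(0.05)  # sd 0.0707.. / sqrt(2)

    def test_single_fold_is_degenerate(self):
        with pytest.raises(ValueError):
            aggregate_folds([0.8])

    def test_presentation_format(self):
        assert format_auc(0.899, 0.008) == "0.899 (±0.008)"


def _binary_predictions(seed=0, hevents_weaker=True):
    """Synthetic CON-ES prediction frame: ES scores shrink with inclusion
    level when `hevents_weaker`, mirroring harder high-inclusion events."""
    rng = np.random.default_rng(seed)
    rows = []
    for fold in range(4):
        for i in range(40):
            rows.append({"event_id": f"c{fold}_{i}", "task": "CON-ES", "fold": fold,
                         "true_label": "CON", "level": 1.0, "stratum": "CON",
                         "score": rng.normal(0.3, 0.15)})
        for i in range(40):
            level = rng.random()
            strength = (1.0 - 0.6 * level) if hevents_weaker else 1.0
            rows.append({"event_id": f"e{fold}_{i}", "task": "CON-ES", "fold": fold,
                         "true_label": "ES", "level": level,
                         "stratum": "HEvents" if level > 0.8 else "MREvents",
                         "score": rng.normal(0.3 + 0.5 * strength, 0.15)})
    return pd.DataFrame(rows)


class TestStratifiedReport:
    def test_mrevents_beat_hevents_when_planted(self):
        reports = {r.scope: r for r in stratified_report(_binary_predictions(), "CON-ES")}
        assert reports["MREvents"].mean > reports["HEvents"].mean
        assert reports["all"].n == reports["MREvents"].n + reports["HEvents"].n

    def test_dsc_reports_four_classes_plus_average(self):
        rng = np.random.default_rng(3)
        rows = []
        for fold in range(3):
            for cls in ("CON", "ES", "ALT3", "ALT5"):
                for i in range(15):
                    p = rng.dirichlet([2, 1, 1, 1] if cls == "CON" else [1, 1, 1, 1])
                    rows.append({"event_id": f"{cls}{fold}_{i}", "task": "DSC",
                                 "fold": fold, "true_label": cls,
                                 "level": 1.0 if cls == "CON" else rng.random(),
                                 "stratum": "CON" if cls == "CON" else "MREvents",
                                 "p_CON": p[0], "p_ES": p[1], "p_ALT3": p[2], "p_ALT5": p[3]})
        reports = [r for r in stratified_report(pd.DataFrame(rows), "DSC") if r.scope == "all"]
        classes = [r.cls for r in reports]
        assert classes == ["CON", "ES", "ALT3", "ALT5", "macro"]
        macro = reports[-1]
        per_fold_means = [np.mean([r.fold_aucs[f] for r in reports[:4]]) for f in range(3)]
        assert macro.mean == pytest.approx(np.mean(per_fold_means))

    def test_empty_stratum_flagged_not_dropped(self):
        preds = _binary_predictions()
        preds = preds[(preds["stratum"] != "HEvents")]
        reports = {r.scope: r for r in stratified_report(preds, "CON-ES")}
        assert reports["HEvents"].computable is False
        assert "HEvents" in reports  # present, not silently dropped


class TestInclusionBins:
    def test_boundary_conventions(self):
        preds = _binary_predictions(seed=5)
        preds.loc[preds["true_label"] == "ES", "level"] = np.linspace(0.0, 0.999, 160)
        by10 = inclusion_bin_auc(preds, n_bins=10)
        assert by10[-1].scope == "bin_10/10" and by10[-1].computable  # 0.999 in closed last bin
        preds2 = _binary_predictions(seed=6)
        es_idx = preds2["true_label"] == "ES"
        preds2.loc[es_idx, "level"] = 0.20
        by5 = inclusion_bin_auc(preds2, n_bins=5)
        assert by5[1].scope == "bin_2/5" and by5[1].computable  # 0.20 on a half-open left edge
        assert all(not r.computable for r in by5 if r.scope != "bin_2/5")

    def test_monotone_trend_when_difficulty_grows_with_inclusion(self):
        preds = _binary_predictions(seed=8)
        by5 = inclusion_bin_auc(preds, n_bins=5)
        aucs = [r.mean for r in by5 if r.computable]
        assert aucs[0] > aucs[-1]  # first bins are easier than the last
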