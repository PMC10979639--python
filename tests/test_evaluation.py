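import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scatinception.errors import InputError
from scatinception.evaluation import (
    ConfusionCounts,
    aggregate_folds,
    assign_fixed_split,
    case_level_predict,
    compute_metrics,
    confusion_counts,
    make_folds,
    roc_auc,
)


def _case_df(n_gbm, n_met):
    rows = [(f"g{i}", "GBM") for i in range(n_gbm)] + [
        (f"m{i}", "MET") for i in range(n_met)
    ]
    return pd.DataFrame(rows, columns=["case_id", "class_label"])


class TestMakeFolds:
    def test_251_cases_fold_sizes(self):
        split = make_folds(_case_df(127, 124), k=5, seed=0)
        sizes = sorted(len(f) for f in split.folds)
        assert sizes == [50, 50, 50, 50, 51]

    def test_partition_law(self):
        df = _case_df(13, 17)
        split = make_folds(df, k=5, seed=3)
        seen = [c for f in split.folds for c in f]
        assert len(seen) == len(set(seen)) == 30
        assert set(seen) == set(df["case_id"])

    def test_forced_stratification(self):
        split = make_folds(_case_df(5, 5), k=5, seed=1)
        for fold in split.folds:
            assert sum(c.startswith("g") for c in fold) == 1
            assert sum(c.startswith("m") for c in fold) == 1

    def test_stratification_within_one_case(self):
        split = make_folds(_case_df(127, 124), k=5, seed=9)
        for fold in split.folds:
            n_gbm = sum(c.startswith("g") for c in fold)
            assert abs(n_gbm - 127 / 5) <= 1

    def test_seeded(self):
        a = make_folds(_case_df(20, 20), k=5, seed=4)
        b = make_folds(_case_df(20, 20), k=5, seed=4)
        assert a.folds == b.folds

    def test_too_few_cases(self):
        with pytest.raises(InputError):
            make_folds(_case_df(2, 1), k=5, seed=0)

    def test_slices_stay_with_case(self):
        # manifest with 3 rows per case still yields case-disjoint folds
        df = _case_df(6, 6).loc[lambda d: d.index.repeat(3)].reset_index(drop=True)
        split = make_folds(df, k=3, seed=0)
        seen = [c for f in split.folds for c in f]
        assert len(seen) == len(set(seen)) == 12


class TestFixedSplit:
    def test_207_of_251(self):
        out = assign_fixed_split(_case_df(127, 124), n_train=207, seed=0)
        assert (out["split"] == "train").sum() == 207
        assert (out["split"] == "test").sum() == 44

    def test_invalid_n_train(self):
        with pytest.raises(InputError):
            assign_fixed_split(_case_df(3, 3), n_train=6)


class TestConfusionCounts:
    def test_perfect_pair(self):
        cc = confusion_counts(["GBM", "MET"], ["GBM", "MET"])
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (1, 1, 0, 0)

    def test_direct_enumeration(self):
        cc = confusion_counts(
            ["GBM", "GBM", "MET", "MET"], ["MET", "GBM", "GBM", "MET"]
        )
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (1, 1, 1, 1)

    def test_matches_bruteforce_tally(self, rng):
        labels = ["GBM", "MET"]
        y_true = [labels[i] for i in rng.integers(0, 2, size=100)]
        y_pred = [labels[i] for i in rng.integers(0, 2, size=100)]
        cc = confusion_counts(y_true, y_pred)
        tp = tn = fp = fn = 0  # independent loop tally
        for t, p in zip(y_true, y_pred):
            if t == "GBM" and p == "GBM":
                tp += 1
            elif t == "GBM":
                fn += 1
            elif p == "MET":
                tn += 1
            else:
                fp += 1
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (tp, tn, fp, fn)
        assert cc.total == 100

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            confusion_counts(["GBM"], ["GBM", "MET"])

    def test_unknown_label(self):
        with pytest.raises(InputError):
            confusion_counts(["GBM"], ["tumor"])


class TestComputeMetrics:
    def test_worked_example(self):
        rep = compute_metrics(ConfusionCounts(tp=3, fn=1, tn=2, fp=2))
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.5)
        assert rep.accuracy == pytest.approx(0.625)

    def test_perfect(self):
        rep = compute_metrics(ConfusionCounts(tp=5, tn=5))
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0

    def test_degenerate_class_warns_not_zero(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            rep = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        assert np.isnan(rep.sensitivity)
        assert rep.specificity == 1.0

    def test_oracle_equivalence_with_per_sample_loop(self, rng):
        labels = ["GBM", "MET"]
        y_true = [labels[i] for i in rng.integers(0, 2, size=60)]
        y_pred = [labels[i] for i in rng.integers(0, 2, size=60)]
        rep = compute_metrics(confusion_counts(y_true, y_pred))
        acc = sum(t == p for t, p in zip(y_true, y_pred)) / 60
        sens_n = [p for t, p in zip(y_true, y_pred) if t == "GBM"]
        spec_n = [p for t, p in zip(y_true, y_pred) if t == "MET"]
        assert rep.accuracy == pytest.approx(acc)
        assert rep.sensitivity == pytest.approx(sens_n.count("GBM") / len(sens_n))
        assert rep.specificity == pytest.approx(spec_n.count("MET") / len(spec_n))


def _pair_auc(scores, labels):
    # O(n^2) Mann-Whitney pair counting oracle
    pos = [s for s, l in zip(scores, labels) if l == "GBM"]
    neg = [s for s, l in zip(scores, labels) if l == "MET"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], ["GBM", "GBM", "MET", "MET"]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, ["GBM", "MET"] * 3) == 0.5

    def test_tie_case_matches_pair_counting(self):
        scores = [0.9, 0.7, 0.7, 0.6, 0.5, 0.4, 0.3, 0.1]
        labels = ["GBM", "GBM", "MET", "GBM", "MET", "GBM", "MET", "MET"]
        assert roc_auc(scores, labels) == pytest.approx(_pair_auc(scores, labels))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_pair_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        labels = ["GBM"] * (n // 2 + 1) + ["MET"] * (n - n // 2 - 1)
        assert roc_auc(scores, labels) == pytest.approx(_pair_auc(scores, labels))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(12)
        labels = ["GBM"] * 6 + ["MET"] * 6
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) + 1, labels)  # strictly monotone
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([0.5, 0.6], ["GBM", "GBM"])


def _reports(accs):
    return [
        compute_metrics(ConfusionCounts(tp=1, tn=1)) for _ in accs
    ]  # placeholder; accuracy overwritten below


def _reports_with_accuracy(accs):
    reports = _reports(accs)
    for r, a in zip(reports, accs):
        r.accuracy = a
    return reports


class TestAggregateFolds:
    def test_core_row_average(self):
        # five fold accuracies -> printed row average 92.3%
        reports = _reports_with_accuracy([0.923, 0.916, 0.934, 0.908, 0.935])
        agg = aggregate_folds(reports)
        assert round(agg["accuracy"]["mean"] * 100, 1) == 92.3

    def test_edema_row_average(self):
        reports = _reports_with_accuracy([0.875, 0.854, 0.832, 0.867, 0.845])
        agg = aggregate_folds(reports)
        assert round(agg["accuracy"]["mean"] * 100, 1) == 85.5

    def test_identical_reports_zero_variance(self):
        agg = aggregate_folds(_reports_with_accuracy([0.9] * 5))
        assert agg["accuracy"]["variance"] == 0.0

    def test_population_variance(self):
        agg = aggregate_folds(_reports_with_accuracy([0.8, 0.9]))
        assert agg["accuracy"]["variance"] == pytest.approx(np.var([0.8, 0.9]))

    def test_permutation_invariance(self, rng):
        accs = list(rng.random(5))
        a = aggregate_folds(_reports_with_accuracy(accs))
        rng.shuffle(accs)
        b = aggregate_folds(_reports_with_accuracy(accs))
        assert a["accuracy"]["mean"] == pytest.approx(b["accuracy"]["mean"])
        assert a["accuracy"]["variance"] == pytest.approx(b["accuracy"]["variance"])

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            aggregate_folds([])


class TestCaseLevelPredict:
    def test_majority(self):
        assert case_level_predict([0.9, 0.8, 0.1]) == "GBM"

    def test_unanimous_met(self):
        assert case_level_predict([0.1, 0.2, 0.3]) == "MET"

    def test_two_of_three_threshold(self):
        assert case_level_predict([0.9, 0.8, 0.1], threshold=0.5) == "GBM"

    def test_odd_count_no_ties(self):
        for probs in ([0.6, 0.4, 0.4], [0.6, 0.6, 0.4]):
            assert case_level_predict(probs) in ("GBM", "MET")
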