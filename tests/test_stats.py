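"""Confusion metrics, kappa, ICC, AUC, permutation test and the
reconstruction of confusion matrices from printed summary rows."""

import itertools

import numpy as np
import pandas as pd
import pytest

from autoaspects import published as pub
from autoaspects.stats import (ConfusionMatrix, ReaderStudy, UndefinedMetricError,
                               accuracy_metric, basic_metrics, cohens_kappa,
                               confusion, icc_absolute_agreement,
                               permutation_test_paired, reconstruct_confusion,
                               roc_auc, round_half_away, sensitivity_metric)


class TestConfusion:
    def test_perfect_agreement(self):
        pred = np.array([1, 1, 0, 0, 1], dtype=bool)
        cm = confusion(pred, pred)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (3, 0, 0, 2)

    def test_total_disagreement(self):
        truth = np.array([1, 0, 1], dtype=bool)
        cm = confusion(~truth, truth)
        assert cm.tp == 0 and cm.tn == 0 and cm.n == 3

    def test_matches_elementwise_tally(self, rng):
        pred = rng.random(200) < 0.4
        truth = rng.random(200) < 0.3
        cm = confusion(pred, truth)
        # element-wise loop oracle
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for p, t in zip(pred, truth):
            tally[("t" if p == t else "f") + ("p" if p else "n")] += 1
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tally["tp"], tally["fp"],
                                                tally["fn"], tally["tn"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([True], [True, False])


class TestBasicMetrics:
    def test_published_caudate_f1_from_precision_recall(self):
        # F1 from the printed precision/recall pair
        f1 = 2 * 0.474 * 0.409 / (0.474 + 0.409)
        assert round_half_away(f1, 3) == 0.439

    def test_m2_row_from_reconstructed_matrix(self):
        cm = ConfusionMatrix(tp=16, fp=18, fn=5, tn=141)
        m = basic_metrics(cm)
        assert round_half_away(m["sensitivity"] * 100, 1) == 76.2
        assert round_half_away(m["specificity"] * 100, 1) == 88.7
        assert round_half_away(m["accuracy"] * 100, 1) == 87.2
        assert round_half_away(m["precision"] * 100, 1) == 47.1
        assert round_half_away(m["f1"], 3) == 0.582

    def test_perfect_classifier_all_ones(self):
        m = basic_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_flagged_undefined(self):
        m = basic_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=4))
        assert m["sensitivity"] is None and m["precision"] is None
        assert m["accuracy"] == 1.0


class TestCohensKappa:
    def test_published_caudate_kappa(self):
        assert round_half_away(cohens_kappa(ConfusionMatrix(9, 10, 13, 148)), 3) == 0.367

    def test_perfect_agreement_is_one(self):
        assert cohens_kappa(ConfusionMatrix(tp=3, fp=0, fn=0, tn=7)) == 1.0

    def test_independent_rater_with_matched_marginals_is_zero(self):
        # independence: tp = P(pred+)P(truth+)n etc.; e.g. 50/100 x 40/100
        cm = ConfusionMatrix(tp=20, fp=30, fn=20, tn=30)
        assert cohens_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_never_exceeds_observed_agreement(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 30, size=4)
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(*map(int, counts))
            try:
                k = cohens_kappa(cm)
            except UndefinedMetricError:
                continue
            po = (cm.tp + cm.tn) / cm.n
            assert k <= po + 1e-12

    def test_invariant_under_class_label_swap(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = map(int, rng.integers(1, 30, size=4))
            a = cohens_kappa(ConfusionMatrix(tp, fp, fn, tn))
            b = cohens_kappa(ConfusionMatrix(tn, fn, fp, tp))
            assert a == pytest.approx(b, abs=1e-12)


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 3))
        assert icc_absolute_agreement(x) == pytest.approx(1.0)

    def test_matches_mean_squares_hand_computation(self):
        x = np.array([[9, 2], [6, 1], [8, 4], [7, 1], [10, 5], [6, 2]], dtype=float)
        n, k = x.shape
        grand = x.mean()
        msr = k * np.sum((x.mean(1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((x.mean(0) - grand) ** 2) / (k - 1)
        mse = (np.sum((x - grand) ** 2) - k * np.sum((x.mean(1) - grand) ** 2)
               - n * np.sum((x.mean(0) - grand) ** 2)) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_absolute_agreement(x) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(5, 2, size=(12, 3)) + rng.normal(0, 1, size=(12, 1))
        df = pd.DataFrame({"targets": np.repeat(np.arange(12), 3),
                           "raters": np.tile(np.arange(3), 12),
                           "ratings": x.ravel()})
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="ratings")
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]  # absolute agreement
        icc3 = ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0]  # consistency
        assert icc_absolute_agreement(x, "ICC2") == pytest.approx(icc2, abs=1e-9)
        assert icc_absolute_agreement(x, "ICC3") == pytest.approx(icc3, abs=1e-9)

    def test_constant_offset_on_one_rater_lowers_absolute_agreement(self):
        rng = np.random.default_rng(1)
        x = np.tile(rng.normal(0, 2, size=(10, 1)), (1, 2)) + rng.normal(0, .1, (10, 2))
        shifted = x.copy()
        shifted[:, 1] += 3.0
        assert icc_absolute_agreement(shifted) < icc_absolute_agreement(x)

    def test_zero_variance_flagged(self):
        with pytest.raises(UndefinedMetricError):
            icc_absolute_agreement(np.ones((5, 2)))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert r["auc"] == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(scores, labels)["auc"] == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_comparison_oracle(self, rng):
        scores = rng.integers(0, 6, size=20).astype(float)  # force ties
        labels = rng.random(20) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, labels)["auc"] == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        a = roc_auc(scores, labels)["auc"]
        b = roc_auc(np.exp(5 * scores) - 2, labels)["auc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [True, True])


def _study(cases, alone, assisted, truth, reader="r1"):
    rows = []
    for c, a, w, t in zip(cases, alone, assisted, truth):
        rows.append({"case": c, "reader": reader, "condition": "alone",
                     "decision": a, "truth": t})
        rows.append({"case": c, "reader": reader, "condition": "with_dlad",
                     "decision": w, "truth": t})
    return ReaderStudy(pd.DataFrame(rows))


class TestPermutationTest:
    def test_identical_conditions_give_large_p(self):
        d = [True, False, True, False, True]
        s = _study(range(5), d, d, [True, True, False, False, True])
        res = permutation_test_paired(accuracy_metric, s, "r1", n_perm=500, seed=0)
        assert res["observed"] == 0.0
        assert res["p_value"] >= 0.5

    def test_matches_exact_enumeration_on_toy_study(self):
        # 5 cases -> exact null over all 2^5 swap patterns
        alone = [False, False, True, False, False]
        assisted = [True, True, True, False, True]
        truth = [True, True, True, True, False]
        s = _study(range(5), alone, assisted, truth)
        alone_a, assisted_a = np.array(alone), np.array(assisted)
        truth_a = np.array(truth)
        observed = (accuracy_metric(assisted_a, truth_a)
                    - accuracy_metric(alone_a, truth_a))
        hits = 0
        for bits in itertools.product([0, 1], repeat=5):
            m = np.array(bits, dtype=bool)
            a = np.where(m, assisted_a, alone_a)
            b = np.where(m, alone_a, assisted_a)
            if accuracy_metric(b, truth_a) - accuracy_metric(a, truth_a) >= observed - 1e-12:
                hits += 1
        exact = hits / 32
        n_perm = 10_000
        res = permutation_test_paired(accuracy_metric, s, "r1", n_perm=n_perm, seed=3)
        mc_sd = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res["p_value"] - exact) <= 3 * mc_sd + 2 / n_perm

    def test_uniform_improvement_is_significant(self):
        n = 20
        alone = [False] * n
        assisted = [True] * n
        truth = [True] * n
        s = _study(range(n), alone, assisted, truth)
        res = permutation_test_paired(sensitivity_metric, s, "r1", n_perm=2000, seed=1)
        assert res["p_value"] <= 0.01

    def test_super_uniform_under_null(self):
        # decisions exchangeable between conditions -> P(p <= a) <= a (+MC slack)
        rng = np.random.default_rng(11)
        reps, n_perm, n_cases = 300, 150, 12
        pvals = []
        for _ in range(reps):
            truth = rng.random(n_cases) < 0.6
            a = rng.random(n_cases) < 0.5
            b = rng.random(n_cases) < 0.5
            s = _study(range(n_cases), a, b, truth)
            pvals.append(permutation_test_paired(accuracy_metric, s, "r1",
                                                 n_perm=n_perm, seed=rng)["p_value"])
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            assert np.mean(pvals <= alpha) <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_missing_condition_rejected(self):
        df = pd.DataFrame([{"case": 0, "reader": "r1", "condition": "alone",
                            "decision": True, "truth": True}])
        with pytest.raises(ValueError, match="with_dlad"):
            permutation_test_paired(accuracy_metric, ReaderStudy(df), "r1", n_perm=10)


class TestReconstructConfusion:
    def test_caudate_row_unique(self):
        r = reconstruct_confusion(0.409, 0.937, 0.872, 0.474, 180)
        assert r.unique
        assert r.matrix == ConfusionMatrix(tp=9, fp=10, fn=13, tn=148)

    def test_putamen_row_unique(self):
        r = reconstruct_confusion(0.865, 0.559, 0.622, 0.337, 180)
        assert r.unique
        assert r.matrix == ConfusionMatrix(tp=32, fp=63, fn=5, tn=80)

    def test_perfect_metrics_degenerate_non_unique(self):
        r = reconstruct_confusion(1.0, 1.0, 1.0, 1.0, 10)
        assert len(r.matrices) == 9  # tp+tn=10 with both classes present
        assert not r.unique

    def test_inconsistent_metrics_yield_empty_with_diagnostic(self):
        r = reconstruct_confusion(0.5, 0.5, 0.9, 0.5, 10)
        assert r.matrices == []
        assert r.closest is not None

    def test_every_published_region_row_reconstructs(self):
        for name, (sens, spec, acc, prec, f1, kappa, _auc) in pub.REGION_ROWS.items():
            r = reconstruct_confusion(sens / 100, spec / 100, acc / 100, prec / 100,
                                      pub.N_REGION_INSTANCES)
            assert r.unique, name
            m = basic_metrics(r.matrix)
            assert round_half_away(m["f1"], 3) == f1, name
            assert round_half_away(cohens_kappa(r.matrix), 3) == kappa, name

    def test_pooled_row_from_summed_matrices(self):
        total = ConfusionMatrix(0, 0, 0, 0)
        for sens, spec, acc, prec, *_ in pub.REGION_ROWS.values():
            total = total + reconstruct_confusion(sens / 100, spec / 100, acc / 100,
                                                  prec / 100, 180).matrix
        m = basic_metrics(total)
        sens, spec, acc, f1, kappa, _ = pub.POOLED_ROW
        assert round_half_away(m["sensitivity"] * 100, 1) == sens
        assert round_half_away(m["specificity"] * 100, 1) == spec
        assert round_half_away(m["accuracy"] * 100, 1) == acc
        assert round_half_away(m["f1"], 2) == f1
        assert round_half_away(cohens_kappa(total), 2) == kappa
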