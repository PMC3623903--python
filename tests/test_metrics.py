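import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import hingecrf as hc
from hingecrf.labels import LabelString
from hingecrf.metrics import Confusion, bootstrap_se, pooled_metric

from _oracles import pairwise_auc


def _ls(bits):
    return LabelString(np.asarray(bits, dtype=np.int8), 2)


class TestConfusion:
    def test_perfect_prediction(self):
        truth = _ls([1] * 7 + [0] * 93)
        c = hc.confusion_counts(truth, truth)
        assert (c.TP, c.TN, c.FP, c.FN) == (7, 93, 0, 0)

    def test_degenerate_all_boundary_predictor(self):
        truth = _ls([1] * 10 + [0] * 90)
        pred = _ls([1] * 100)
        c = hc.confusion_counts(pred, truth)
        assert (c.TP, c.FP, c.TN, c.FN) == (10, 90, 0, 0)

    def test_random_case_against_positionwise_recount(self):
        rng = np.random.default_rng(0)
        truth = _ls(rng.integers(0, 2, size=500))
        pred = _ls(rng.integers(0, 2, size=500))
        c = hc.confusion_counts(pred, truth)
        tp = fp = tn = fn = 0
        for p, t in zip(pred.codes, truth.codes):
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)
        assert c.total == 500

    def test_three_state_labels_rejected(self):
        l3 = LabelString(np.array([0, 1, 2], dtype=np.int8), 3)
        with pytest.raises(ValueError):
            hc.confusion_counts(l3, l3)


class TestScalarMetrics:
    def test_hand_confusion_case(self):
        rep = hc.scalar_metrics(Confusion(TP=8, FN=2, TN=85, FP=5))
        assert rep.Sn == pytest.approx(0.800, abs=1e-9)
        assert rep.Sp == pytest.approx(0.9444, abs=5e-5)
        assert rep.Ac == pytest.approx(0.93, abs=1e-9)
        assert rep.MCC == pytest.approx(0.664, abs=5e-4)

    def test_perfect_confusion(self):
        rep = hc.scalar_metrics(Confusion(TP=10, FN=0, TN=90, FP=0))
        assert rep.Sn == rep.Sp == rep.Ac == rep.MCC == rep.Sw == 1.0

    def test_weighted_score_convention(self):
        # the Sn/Sp operating point published for the R=10 hinge size
        rep = hc.scalar_metrics(Confusion(TP=81, FN=19, TN=87, FP=13))
        assert rep.Sn == pytest.approx(0.81)
        assert rep.Sp == pytest.approx(0.87)
        assert rep.Sw == pytest.approx(0.68)
        # Sw equals 2*balanced accuracy - 1
        assert rep.Sw == pytest.approx(2 * ((rep.Sn + rep.Sp) / 2) - 1)

    def test_zero_denominators_reported_undefined(self):
        rep = hc.scalar_metrics(Confusion(TP=0, FN=0, TN=10, FP=0))
        assert rep.Sn is None and rep.MCC is None and rep.Sw is None
        assert rep.Sp == 1.0

    def test_mcc_invariant_under_class_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
            a = hc.scalar_metrics(Confusion(tp, fp, tn, fn)).MCC
            b = hc.scalar_metrics(Confusion(tn, fn, tp, fp)).MCC
            assert a == pytest.approx(b, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        truth = _ls([1, 1, 0, 0])
        assert hc.roc_auc([0.9, 0.8, 0.2, 0.1], truth) == 1.0

    def test_all_ties_give_half(self):
        truth = _ls([1, 0, 1, 0])
        assert hc.roc_auc([0.5] * 4, truth) == 0.5

    def test_matches_pairwise_oracle_and_sklearn(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, size=200)
        truth[0], truth[1] = 0, 1
        scores = np.round(rng.random(200), 2)  # rounding forces ties
        got = hc.roc_auc(scores, _ls(truth))
        assert got == pytest.approx(pairwise_auc(scores, truth), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_negated_scores_complement(self):
        rng = np.random.default_rng(3)
        truth = _ls(rng.integers(0, 2, size=100))
        scores = rng.random(100)
        assert hc.roc_auc(scores, truth) == pytest.approx(
            1.0 - hc.roc_auc(-scores, truth), abs=1e-12
        )

    def test_single_class_undefined(self):
        assert hc.roc_auc([0.1, 0.2], _ls([0, 0])) is None


class TestBootstrap:
    def _bernoulli_records(self, rng, m=40, k=50, q=0.3):
        records = []
        for _ in range(m):
            truth = _ls(np.zeros(k))
            pred = _ls((rng.random(k) < q).astype(int))
            records.append((pred, truth, np.zeros(k)))
        return records

    def test_constant_metric_has_zero_se(self):
        records = [(_ls([1, 0, 0, 0]), _ls([1, 0, 0, 0]), np.zeros(4)) for _ in range(10)]
        assert bootstrap_se(records, pooled_metric("Ac"), seed=0) == 0.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        records = self._bernoulli_records(rng)
        a = bootstrap_se(records, pooled_metric("Ac"), seed=11)
        b = bootstrap_se(records, pooled_metric("Ac"), seed=11)
        assert a == b
        assert a != bootstrap_se(records, pooled_metric("Ac"), seed=12)

    def test_bernoulli_accuracy_matches_sampling_theory(self):
        """SE of pooled accuracy under 80% without-replacement subsampling:
        sqrt((1-f) * q(1-q) / (f*m*k)), the finite-population form."""
        rng = np.random.default_rng(5)
        m, k, q, f = 40, 50, 0.3, 0.8
        records = self._bernoulli_records(rng, m=m, k=k, q=q)
        se = bootstrap_se(records, pooled_metric("Ac"), frac=f, seed=6)
        analytic = np.sqrt((1 - f) * q * (1 - q) / (f * m * k))
        assert abs(se - analytic) / analytic < 0.25

    def test_requires_two_targets(self):
        with pytest.raises(ValueError):
            bootstrap_se([(_ls([1]), _ls([1]), np.zeros(1))], pooled_metric("Ac"))
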