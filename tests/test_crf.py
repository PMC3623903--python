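import numpy as np
import pytest

import hingecrf as hc
from hingecrf.crf import (
    CRFModel,
    _Batch,
    _forward_backward,
    _node_scores,
    _objective,
    sequence_log_likelihood,
)
from hingecrf.labels import LabelString

from _oracles import crf_enumerate

FEATURES = [f"x:0:{c}" for c in "ABCDEF"]


def random_instance(rng, L=None, n_feats=6, feats_per_pos=2):
    L = L or int(rng.integers(1, 9))
    x = [
        [FEATURES[rng.integers(n_feats)] for _ in range(feats_per_pos)]
        for _ in range(L)
    ]
    vocab = {f: i for i, f in enumerate(FEATURES[:n_feats])}
    model = CRFModel(vocab, rng.normal(scale=0.8, size=3 * n_feats + 9))
    return model, x


class TestInferenceAgainstEnumeration:
    def test_marginals_partition_and_viterbi(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            model, x = random_instance(rng)
            X = model.encode(x)
            S, T = _node_scores(model, X), model.T
            log_z_ref, marg_ref, path_ref = crf_enumerate(S, T)
            log_z, node, _ = _forward_backward(S, T)
            assert log_z == pytest.approx(log_z_ref, abs=1e-9)
            assert np.abs(node - marg_ref).max() < 1e-9
            marg = hc.posterior_marginals(model, x)
            assert np.abs(marg.by_code() - marg_ref).max() < 1e-9
            assert tuple(hc.viterbi_path(model, x).codes) == path_ref

    def test_sequence_likelihoods_sum_to_one(self):
        import itertools

        rng = np.random.default_rng(1)
        model, x = random_instance(rng, L=4)
        total = sum(
            np.exp(sequence_log_likelihood(model, x, LabelString(np.array(p), 3)))
            for p in itertools.product(range(3), repeat=4)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestGradient:
    def test_matches_central_differences(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            model, x = random_instance(rng, L=5)
            y = rng.integers(0, 3, size=5)
            batch = _Batch([model.encode(x)], [y], model.n_features)
            w = rng.normal(scale=0.5, size=model.weights.size)
            _, grad = _objective(w, batch, 1.0)
            num = np.zeros_like(w)
            for i in range(w.size):
                e = np.zeros_like(w)
                e[i] = 1e-6
                num[i] = (
                    _objective(w + e, batch, 1.0)[0] - _objective(w - e, batch, 1.0)[0]
                ) / 2e-6
            scale = max(np.abs(num).max(), 1.0)
            assert np.abs(grad - num).max() / scale < 1e-5

    def test_batched_objective_matches_per_sequence_likelihood(self):
        """The padded-batch objective agrees with summing the independent
        single-sequence likelihood path (different recursion code)."""
        rng = np.random.default_rng(3)
        model, _ = random_instance(rng)
        xs = [random_instance(rng, L=int(rng.integers(1, 9)))[1] for _ in range(4)]
        ys = [rng.integers(0, 3, size=len(x)) for x in xs]
        w = rng.normal(scale=0.5, size=model.weights.size)
        model.weights = w
        batch = _Batch([model.encode(x) for x in xs], list(ys), model.n_features)
        nll, _ = _objective(w, batch, 1e6)  # negligible prior
        direct = -sum(
            sequence_log_likelihood(model, x, LabelString(y.astype(np.int8), 3))
            for x, y in zip(xs, ys)
        )
        assert nll == pytest.approx(direct + float(w @ w) / (2 * 1e12), abs=1e-8)


class TestTraining:
    def _toy_separable(self):
        xa = [["x:0:A"]] * 6
        xb = [["x:0:B"]] * 6
        ya = LabelString(np.zeros(6, dtype=np.int8), 3)
        yb = LabelString(np.ones(6, dtype=np.int8), 3)
        return [(xa, ya), (xb, yb)]

    def test_separable_toy_set_recovered(self):
        data = self._toy_separable()
        model = hc.train_crf(data, hc.TrainConfig(l2_sigma=10.0, max_iter=100))
        for x, y in data:
            assert hc.viterbi_path(model, x) == y

    def test_zero_iterations_gives_uniform_model(self):
        data = self._toy_separable()
        model = hc.train_crf(data, hc.TrainConfig(max_iter=0))
        assert np.all(model.weights == 0)
        marg = hc.posterior_marginals(model, data[0][0])
        assert np.allclose(marg.values, 1 / 3)
        # all-zero weights: tie broken toward label 0 everywhere
        assert np.all(hc.viterbi_path(model, data[0][0]).codes == 0)

    def test_objective_history_non_decreasing(self):
        data = self._toy_separable()
        model = hc.train_crf(data, hc.TrainConfig(max_iter=50))
        hist = model.history
        assert len(hist) >= 2
        assert all(b >= a - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_length_mismatch_rejected(self):
        x = [["x:0:A"]] * 3
        y = LabelString(np.zeros(4, dtype=np.int8), 3)
        with pytest.raises(ValueError):
            hc.train_crf([(x, y)])

    def test_single_position_closed_form(self):
        """L=1: marginals are the softmax of the summed per-label weights."""
        rng = np.random.default_rng(4)
        model, _ = random_instance(rng)
        x = [[FEATURES[0], FEATURES[3]]]
        scores = model.W[0] + model.W[3]
        expected = np.exp(scores - scores.max())
        expected /= expected.sum()
        assert np.allclose(hc.posterior_marginals(model, x).by_code(), expected)

    def test_model_json_round_trip(self):
        data = self._toy_separable()
        model = hc.train_crf(data, hc.TrainConfig(max_iter=30))
        clone = CRFModel.from_json(model.to_json())
        assert clone.feature_index == model.feature_index
        assert np.array_equal(clone.weights, model.weights)
        x = data[0][0]
        assert np.array_equal(
            hc.posterior_marginals(clone, x).values,
            hc.posterior_marginals(model, x).values,
        )

    def test_unseen_features_fall_back_to_uniform(self):
        model = hc.train_crf(self._toy_separable(), hc.TrainConfig(max_iter=30))
        marg = hc.posterior_marginals(model, [["x:0:NEVER_SEEN"]])
        assert np.allclose(marg.values, 1 / 3, atol=1e-12)
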