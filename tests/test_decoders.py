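import itertools

import numpy as np
import pytest

from flexdecode.characterize import Barcode
from flexdecode.core import BinnedTensor
from flexdecode.decoders import (
    FlexDecoder,
    SvmModel,
    binarize_counts,
    build_flex_weights,
    classification_probability,
    decide_bins,
    default_analog_threshold,
    flex_classify,
    nearest_centroid_confusion,
    svm_classify,
    train_svm,
)


def primal_objective(w, b, X, y, C):
    slacks = np.maximum(0.0, 1.0 - y * (X @ w + b))
    return 0.5 * w @ w + C * slacks.sum()


class TestTrainSvm:
    def test_separable_clusters_match_analytic_maximum_margin(self):
        # support points (+1): x = 1 plane; (-1): x = -1 plane -> w = (1, 0), b = 0
        pos = np.array([[1.0, 0.0], [1.0, 1.0]])
        neg = np.array([[-1.0, 0.0], [-1.0, 1.0]])
        model = train_svm(pos, neg, C=1e6)
        np.testing.assert_allclose(model.weights, [1.0, 0.0], atol=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        assert np.all(model.margins >= 1.0 - 1e-6)  # zero training error

    def test_swapped_labels_negate_weights(self, rng):
        pos = rng.normal(loc=2.0, size=(20, 5))
        neg = rng.normal(loc=-2.0, size=(20, 5))
        a = train_svm(pos, neg, C=1.0)
        b = train_svm(neg, pos, C=1.0)
        np.testing.assert_allclose(a.weights, -b.weights, atol=1e-6)
        assert a.bias == pytest.approx(-b.bias, abs=1e-6)

    def test_degenerate_single_point_class_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            train_svm(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0], [0.0, 2.0]]))

    def test_optimality_against_random_perturbations(self, rng):
        pos = rng.normal(loc=1.0, size=(30, 4))
        neg = rng.normal(loc=-1.0, size=(30, 4))
        C = 0.01
        model = train_svm(pos, neg, C=C)
        X = np.vstack([pos, neg])
        y = np.concatenate([np.ones(30), -np.ones(30)])
        best = primal_objective(model.weights, model.bias, X, y, C)
        for _ in range(1000):
            dw = rng.normal(scale=0.05, size=4)
            db = rng.normal(scale=0.05)
            perturbed = primal_objective(model.weights + dw, model.bias + db, X, y, C)
            assert best <= perturbed + 1e-9

    def test_held_out_accuracy_on_synthetic_ensemble(self):
        from flexdecode.core import bin_spikes
        from flexdecode.simulate import GeneratorConfig, sample_tuning, sequence_protocol, simulate_trials

        cfg = GeneratorConfig(n_neurons=85, n_trials=10, odors=("hex", "2oct"), seed=5)
        gt = sample_tuning(cfg)
        rasters = {}
        for stream, odor in enumerate(("hex", "2oct"), start=1):
            raster, _ = simulate_trials(cfg, sequence_protocol(odor, trial_count=10), gt=gt, stream=stream)
            rasters[odor] = bin_spikes(raster, 0.05, (0.0, 4.0))

        def bins(t, trials):
            return t.counts[:, trials, :].transpose(1, 2, 0).reshape(-1, t.n_neurons).astype(float)

        train_trials, test_trials = list(range(5)), list(range(5, 10))
        model = train_svm(bins(rasters["hex"], train_trials), bins(rasters["2oct"], train_trials))
        pos_scores = model.score(bins(rasters["hex"], test_trials))
        neg_scores = model.score(bins(rasters["2oct"], test_trials))
        acc = np.mean(np.concatenate([pos_scores > 0, neg_scores <= 0]))
        assert acc >= 0.95


class TestSvmClassify:
    def test_zero_vector_negative_bias_absent(self):
        model = SvmModel(weights=np.array([1.0, 1.0]), bias=-0.5, C=0.01)
        assert not svm_classify(model, np.zeros(2))

    def test_on_hyperplane_tie_broken_to_absent(self):
        model = SvmModel(weights=np.array([1.0, -1.0]), bias=0.0, C=0.01)
        assert not svm_classify(model, np.array([2.0, 2.0]))

    def test_matches_brute_force_dot_product(self, rng):
        model = SvmModel(weights=rng.normal(size=8), bias=0.3, C=0.01)
        for _ in range(100):
            x = rng.normal(size=8)
            expected = float(np.sum(model.weights * x)) + 0.3 > 0
            assert svm_classify(model, x) == expected

    def test_length_mismatch_rejected(self):
        model = SvmModel(weights=np.ones(3), bias=0.0, C=0.01)
        with pytest.raises(ValueError, match="length"):
            svm_classify(model, np.ones(4))


class TestFlexDecoder:
    def test_weights_copied_from_barcode(self):
        barcode = Barcode(labels=np.array([1, 0, 1, 1], bool), neuron_ids=("a", "b", "c", "d"))
        dec = build_flex_weights(barcode)
        np.testing.assert_array_equal(dec.weights, [1, 0, 1, 1])
        assert dec.n == 3

    def test_m_equal_n_rejected(self):
        barcode = Barcode(labels=np.array([1, 0, 1, 1], bool), neuron_ids=("a", "b", "c", "d"))
        with pytest.raises(ValueError, match="m="):
            build_flex_weights(barcode, m=3)

    def test_empty_barcode_rejected(self):
        barcode = Barcode(labels=np.zeros(4, bool), neuron_ids=("a", "b", "c", "d"))
        with pytest.raises(ValueError, match="all zero"):
            build_flex_weights(barcode)

    def test_two_of_three_present(self):
        dec = FlexDecoder(weights=np.array([1, 1, 1, 0]), m=2)
        x = np.array([1, 0, 1, 0])  # neurons 1 and 3 active
        assert flex_classify(dec, x, "digital")

    def test_weight_zero_neuron_ignored(self):
        dec = FlexDecoder(weights=np.array([1, 1, 1, 0]), m=2)
        x = np.array([0, 0, 0, 1])  # only the weight-0 neuron is active
        assert not flex_classify(dec, x, "digital")

    def test_digital_matches_or_of_ands_truth_table(self):
        # exhaustive over all 2^6 binary inputs for v with n = 4 ones, m = 2
        v = np.array([1, 1, 0, 1, 0, 1])
        m = 2
        dec = FlexDecoder(weights=v, m=m)
        weighted = np.flatnonzero(v)
        for bits in itertools.product((0, 1), repeat=6):
            x = np.array(bits)
            # brute-force OR over all n-choose-m ANDs of weighted neurons
            oracle = any(
                all(x[i] for i in combo)
                for combo in itertools.combinations(weighted, m)
            )
            assert flex_classify(dec, x, "digital") == oracle

    def test_digital_invariant_to_which_m_neurons(self):
        dec = FlexDecoder(weights=np.array([1, 1, 1, 1, 0]), m=2)
        for combo in itertools.combinations(range(4), 2):
            x = np.zeros(5, int)
            x[list(combo)] = 1
            assert flex_classify(dec, x, "digital")

    def test_analog_thresholding(self):
        dec = FlexDecoder(weights=np.array([1, 0, 1]), tau=4.0)
        assert flex_classify(dec, np.array([3.0, 99.0, 1.0]), "analog")
        assert not flex_classify(dec, np.array([3.0, 99.0, 0.5]), "analog")

    def test_default_analog_threshold_formula(self):
        dec = FlexDecoder(weights=np.array([1, 1, 0, 1]))
        bins = np.array([[2.0, 2.0, 0.0, 2.0], [4.0, 4.0, 9.0, 4.0]])  # scores 6, 12
        assert default_analog_threshold(dec, bins, m=2) == pytest.approx(2 / 3 * 9.0)

    def test_monotone_in_active_neurons(self, rng):
        dec = FlexDecoder(weights=rng.integers(0, 2, size=10) | np.eye(10, dtype=int)[0], m=1)
        for _ in range(50):
            x = rng.integers(0, 2, size=10)
            if flex_classify(dec, x, "digital"):
                more = x.copy()
                more[rng.integers(10)] = 1
                assert flex_classify(dec, more, "digital")

    def test_permutation_equivariance(self, rng):
        v = np.array([1, 0, 1, 1, 0, 1])
        dec = FlexDecoder(weights=v, m=2, tau=3.0)
        for _ in range(30):
            x = rng.integers(0, 4, size=6).astype(float)
            perm = rng.permutation(6)
            dec_p = FlexDecoder(weights=v[perm], m=2, tau=3.0)
            assert flex_classify(dec, x, "analog") == flex_classify(dec_p, x[perm], "analog")
            xb = (x > 1).astype(int)
            assert flex_classify(dec, xb, "digital") == flex_classify(dec_p, xb[perm], "digital")


class TestBatchDecisions:
    def _tensor(self, rng, shape=(6, 4, 10)):
        return BinnedTensor(
            counts=rng.poisson(2.0, size=shape),
            neuron_ids=tuple(f"n{i}" for i in range(shape[0])),
            bin_width_s=0.05,
            window=(0.0, 0.05 * shape[2]),
        )

    def test_analog_batch_matches_single_calls(self, rng):
        t = self._tensor(rng)
        dec = FlexDecoder(weights=np.array([1, 0, 1, 0, 1, 1]), tau=7.0)
        batch = decide_bins(dec, t, "analog")
        for trial in range(t.n_trials):
            for b in range(t.n_bins):
                assert batch[trial, b] == flex_classify(dec, t.counts[:, trial, b].astype(float), "analog")

    def test_digital_batch_matches_single_calls(self, rng):
        t = self._tensor(rng)
        thr = np.full(6, 1.5)
        dec = FlexDecoder(weights=np.array([1, 0, 1, 0, 1, 1]), m=2)
        batch = decide_bins(dec, t, "digital", thr)
        active = binarize_counts(t, thr)
        for trial in range(t.n_trials):
            for b in range(t.n_bins):
                assert batch[trial, b] == flex_classify(dec, active[:, trial, b].astype(int), "digital")


class TestClassificationProbability:
    def test_all_trials_positive_gives_one(self):
        d = np.ones((10, 5), bool)
        p = classification_probability(d, np.arange(5) * 0.05, 0.05)
        np.testing.assert_array_equal(p.probability, 1.0)

    def test_seven_of_ten(self):
        d = np.zeros((10, 1), bool)
        d[:7, 0] = True
        p = classification_probability(d, np.zeros(1), 0.05)
        assert p.probability[0] == pytest.approx(0.7)

    def test_matches_brute_force_counting(self, rng):
        d = rng.integers(0, 2, size=(8, 12)).astype(bool)
        p = classification_probability(d, np.arange(12) * 0.05, 0.05)
        for b in range(12):
            assert p.probability[b] == sum(d[t, b] for t in range(8)) / 8

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            classification_probability(np.zeros((0, 5), bool), np.arange(5) * 0.05, 0.05)


class TestNearestCentroidConfusion:
    def test_separated_clusters_identity_matrix(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3)) + 100.0
        X = np.vstack([a, b])
        y = np.array(["a"] * 10 + ["b"] * 10)
        frac, _ = nearest_centroid_confusion(X, y)
        np.testing.assert_allclose(frac, np.eye(2))

    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array(["a", "b", "c"] * 10)
        frac, _ = nearest_centroid_confusion(X, y)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)

    def test_identical_distributions_near_uniform(self):
        # off-diagonal mass ~ uniform within binomial error over 100 seeds
        rates = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(20, 3))
            y = np.array(["a"] * 10 + ["b"] * 10)
            frac, _ = nearest_centroid_confusion(X, y)
            rates.append(frac[0, 1])
        mean_off = np.mean(rates)
        # LOO nearest-centroid on iid classes misclassifies slightly above 1/2
        # (removing the held-out point shifts its own centroid away); binomial
        # s.e. over 100 seeds x 10 trials ~ 0.016
        assert 0.45 <= mean_off <= 0.65

    def test_single_trial_class_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError, match="two trials"):
            nearest_centroid_confusion(X, np.array(["a", "a", "b"]))

    def test_matches_brute_force_loo_oracle(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        frac, _ = nearest_centroid_confusion(X, y)
        classes = ["a", "b", "c"]
        counts = np.zeros((3, 3))
        for i in range(12):
            keep = np.arange(12) != i
            dists = [
                np.linalg.norm(X[i] - X[keep & (y == c)].mean(axis=0)) for c in classes
            ]
            counts[classes.index(y[i]), int(np.argmin(dists))] += 1
        np.testing.assert_allclose(frac, counts / counts.sum(axis=1, keepdims=True))
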