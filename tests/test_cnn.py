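"""Classifier architecture, training contracts, scoring, event extraction."""

import numpy as np
import pytest

from csdgait.cnn import (
    ModelSpec,
    SolverConfig,
    ToeOffCNN,
    build_model,
    detect_events,
    load_model,
    predict_scores,
    save_model,
    train,
)
from csdgait.csd import NormalizedCSDMap


def toy_problem(n_per_class=10, size=16, seed=0):
    """Linearly separable blobs rendered as tiny images."""
    r = np.random.default_rng(seed)
    X0 = r.random((n_per_class, size, size)).astype(np.float32) * 0.4
    X1 = 0.6 + r.random((n_per_class, size, size)).astype(np.float32) * 0.4
    X = np.concatenate([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestBuildModel:
    def test_stage_shapes_for_48x32(self):
        spec = build_model(48, 32)
        assert spec.stage_shapes() == [(24, 16), (12, 8), (6, 4)]
        assert spec.fc_sizes[-1] == 2

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_model(4, 4)

    def test_architecture_is_fixed(self):
        spec = build_model(16, 16)
        assert spec.conv_channels == (64, 128, 256)
        assert spec.conv_kernels == (5, 3, 3)
        assert spec.fc_sizes == (1024, 512, 2)

    def test_parameter_count_matches_hand_computation(self):
        # conv: 1*64*25+64, 64*128*9+128, 128*256*9+256
        # fc:   6144*1024+1024, 1024*512+512, 512*2+2
        expected = 1664 + 73856 + 295168 + 6292480 + 524800 + 1026
        assert build_model(48, 32).param_count() == expected == 7_188_994

    def test_network_parameters_match_spec_count(self):
        from csdgait.cnn import _build_net

        for shape in [(48, 32), (16, 16)]:
            spec = build_model(*shape)
            assert _build_net(spec).param_count() == spec.param_count()


class TestTraining:
    def test_overfits_small_toy_set(self):
        X, y = toy_problem()
        clf = ToeOffCNN(
            input_h=16, input_w=16, max_iter=500, weight_init_std=0.01,
            random_state=0, log_every=100,
        )
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_random_labels_give_chance_holdout_accuracy(self):
        r = np.random.default_rng(1)
        X = r.random((120, 16, 16)).astype(np.float32)
        y = np.tile([0, 1], 60)  # balanced, independent of X
        clf = ToeOffCNN(
            input_h=16, input_w=16, max_iter=150, weight_init_std=0.01, random_state=1
        )
        clf.fit(X[:60], y[:60])
        acc = (clf.predict(X[60:]) == y[60:]).mean()
        assert abs(acc - 0.5) < 0.2  # binomial noise at n=60

    def test_same_seed_identical_loss_curves(self):
        X, y = toy_problem()
        kw = dict(input_h=16, input_w=16, max_iter=60, random_state=7)
        c1 = ToeOffCNN(**kw).fit(X, y)
        c2 = ToeOffCNN(**kw).fit(X, y)
        assert np.array_equal(c1.loss_curve_, c2.loss_curve_)

    def test_single_class_rejected(self):
        X, _ = toy_problem()
        with pytest.raises(ValueError, match="both classes"):
            ToeOffCNN(input_h=16, input_w=16, max_iter=5).fit(X, np.zeros(len(X)))

    def test_solver_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            SolverConfig(max_iterations=0)

    def test_train_wrapper_uses_solver(self):
        X, y = toy_problem(n_per_class=6)
        solver = SolverConfig(max_iterations=20, seed=3, weight_init_std=0.01)
        clf = train((X, y), solver)
        assert clf.n_iter_ == 20
        assert len(clf.loss_curve_) == 20

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        clf = ToeOffCNN(max_iter=10, random_state=0)
        params = clf.get_params()
        assert params["learning_rate"] == 0.001
        assert params["momentum"] == 0.9
        assert params["weight_decay"] == 0.0005
        clone(clf)  # must be cloneable for model selection


class TestScoring:
    def test_untrained_symmetric_net_scores_near_half(self):
        # with the near-symmetric tiny-Gaussian init the two logits are
        # almost tied, so a 2-way softmax sits at ~0.5 before training
        X, y = toy_problem(n_per_class=4)
        clf = ToeOffCNN(
            input_h=16, input_w=16, max_iter=1, random_state=0,
            weight_init_std=0.0001,
        )
        clf.fit(X, y)
        s = clf.decision_scores(X)
        assert np.all(np.abs(s - 0.5) < 0.05)

    def test_probabilities_normalized_and_aligned(self):
        X, y = toy_problem(n_per_class=5)
        clf = ToeOffCNN(input_h=16, input_w=16, max_iter=30, random_state=0).fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        maps = [
            NormalizedCSDMap(values=x, n=2, anchor_frame_index=i + 3)
            for i, x in enumerate(X[:4])
        ]
        anchors, scores = predict_scores(clf, maps)
        assert anchors.tolist() == [3, 4, 5, 6]
        assert len(scores) == 4
        assert np.all((scores >= 0) & (scores <= 1))

    def test_dimension_mismatch_rejected(self):
        X, y = toy_problem(n_per_class=4)
        clf = ToeOffCNN(input_h=16, input_w=16, max_iter=1, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="shape"):
            clf.decision_scores(np.zeros((2, 8, 8)))


class TestCheckpoint:
    def test_round_trip_preserves_scores(self, tmp_path):
        X, y = toy_problem(n_per_class=5)
        clf = ToeOffCNN(input_h=16, input_w=16, max_iter=30, random_state=0).fit(X, y)
        save_model(clf, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        assert np.allclose(back.decision_scores(X), clf.decision_scores(X))


class TestDetectEvents:
    def test_two_peaks_survive_separation(self):
        det = detect_events(
            np.array([0.1, 0.9, 0.1, 0.1, 0.95, 0.1]), threshold=0.5, min_separation=2
        )
        assert det.predicted_indices.tolist() == [1, 4]

    def test_all_below_threshold_gives_empty(self):
        det = detect_events(np.full(10, 0.2), threshold=0.5, min_separation=2)
        assert det.predicted_indices.size == 0

    def test_close_peaks_suppressed_to_higher(self):
        det = detect_events(
            np.array([0.1, 0.8, 0.9, 0.1]), threshold=0.5, min_separation=3
        )
        assert det.predicted_indices.tolist() == [2]

    def test_matches_brute_force_nms_on_random_scores(self, rng):
        def brute(scores, thr, sep):
            n = len(scores)
            cand = [
                i for i in range(n)
                if scores[i] > thr
                and (i == 0 or scores[i] >= scores[i - 1])
                and (i == n - 1 or scores[i] >= scores[i + 1])
            ]
            kept = []
            for i in sorted(cand, key=lambda i: (-scores[i], i)):
                if all(abs(i - j) >= sep for j in kept):
                    kept.append(i)
            return sorted(kept)

        for _ in range(25):
            scores = np.round(rng.random(30), 3)
            got = detect_events(scores, 0.5, 4).predicted_indices.tolist()
            assert got == brute(scores, 0.5, 4)

    def test_anchor_offset_respected(self):
        det = detect_events(
            np.array([0.1, 0.9, 0.1]), threshold=0.5, min_separation=2,
            anchor_indices=np.array([5, 6, 7]),
        )
        assert det.predicted_indices.tolist() == [6]

    def test_non_consecutive_anchors_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            detect_events(np.array([0.9, 0.9]), anchor_indices=np.array([1, 5]))
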