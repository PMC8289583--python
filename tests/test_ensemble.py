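import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beatboost import ensemble


class TestWeightedError:
    def test_all_correct_is_zero(self):
        w = np.full(4, 0.25)
        assert ensemble.weighted_error(list("NNVV"), list("NNVV"), w) == 0.0

    def test_all_wrong_is_one(self):
        w = np.full(4, 0.25)
        assert ensemble.weighted_error(list("VVNN"), list("NNVV"), w) == 1.0

    def test_uniform_weights_one_wrong_of_four(self):
        w = np.full(4, 0.25)
        assert ensemble.weighted_error(list("NNVN"), list("NNVV"), w) == pytest.approx(0.25)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            ensemble.weighted_error(["N"], ["N"], np.array([0.5]))


class TestAlpha:
    def test_symmetry_point(self):
        assert ensemble.alpha(0.5) == 0.0

    def test_quarter_error_closed_form(self):
        assert ensemble.alpha(0.25) == pytest.approx(0.5 * math.log(3.0), abs=1e-15)

    def test_monotone_decreasing_on_grid(self):
        grid = np.arange(0.01, 0.50, 0.01)
        vals = [ensemble.alpha(e) for e in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v > 0 for v in vals)

    def test_clamped_at_zero_error(self):
        assert np.isfinite(ensemble.alpha(0.0))
        assert ensemble.alpha(0.0) > 10


class TestUpdateWeights:
    def test_zero_alpha_leaves_weights(self):
        w = np.array([0.3, 0.7])
        out = ensemble.update_weights(w, np.array([True, False]), 0.0)
        np.testing.assert_allclose(out, w)

    def test_hand_computed_two_samples(self):
        # uniform weights, second sample wrong, alpha = 1/2 ln 3:
        # w' = (0.5*3^-1/2, 0.5*3^1/2) / z = (0.25, 0.75)
        out = ensemble.update_weights(
            np.array([0.5, 0.5]), np.array([True, False]), 0.5 * math.log(3.0)
        )
        np.testing.assert_allclose(out, [0.25, 0.75], atol=1e-15)

    @given(
        n=st.integers(2, 30),
        seed=st.integers(0, 10_000),
        a=st.floats(-2, 2, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalization_contract(self, n, seed, a):
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(n))
        correct = rng.random(n) < 0.5
        out = ensemble.update_weights(w, correct, a)
        assert abs(out.sum() - 1.0) <= 1e-12
        assert (out >= 0).all()


class TestResampleRound:
    def test_weights_reset_to_uniform(self):
        labels = np.array(list("NNNNNVVS"), dtype=object)
        w, idx = ensemble.resample_round(labels, np.random.default_rng(0))
        np.testing.assert_allclose(w, np.full(8, 1 / 8))
        assert len(idx) == 8

    def test_bootstrap_reproducible_under_seed(self):
        labels = np.array(list("NNNNVVVS"), dtype=object)
        _, i1 = ensemble.resample_round(labels, np.random.default_rng(7))
        _, i2 = ensemble.resample_round(labels, np.random.default_rng(7))
        assert np.array_equal(i1, i2)

    def test_balanced_bootstrap_keeps_minority_classes(self):
        labels = np.array(["N"] * 90 + ["S"] * 6 + ["V"] * 4, dtype=object)
        _, idx = ensemble.resample_round(labels, np.random.default_rng(1))
        got = set(idx.tolist())
        assert set(range(90, 100)) <= got  # every minority sample present


def _xy_separable(n=20, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(-2.0, 0.3, (n // 2, 2))
    x1 = rng.normal(+2.0, 0.3, (n // 2, 2))
    X = np.vstack([x0, x1])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
    return X, y


class TestFitPredict:
    def test_separable_toy_reaches_training_accuracy_one(self):
        X, y = _xy_separable()
        cfg = ensemble.AdaBoostConfig(rounds=3, n_estimators=5, seed=0)
        model = ensemble.fit(X, y, cfg)
        assert np.mean(ensemble.predict(model, X) == y) == 1.0

    def test_single_round_equals_base_forest(self):
        X, y = _xy_separable(40, seed=2)
        cfg = ensemble.AdaBoostConfig(rounds=1, n_estimators=10, seed=4)
        model = ensemble.fit(X, y, cfg)
        base_pred = model.base_learners[0].predict(X).astype(object)
        assert np.array_equal(ensemble.predict(model, X), base_pred)

    def test_seeded_determinism(self):
        X, y = _xy_separable(40, seed=5)
        cfg = ensemble.AdaBoostConfig(rounds=4, n_estimators=10, seed=9)
        m1, m2 = ensemble.fit(X, y, cfg), ensemble.fit(X, y, cfg)
        assert m1.alphas == m2.alphas
        assert m1.errors == m2.errors
        assert np.array_equal(ensemble.predict(m1, X), ensemble.predict(m2, X))

    def test_single_class_input_rejected(self):
        X = np.zeros((5, 2))
        y = np.array(["N"] * 5, dtype=object)
        with pytest.raises(ensemble.TrainingError, match="two classes"):
            ensemble.fit(X, y)

    def test_feature_count_mismatch_rejected(self):
        X, y = _xy_separable()
        model = ensemble.fit(X, y, ensemble.AdaBoostConfig(rounds=1, n_estimators=3))
        with pytest.raises(ValueError, match="feature count"):
            ensemble.predict(model, np.zeros((2, 5)))

    def test_hopeless_base_learner_exhausts_retries(self):
        class WrongConstant:
            def __init__(self, rs): ...
            def fit(self, X, y, sample_weight=None):
                self._cls = "b"
                return self
            def predict(self, X):
                return np.array([self._cls] * len(X), dtype=object)

        X = np.zeros((10, 2))
        y = np.array(["a"] * 9 + ["b"], dtype=object)
        cfg = ensemble.AdaBoostConfig(
            rounds=2, base_learner=lambda rs: WrongConstant(rs),
            max_resample_retries=3, balanced_bootstrap=False,
        )
        with pytest.raises(ensemble.TrainingError, match="round 1"):
            ensemble.fit(X, y, cfg)

    def test_error_just_below_half_is_accepted(self):
        # a constant learner wrong on 49% of the weight must not reset
        class Constant:
            def __init__(self, rs): ...
            def fit(self, X, y, sample_weight=None):
                return self
            def predict(self, X):
                return np.array(["a"] * len(X), dtype=object)

        X = np.zeros((100, 2))
        y = np.array(["a"] * 51 + ["b"] * 49, dtype=object)
        cfg = ensemble.AdaBoostConfig(
            rounds=1, base_learner=lambda rs: Constant(rs),
            balanced_bootstrap=False,
        )
        model = ensemble.fit(X, y, cfg)
        assert model.errors[0] == pytest.approx(0.49)

    def test_two_learners_higher_alpha_wins_vote(self):
        class Fixed:
            def __init__(self, labels): self._labels = labels
            n_features_in_ = 1
            def predict(self, X):
                return np.array([self._labels] * len(X), dtype=object).ravel()

        model = ensemble.AdaBoostModel(
            base_learners=[Fixed("N"), Fixed("V")],
            alphas=[1.0, 0.2],
            classes=["N", "V"],
            config=ensemble.AdaBoostConfig(),
        )
        assert ensemble.predict(model, np.zeros((3, 1))).tolist() == ["N"] * 3

    def test_vote_tie_breaks_by_class_order(self):
        class Fixed:
            def __init__(self, label): self._label = label
            n_features_in_ = 1
            def predict(self, X):
                return np.array([self._label] * len(X), dtype=object)

        model = ensemble.AdaBoostModel(
            base_learners=[Fixed("V"), Fixed("S")],
            alphas=[0.7, 0.7],
            classes=["S", "V"],  # canonical AAMI order S before V
            config=ensemble.AdaBoostConfig(),
        )
        assert ensemble.predict(model, np.zeros((1, 1)))[0] == "S"

    def test_model_archive_round_trip(self, tmp_path):
        X, y = _xy_separable(30, seed=6)
        cfg = ensemble.AdaBoostConfig(rounds=2, n_estimators=5, seed=1)
        model = ensemble.fit(X, y, cfg)
        ensemble.save_model(model, tmp_path / "m.pkl")
        back = ensemble.load_model(tmp_path / "m.pkl")
        assert back.alphas == model.alphas
        assert np.array_equal(ensemble.predict(back, X), ensemble.predict(model, X))

    def test_one_vs_rest_mode_predicts_all_classes(self):
        rng = np.random.default_rng(0)
        centers = {"N": (-3, 0), "S": (3, 0), "V": (0, 3)}
        X = np.vstack([rng.normal(c, 0.3, (20, 2)) for c in centers.values()])
        y = np.array(sum(([k] * 20 for k in centers), []), dtype=object)
        cfg = ensemble.AdaBoostConfig(rounds=2, n_estimators=5, seed=3, one_vs_rest=True)
        model = ensemble.fit(X, y, cfg)
        pred = ensemble.predict(model, X)
        assert np.mean(pred == y) >= 0.95


class BruteForceStump:
    """Exhaustive weighted decision stump with deterministic tie-breaks.

    Shared by the ensemble (as a pluggable base learner) and by the
    hand-rolled boosting oracle below, so both see identical base
    predictions and the boosting arithmetic itself is what differs.
    """

    def __init__(self, random_state=None): ...

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight)
        classes = sorted(set(y))
        best = None
        for j in range(X.shape[1]):
            for thr in np.unique(X[:, j]):
                for lo in classes:
                    for hi in classes:
                        pred = np.where(X[:, j] <= thr, lo, hi)
                        err = w[pred != y].sum()
                        key = (err, j, thr, str(lo), str(hi))
                        if best is None or key < best:
                            best = key
                            self._rule = (j, thr, lo, hi)
        return self

    def predict(self, X):
        j, thr, lo, hi = self._rule
        return np.where(np.asarray(X, dtype=float)[:, j] <= thr, lo, hi).astype(object)


def boosting_oracle(X, y, rounds):
    """Independent hand implementation of the boosting recursion."""
    n = len(y)
    w = np.full(n, 1.0 / n)
    trajectory = []
    for _ in range(rounds):
        stump = BruteForceStump().fit(X, y, sample_weight=w * n)
        pred = stump.predict(X)
        e = float(np.sum(w * (pred != y)))
        e_c = min(max(e, 1e-10), 1 - 1e-10)
        a = 0.5 * np.log((1 - e_c) / e_c)
        w_new = np.where(pred == y, w * np.exp(-a), w * np.exp(a))
        w = w_new / w_new.sum()
        trajectory.append((e, a, w.copy()))
    return trajectory


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_training_trajectory_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 2))
        y = np.array(list("aabbabab"), dtype=object)
        rounds = 4
        cfg = ensemble.AdaBoostConfig(
            rounds=rounds,
            base_learner=lambda rs: BruteForceStump(rs),
            bootstrap=False,
            seed=seed,
        )
        model = ensemble.fit(X, y, cfg, keep_history=True)
        oracle = boosting_oracle(X, y, rounds)
        for m in range(rounds):
            e_o, a_o, w_o = oracle[m]
            assert model.errors[m] == pytest.approx(e_o, abs=1e-12)
            assert model.alphas[m] == pytest.approx(a_o, abs=1e-12)
            np.testing.assert_allclose(model.weight_history[m + 1], w_o, atol=1e-12)

    def test_binary_vote_reproduces_sign_rule(self):
        # enumerate all +/-1 prediction patterns of two learners on one
        # sample: argmax of alpha-weighted votes == sign of the alpha-
        # weighted sum whenever the sum is nonzero
        for a1 in (0.3, 1.1):
            for a2 in (0.2, 0.9):
                for p1 in (-1, 1):
                    for p2 in (-1, 1):
                        class Fixed:
                            def __init__(self, p): self.p = p
                            n_features_in_ = 1
                            def predict(self, X):
                                return np.array([self.p] * len(X), dtype=object)

                        model = ensemble.AdaBoostModel(
                            base_learners=[Fixed(p1), Fixed(p2)],
                            alphas=[a1, a2],
                            classes=[1, -1],
                            config=ensemble.AdaBoostConfig(),
                        )
                        s = a1 * p1 + a2 * p2
                        got = ensemble.predict(model, np.zeros((1, 1)))[0]
                        if s != 0:
                            assert got == int(np.sign(s))
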