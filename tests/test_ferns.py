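import numpy as np
import pytest

import ppifern.ferns as ferns
from ppifern.ferns import (
    Fern,
    FernTest,
    FernsModel,
    class_log_scores,
    fern_index,
    fit,
    predict,
    predict_proba,
    sample_ferns,
    smoothed_prob,
)


def brute_force_posterior(model: FernsModel, X_train, y_train, x):
    """Independent dense evaluation: recount outcomes with plain Python
    loops, materialize every one of the K outcomes per fern, multiply raw
    (unlogged) smoothed probabilities and normalize."""
    K = 2 ** model.S
    n_ci = [int((y_train == 0).sum()), int((y_train == 1).sum())]
    likelihood = [1.0, 1.0]
    for fern in model.ferns:
        # dense count table, rebuilt from scratch
        counts = [[0, 0] for _ in range(K)]
        for row, label in zip(X_train, y_train):
            k = 0
            for s, t in enumerate(fern.tests):
                fired = row[t.dim] > t.threshold if t.kind == "threshold" \
                    else row[t.dim] > row[t.dim2]
                if fired:
                    k += 2 ** s
            counts[k][label] += 1
        kx = 0
        for s, t in enumerate(fern.tests):
            fired = x[t.dim] > t.threshold if t.kind == "threshold" \
                else x[t.dim] > x[t.dim2]
            if fired:
                kx += 2 ** s
        for ci in (0, 1):
            likelihood[ci] *= (model.Nr + counts[kx][ci]) / (
                K * model.Nr + n_ci[ci]
            )
    total = likelihood[0] + likelihood[1]
    return np.array([likelihood[0] / total, likelihood[1] / total])


class TestSampling:
    def test_minimal_fern_shape(self):
        f = sample_ferns(1, 1, 1, np.array([[0.0, 1.0]]), np.random.default_rng(0))
        assert len(f) == 1 and len(f[0].tests) == 1
        assert f[0].tests[0].dim == 0
        assert 0.0 <= f[0].tests[0].threshold <= 1.0

    def test_seeded_determinism(self):
        ranges = np.stack([np.zeros(6), np.ones(6)], axis=1)
        f1 = sample_ferns(6, 3, 4, ranges, np.random.default_rng(5))
        f2 = sample_ferns(6, 3, 4, ranges, np.random.default_rng(5))
        assert [t for fern in f1 for t in fern.tests] == [
            t for fern in f2 for t in fern.tests
        ]

    def test_default_configuration_has_thousand_tests(self):
        ranges = np.stack([np.zeros(10), np.ones(10)], axis=1)
        f = sample_ferns(10, 20, 50, ranges, np.random.default_rng(0))
        assert sum(len(fern.tests) for fern in f) == 1000  # N = S * M

    def test_degenerate_range_pins_threshold(self, caplog):
        ranges = np.array([[0.5, 0.5]])
        with caplog.at_level("WARNING"):
            f = sample_ferns(1, 2, 1, ranges, np.random.default_rng(0))
        assert all(t.threshold == 0.5 for t in f[0].tests)
        # strictly-greater comparison: the test never fires at the pin
        assert fern_index(np.array([0.5]), f[0]) == 0


class TestFernIndex:
    def test_all_false_gives_zero(self):
        fern = Fern(tests=[FernTest(0, 10.0), FernTest(0, 10.0)])
        assert fern_index(np.array([1.0]), fern) == 0

    def test_first_test_is_least_significant_bit(self):
        # bits (b1, b2, b3) = (1, 0, 1) -> 1*1 + 0*2 + 1*4 = 5
        fern = Fern(tests=[FernTest(0, 0.0), FernTest(1, 0.0), FernTest(2, 0.0)])
        assert fern_index(np.array([1.0, -1.0, 1.0]), fern) == 5

    def test_all_true_gives_full_house(self):
        fern = Fern(tests=[FernTest(0, -10.0)] * 4)
        assert fern_index(np.array([0.0]), fern) == 15

    def test_pairwise_kind(self):
        fern = Fern(tests=[FernTest(0, kind="pairwise", dim2=1)])
        assert fern_index(np.array([2.0, 1.0]), fern) == 1
        assert fern_index(np.array([1.0, 2.0]), fern) == 0


class TestFit:
    def test_two_instance_counts_and_self_prediction(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        model = fit(X, y, S=1, M=1, rng=3)
        assert model.class_totals.tolist() == [1, 1]
        assert sum(c.sum() for c in model.ferns[0].table.values()) == 2
        # each training instance lands on its own class
        assert predict(model, X).tolist() == [0, 1]

    def test_duplicated_training_set_doubles_counts(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(20, 3))
        y = (rng.random(20) < 0.5).astype(int)
        y[:2] = [0, 1]
        m1 = fit(X, y, S=2, M=2, rng=9)
        m2 = fit(np.vstack([X, X]), np.r_[y, y], S=2, M=2, rng=9)
        for f1, f2 in zip(m1.ferns, m2.ferns):
            assert set(f1.table) == set(f2.table)
            for k in f1.table:
                np.testing.assert_array_equal(2 * f1.table[k], f2.table[k])

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(15, 4))
        y = (rng.random(15) < 0.5).astype(int)
        y[:2] = [0, 1]
        perm = rng.permutation(15)
        m1 = fit(X, y, S=3, M=2, rng=4)
        m2 = fit(X[perm], y[perm], S=3, M=2, rng=4)
        for f1, f2 in zip(m1.ferns, m2.ferns):
            assert {k: v.tolist() for k, v in f1.table.items()} == \
                   {k: v.tolist() for k, v in f2.table.items()}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            fit(np.zeros((4, 2)), np.zeros(4, dtype=int), S=1, M=1)


class TestSmoothing:
    def test_hand_substitution(self):
        fern = Fern(tests=[FernTest(0, 0.0)], table={2: np.array([2, 0])})
        p = smoothed_prob(fern, 2, 0, Nr=1.0, K=4, class_totals=np.array([3, 0]))
        assert p == pytest.approx(3 / 7, abs=1e-15)

    def test_uniform_when_class_unseen(self):
        fern = Fern(tests=[FernTest(0, 0.0)], table={})
        for k in range(4):
            p = smoothed_prob(fern, k, 1, Nr=1.0, K=4, class_totals=np.array([5, 0]))
            assert p == pytest.approx(1 / 4, abs=1e-15)

    def test_sums_to_one_over_all_outcomes(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(30, 4))
        y = (rng.random(30) < 0.4).astype(int)
        y[:2] = [0, 1]
        model = fit(X, y, S=3, M=2, rng=1)
        for fern in model.ferns:
            for ci in (0, 1):
                total = sum(
                    smoothed_prob(fern, k, ci, model.Nr, model.K, model.class_totals)
                    for k in range(model.K)
                )
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_sparse_closed_form_matches_at_deep_ferns(self):
        # S = 20 means K = 1,048,576: sum stored entries plus the closed
        # form for the absent ones instead of materializing all K.
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(100, 8))
        y = (rng.random(100) < 0.5).astype(int)
        y[:2] = [0, 1]
        model = fit(X, y, S=20, M=3, rng=5)
        for fern in model.ferns:
            for ci in (0, 1):
                denom = model.K * model.Nr + float(model.class_totals[ci])
                stored = sum(
                    (model.Nr + float(c[ci])) / denom for c in fern.table.values()
                )
                absent = (model.K - len(fern.table)) * model.Nr / denom
                assert stored + absent == pytest.approx(1.0, abs=1e-9)


class TestScoring:
    def test_symmetric_counts_give_equal_scores(self):
        fern = Fern(
            tests=[FernTest(0, 0.5)],
            table={0: np.array([3, 3]), 1: np.array([2, 2])},
        )
        model = FernsModel(
            ferns=[fern], S=1, M=1, Nr=1.0,
            class_totals=np.array([5, 5]),
            train_feature_ranges=np.array([[0.0, 1.0]]),
        )
        s = class_log_scores(model, np.array([0.2]))
        assert s[0] == pytest.approx(s[1], abs=1e-15)
        assert predict(model, np.array([0.2])) == 0  # tie goes to class 0

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(123)
        for trial in range(30):
            n = int(rng.integers(4, 21))
            D = int(rng.integers(1, 5))
            S = int(rng.integers(1, 4))
            M = int(rng.integers(1, 3))
            X = rng.uniform(size=(n, D))
            y = (rng.random(n) < 0.5).astype(int)
            y[:2] = [0, 1]
            model = fit(X, y, S=S, M=M, rng=int(rng.integers(0, 1000)))
            x = rng.uniform(size=D)
            expected = brute_force_posterior(model, X, y, x)
            np.testing.assert_allclose(
                predict_proba(model, x), expected, atol=1e-12
            )

    def test_fern_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(25, 5))
        y = (rng.random(25) < 0.5).astype(int)
        y[:2] = [0, 1]
        model = fit(X, y, S=3, M=4, rng=8)
        x = rng.uniform(size=5)
        before = class_log_scores(model, x)
        model.ferns = model.ferns[::-1]
        np.testing.assert_allclose(class_log_scores(model, x), before, rtol=1e-15)

    def test_adding_instance_of_class_raises_its_posterior(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(20, 3))
        y = (rng.random(20) < 0.5).astype(int)
        y[:2] = [0, 1]
        x = rng.uniform(size=3)
        m1 = fit(X, y, S=2, M=2, rng=6)
        m2 = fit(np.vstack([X, x]), np.r_[y, 1], S=2, M=2, rng=6)
        p1 = predict_proba(m1, x)[1]
        p2 = predict_proba(m2, x)[1]
        assert p2 >= p1 - 1e-12

    def test_proba_sums_to_one_and_batch_matches_single(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(30, 4))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        model = fit(X, y, S=4, M=3, rng=2)
        Q = rng.uniform(size=(7, 4))
        P = predict_proba(model, Q)
        np.testing.assert_allclose(P.sum(axis=1), np.ones(7), atol=1e-12)
        for i in range(7):
            np.testing.assert_allclose(P[i], predict_proba(model, Q[i]), atol=0)

    def test_seeded_fit_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(40, 6))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        m1 = fit(X, y, S=5, M=4, rng=11)
        m2 = fit(X, y, S=5, M=4, rng=11)
        np.testing.assert_array_equal(predict(m1, X), predict(m2, X))
        assert m1.to_dict() == m2.to_dict()


class TestNullBehaviour:
    def test_permuted_labels_score_near_chance(self):
        """5-fold CV of ferns alone on separable blobs whose labels were
        permuted must land in the binomial chance band."""
        from ppifern.evaluate import kfold_split
        from ppifern.synthetic import generate_blobs

        X, y = generate_blobs(500, 10, 10.0, rng=0)
        y_perm = np.random.default_rng(1).permutation(y)
        accs = []
        for test_idx in kfold_split(500, 5, seed=2, stratify_labels=y_perm):
            mask = np.ones(500, dtype=bool)
            mask[test_idx] = False
            model = fit(X[mask], y_perm[mask], S=6, M=10, rng=3)
            accs.append((predict(model, X[test_idx]) == y_perm[test_idx]).mean())
        assert 0.40 <= np.mean(accs) <= 0.60
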