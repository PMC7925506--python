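"""Classifier implementations against brute-force oracles and sanity cases."""

import math

import numpy as np
import pytest

import gaitbench as gb
from gaitbench.classifiers import (
    ClassifierSpec,
    default_specs,
    naive_bayes_scores,
    pnn_scores,
    scg_minimize,
    _silverman_bw,
)


def _blobs(rng, n=20, d=3, c0=0.2, c1=0.8, sd=0.05):
    X = np.vstack([rng.normal(c0, sd, (n, d)), rng.normal(c1, sd, (n, d))])
    y = np.array(["healthy"] * n + ["pathological"] * n)
    return X, y


# ----------------------------------------------------------------- specs


def test_spec_validation():
    with pytest.raises(ValueError):
        ClassifierSpec("KNN", {"k": 4})  # even
    with pytest.raises(ValueError):
        ClassifierSpec("PNN", {"spread": 0.0})
    with pytest.raises(ValueError):
        ClassifierSpec("NF", {"epochs": 0})
    with pytest.raises(ValueError):
        ClassifierSpec("MLP")
    assert set(default_specs()) == set(gb.CLASSIFIER_NAMES)


def test_single_class_training_rejected():
    X = np.zeros((5, 2))
    y = np.array(["a"] * 5)
    with pytest.raises(ValueError, match="both classes"):
        gb.fit_predict(default_specs()["KNN"], X, y, X)


# ----------------------------------------------------------------- KNN


def test_knn_matches_hand_enumerated_votes():
    """7-point 1-D set: labels from explicit 5-nearest majority votes."""
    X = np.array([[0.0], [0.1], [0.2], [0.8], [0.9], [1.0], [0.55]])
    y = np.array(["a", "a", "a", "b", "b", "b", "b"])
    # x=0.3: neighbors {0.2,0.1,0.55,0.0,0.8} -> a,a,b,a,b -> 'a'
    # x=0.6: neighbors {0.55,0.8,0.9,0.2,1.0} -> b,b,b,a,b -> 'b'
    pred = gb.knn_predict(X, y, np.array([[0.3], [0.6]]), k=5)
    assert list(pred) == ["a", "b"]


def test_knn_includes_all_kth_distance_ties():
    # k=1 with two equidistant neighbors of different classes: both vote,
    # tie breaks to the first class in sorted order.
    X = np.array([[0.0], [1.0]])
    y = np.array(["b", "a"])
    assert gb.knn_predict(X, y, np.array([[0.5]]), k=1)[0] == "a"


def test_knn_matches_bruteforce_on_random_data(rng):
    X, y = _blobs(rng, n=10, sd=0.3)
    Xt = rng.uniform(0, 1, (8, 3))
    pred = gb.knn_predict(X, y, Xt, k=5)
    for x, p in zip(Xt, pred):
        d = [math.dist(x, xi) for xi in X]
        order = np.argsort(d, kind="stable")
        kth = sorted(d)[4]
        votes = [y[i] for i in range(len(X)) if d[i] <= kth + 1e-12]
        counts = {c: votes.count(c) for c in sorted(set(y))}
        assert p == max(sorted(counts), key=lambda c: counts[c])


# ----------------------------------------------------------------- PNN


def test_pnn_memorizes_with_tiny_spread(rng):
    X, y = _blobs(rng, n=10)
    pred = gb.pnn_predict(X, y, X, spread=1e-3)
    assert np.array_equal(pred, y)


def test_pnn_tie_breaks_to_first_class():
    X = np.array([[0.0], [1.0]])
    y = np.array(["z", "a"])
    # midpoint is equidistant: scores equal, first class in sorted order wins
    assert gb.pnn_predict(X, y, np.array([[0.5]]), spread=0.1)[0] == "a"


def test_pnn_scores_match_double_loop_oracle(rng):
    X, y = _blobs(rng, n=5, d=2, sd=0.3)
    Xt = rng.uniform(0, 1, (6, 2))
    spread = 0.17
    scores, classes = pnn_scores(X, y, Xt, spread)
    for ti, x in enumerate(Xt):
        for ci, c in enumerate(classes):
            pts = X[y == c]
            acc = 0.0
            for p in pts:
                acc += math.exp(-sum((a - b) ** 2 for a, b in zip(x, p)) / (2 * spread**2))
            assert scores[ti, ci] == pytest.approx(acc / len(pts), abs=1e-12)


def test_pnn_empty_class_rejected():
    with pytest.raises(ValueError):
        pnn_scores(np.zeros((2, 1)), np.array(["a", "b"]), np.zeros((1, 1)), -0.1)


# ----------------------------------------------------------------- NB


def test_naive_bayes_scores_match_double_loop_oracle(rng):
    X, y = _blobs(rng, n=8, d=2, sd=0.2)
    Xt = rng.uniform(0, 1, (5, 2))
    scores, classes = naive_bayes_scores(X, y, Xt)
    for ti, x in enumerate(Xt):
        for ci, c in enumerate(classes):
            pts = X[y == c]
            log_post = math.log(len(pts) / len(X))
            for j in range(2):
                h = _silverman_bw(pts[:, j])
                dens = sum(
                    math.exp(-0.5 * ((x[j] - p) / h) ** 2) for p in pts[:, j]
                ) / (len(pts) * h * math.sqrt(2 * math.pi))
                log_post += math.log(dens)
            assert scores[ti, ci] == pytest.approx(log_post, abs=1e-12)


# ------------------------------------------------- subtractive clustering


def test_subtractive_identical_points_one_center():
    X = np.tile([[0.4, 0.6]], (9, 1))
    centers = gb.subtractive_clustering(X)
    assert centers.shape == (1, 2)
    assert np.allclose(centers[0], [0.4, 0.6])


def test_subtractive_single_point():
    centers = gb.subtractive_clustering(np.array([[0.2, 0.9]]))
    assert np.allclose(centers, [[0.2, 0.9]])
    with pytest.raises(ValueError):
        gb.subtractive_clustering(np.empty((0, 2)))


def test_subtractive_two_blobs_two_centers(rng):
    X = np.vstack([rng.normal(0.2, 0.02, (15, 2)), rng.normal(0.8, 0.02, (15, 2))])
    centers = gb.subtractive_clustering(X, 0.5)
    assert len(centers) == 2
    assert np.linalg.norm(centers - np.array([0.2, 0.2]), axis=1).min() < 0.1
    assert np.linalg.norm(centers - np.array([0.8, 0.8]), axis=1).min() < 0.1


def test_subtractive_first_center_maximizes_potential(rng):
    """The first center is the point of maximum potential, computed by a
    direct double loop."""
    X = rng.uniform(0, 1, (12, 2))
    ra = 0.5
    pot = []
    for xi in X:
        pot.append(sum(math.exp(-4 * math.dist(xi, xj) ** 2 / ra**2) for xj in X))
    centers = gb.subtractive_clustering(X, ra)
    assert np.allclose(centers[0], X[int(np.argmax(pot))], atol=1e-9)


# ----------------------------------------------------------------- FIS


def test_fis_constant_label_predicts_constant(rng):
    X = rng.uniform(0, 1, (12, 3))
    y = np.array(["a"] * 6 + ["b"] * 6)
    # all-b training impossible (needs both classes); check near-constant:
    Xc = np.vstack([np.full((6, 3), 0.1), np.full((6, 3), 0.9)])
    pred = gb.fis_fit_predict(Xc, y, Xc)
    assert np.array_equal(pred, y)


def test_fis_one_rule_equals_linear_least_squares(rng):
    """With a single cluster the FIS output is exactly the least-squares
    linear model; compare to the normal-equations solution."""
    X = np.tile([[0.5, 0.5]], (10, 1)) + rng.normal(0, 0.01, (10, 2))
    y01 = rng.integers(0, 2, 10)
    y = np.where(y01 == 1, "b", "a")
    centers = gb.subtractive_clustering(X, 0.5)
    assert len(centers) == 1
    A = np.column_stack([X, np.ones(10)])
    theta = np.linalg.solve(A.T @ A + 1e-12 * np.eye(3), A.T @ y01)
    out_oracle = A @ theta
    pred = gb.fis_fit_predict(X, y, X)
    assert np.array_equal(pred, np.where(out_oracle >= 0.5, "b", "a"))


def test_fis_separates_blobs(rng):
    X, y = _blobs(rng, n=15, d=2)
    pred = gb.fis_fit_predict(X, y, X)
    assert np.mean(pred == y) >= 0.95


# ----------------------------------------------------------------- NF


def test_nf_init_only_boundary_is_midpoint_hyperplane(rng):
    """With 0 epochs on mirror-symmetric blobs, the decision boundary is
    the perpendicular bisector of the class means."""
    X0 = rng.normal(0.3, 0.05, (20, 2))
    X1 = 1.0 - X0  # exact mirror symmetry
    X = np.vstack([X0, X1])
    y = np.array(["a"] * 20 + ["b"] * 20)
    test = np.array([[0.45, 0.45], [0.55, 0.55], [0.2, 0.2], [0.8, 0.8]])
    pred = gb.nf_fit_predict(X, y, test, epochs=0)
    assert list(pred) == ["a", "b", "a", "b"]


def test_nf_scg_loss_non_increasing(rng):
    X, y = _blobs(rng, n=20, d=2, sd=0.15)
    pred, hist = gb.nf_fit_predict(X, y, X, epochs=100, return_history=True)
    assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))
    assert np.mean(pred == y) >= 0.95


def test_scg_minimizes_quadratic():
    A = np.diag([1.0, 10.0, 100.0])
    b = np.array([1.0, -2.0, 3.0])

    def fg(w):
        return 0.5 * w @ A @ w - b @ w, A @ w - b

    w, hist = scg_minimize(fg, np.zeros(3), max_epochs=200)
    assert np.allclose(w, np.linalg.solve(A, b), atol=1e-6)
    assert hist[-1] <= hist[0]


# ----------------------------------------------------------- all nine


@pytest.mark.parametrize("name", gb.CLASSIFIER_NAMES)
def test_every_classifier_is_deterministic(name, rng):
    X, y = _blobs(rng, n=12, d=5, sd=0.15)
    Xt = rng.uniform(0, 1, (6, 5))
    spec = default_specs()[name]
    a = gb.fit_predict(spec, X, y, Xt, seed=3)
    b = gb.fit_predict(spec, X, y, Xt, seed=3)
    assert np.array_equal(a, b)
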