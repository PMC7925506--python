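"""The nine binary gait classifiers.

SVM (RBF kernel, box constraint 1) and CART (Gini, frequency priors) are
standard fits delegated to scikit-learn.  The others are implemented here
because their stated semantics are specific:

* LDA / QDA — Gaussian discriminants with pooled / per-class covariances; a
  1e-6 diagonal ridge keeps near-collinear gait features (cadence is almost
  a function of the mean cycle duration) from producing singular matrices;
* KNN — K = 5, Euclidean distance, with *all* neighbors tied at the K-th
  distance included in the vote;
* Naive Bayes — per-feature Gaussian kernel density estimates (Silverman
  bandwidth per feature per class), class posterior by the product rule;
* PNN — probabilistic neural network: Gaussian radial-basis kernel sums per
  class with a fixed spread (default 0.1 in the normalized feature space);
* FIS — first-order Sugeno fuzzy inference system with one rule per cluster
  from subtractive clustering (influence radius 0.5), Gaussian memberships,
  linear consequents fit by least squares;
* NF — neuro-fuzzy classifier: one Gaussian cluster per class with centers,
  widths and biases trained by Moller's scaled conjugate gradient on the
  cross-entropy loss, at most 100 epochs.

All classifiers expect features normalized to [0, 1]; class order is the
sorted order of the training labels, and every tie breaks toward the first
class in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "default_specs",
    "fit_predict",
    "knn_predict",
    "naive_bayes_predict",
    "pnn_predict",
    "subtractive_clustering",
    "fis_fit_predict",
    "nf_fit_predict",
    "scg_minimize",
]

CLASSIFIER_NAMES = ("LDA", "QDA", "KNN", "NB", "SVM", "NF", "CART", "PNN", "FIS")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier name plus its (stated-default) hyperparameters."""

    name: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")
        hp = self.hyperparams
        if self.name == "KNN":
            k = hp.get("k", 5)
            if k < 1 or k % 2 == 0:
                raise ValueError("KNN k must be odd and >= 1")
        if self.name == "PNN" and hp.get("spread", 0.1) <= 0:
            raise ValueError("PNN spread must be positive")
        if self.name == "NF" and hp.get("epochs", 100) < 1:
            raise ValueError("NF epochs must be >= 1")


def default_specs() -> dict[str, ClassifierSpec]:
    """The nine classifiers with their stated default hyperparameters."""
    return {
        "LDA": ClassifierSpec("LDA", {"ridge": 1e-6}),
        "QDA": ClassifierSpec("QDA", {"ridge": 1e-6}),
        "KNN": ClassifierSpec("KNN", {"k": 5}),
        "NB": ClassifierSpec("NB", {}),
        "SVM": ClassifierSpec("SVM", {"C": 1.0, "tol": 1e-3}),
        "NF": ClassifierSpec("NF", {"epochs": 100}),
        "CART": ClassifierSpec("CART", {}),
        "PNN": ClassifierSpec("PNN", {"spread": 0.1}),
        "FIS": ClassifierSpec("FIS", {"influence": 0.5}),
    }


def _class_order(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    return classes


# ---------------------------------------------------------------------------
# Gaussian discriminant analysis (linear and quadratic)


def _gaussian_discriminant_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    pooled: bool,
    ridge: float = 1e-6,
) -> np.ndarray:
    """LDA (pooled covariance) / QDA (per-class covariance) by maximum
    Gaussian log-posterior, with a diagonal ridge against degeneracy."""
    classes = _class_order(y_train)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    n, d = X_train.shape
    means, covs, priors = [], [], []
    for c in classes:
        Xc = X_train[y_train == c]
        means.append(Xc.mean(axis=0))
        covs.append(np.cov(Xc.T, ddof=1).reshape(d, d) if len(Xc) > 1 else np.zeros((d, d)))
        priors.append(len(Xc) / n)
    if pooled:
        weights = [(np.sum(y_train == c) - 1) / (n - len(classes)) for c in classes]
        pooled_cov = sum(w * S for w, S in zip(weights, covs))
        covs = [pooled_cov for _ in classes]
    scores = np.zeros((len(X_test), len(classes)))
    for ci in range(len(classes)):
        S = covs[ci] + ridge * np.eye(d)
        sign, logdet = np.linalg.slogdet(S)
        Sinv = np.linalg.inv(S)
        diff = X_test - means[ci]
        maha = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
        scores[:, ci] = math.log(priors[ci]) - 0.5 * (logdet + maha)
    return classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# K-nearest neighbors


def knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int = 5
) -> np.ndarray:
    """Majority vote over the k nearest training points (Euclidean).

    Training points whose distance equals the k-th smallest are all included
    in the vote; vote ties break toward the first class in sorted order.
    """
    classes = _class_order(y_train)
    X_train = np.asarray(X_train, dtype=float)
    preds = []
    for x in np.atleast_2d(np.asarray(X_test, dtype=float)):
        d = np.linalg.norm(X_train - x, axis=1)
        kth = np.sort(d)[min(k, len(d)) - 1]
        voters = y_train[d <= kth + 1e-12]
        counts = [(voters == c).sum() for c in classes]
        preds.append(classes[int(np.argmax(counts))])
    return np.asarray(preds)


# ---------------------------------------------------------------------------
# Naive Bayes with Gaussian kernel density estimation


def _silverman_bw(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(float(np.mean(x))), 1.0) * 1e-3
    return 0.9 * scale * n ** (-0.2)


def naive_bayes_scores(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-posterior scores (rows: test points, cols: classes)."""
    classes = _class_order(y_train)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    scores = np.zeros((len(X_test), len(classes)))
    for ci, c in enumerate(classes):
        Xc = X_train[y_train == c]
        scores[:, ci] = math.log(len(Xc) / len(X_train))
        for j in range(X_train.shape[1]):
            h = _silverman_bw(Xc[:, j])
            u = (X_test[:, j][:, None] - Xc[:, j][None, :]) / h
            dens = np.exp(-0.5 * u * u).mean(axis=1) / (h * math.sqrt(2 * math.pi))
            scores[:, ci] += np.log(np.maximum(dens, 1e-300))
    return scores, classes


def naive_bayes_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    scores, classes = naive_bayes_scores(X_train, y_train, X_test)
    return classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# Probabilistic neural network


def pnn_scores(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, spread: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class average Gaussian-kernel activation for each test point."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    classes = _class_order(y_train)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    scores = np.zeros((len(X_test), len(classes)))
    for ci, c in enumerate(classes):
        Xc = X_train[y_train == c]
        if len(Xc) == 0:
            raise ValueError(f"class {c!r} has no training points")
        d2 = ((X_test[:, None, :] - Xc[None, :, :]) ** 2).sum(axis=2)
        scores[:, ci] = np.exp(-d2 / (2.0 * spread * spread)).mean(axis=1)
    return scores, classes


def pnn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, spread: float = 0.1
) -> np.ndarray:
    """Bayesian decision over kernel-density class scores; ties (including
    the all-underflow case) break toward the first class in sorted order."""
    scores, classes = pnn_scores(X_train, y_train, X_test, spread)
    return classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# Subtractive clustering and the Sugeno FIS


def subtractive_clustering(
    X: np.ndarray,
    influence_radius: float = 0.5,
    accept_ratio: float = 0.5,
    reject_ratio: float = 0.15,
) -> np.ndarray:
    """Chiu's subtractive clustering on (nominally [0,1]-normalized) data.

    Each point's potential is ``sum_j exp(-4 |x_i - x_j|^2 / r_a^2)``; the
    max-potential point becomes a center and its neighborhood potential is
    subtracted with squash radius ``r_b = 1.5 r_a``.  Candidates above
    ``accept_ratio`` of the first potential are accepted outright, below
    ``reject_ratio`` rejected (stop); in between the standard
    distance-plus-potential criterion decides.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("subtractive clustering needs at least one point")
    ra = influence_radius
    rb = 1.5 * ra
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    potential = np.exp(-4.0 * d2 / (ra * ra)).sum(axis=1)
    squash = np.exp(-4.0 * d2 / (rb * rb))

    centers: list[int] = []
    p = potential.copy()
    p_first = None
    for _ in range(len(X)):
        i = int(np.argmax(p))
        pi = p[i]
        if p_first is None:
            p_first = pi
        elif pi > accept_ratio * p_first:
            pass
        elif pi < reject_ratio * p_first:
            break
        else:
            d_min = math.sqrt(min(d2[i, c] for c in centers))
            if d_min / ra + pi / p_first < 1.0:
                p[i] = 0.0
                continue
        centers.append(i)
        p = p - pi * squash[i]
    return X[centers]


def _fis_memberships(
    X: np.ndarray, centers: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    """Normalized rule firing strengths, rows: points, cols: rules."""
    diff = X[:, None, :] - centers[None, :, :]
    w = np.exp(-0.5 * ((diff / sd) ** 2).sum(axis=2))
    tot = w.sum(axis=1, keepdims=True)
    tot = np.where(tot <= 1e-300, 1.0, tot)
    return w / tot


def fis_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    influence: float = 0.5,
) -> np.ndarray:
    """First-order Sugeno FIS: one rule per subtractive cluster.

    Gaussian memberships with per-feature sd ``r_a * range / sqrt(8)``,
    product firing, linear consequents fit jointly by least squares on the
    labels encoded 0/1; a pattern is assigned class 1 when the crisp output
    reaches 0.5.
    """
    classes = _class_order(y_train)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y01 = (y_train == classes[1]).astype(float)

    centers = subtractive_clustering(X_train, influence)
    rng_span = np.maximum(X_train.max(axis=0) - X_train.min(axis=0), 1e-6)
    sd = influence * rng_span / math.sqrt(8.0)

    def design(X: np.ndarray) -> np.ndarray:
        wn = _fis_memberships(X, centers, sd)
        cols = [wn * X[:, [j]] for j in range(X.shape[1])] + [wn]
        return np.concatenate(cols, axis=1)

    A = design(X_train)
    theta, *_ = np.linalg.lstsq(A, y01, rcond=None)
    if not np.all(np.isfinite(theta)):
        # rank-deficient design: ridge fallback
        lam = 1e-8
        theta = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]), A.T @ y01)
    out = design(X_test) @ theta
    return np.where(out >= 0.5, classes[1], classes[0])


# ---------------------------------------------------------------------------
# Neuro-fuzzy classifier trained by scaled conjugate gradient


def scg_minimize(
    fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    w0: np.ndarray,
    max_epochs: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, list[float]]:
    """Moller's scaled conjugate gradient.

    Returns the optimized parameters and the loss history at accepted steps
    (non-increasing by construction: a step is accepted only when the
    comparison parameter Delta >= 0, i.e. the loss did not increase).
    """
    w = np.asarray(w0, dtype=float).copy()
    f, g = fun_grad(w)
    r = -g
    p = r.copy()
    success = True
    lam, lam_bar = 1e-6, 0.0
    sigma0 = 1e-5
    history = [f]
    n = len(w)
    p2 = delta = 0.0
    for k in range(1, max_epochs + 1):
        if success:
            p2 = float(p @ p)
            if p2 < 1e-300:
                break
            sigma = sigma0 / math.sqrt(p2)
            _, g_sig = fun_grad(w + sigma * p)
            delta = float(p @ (g_sig - g)) / sigma
        delta += (lam - lam_bar) * p2
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        if abs(mu) < 1e-120 or delta == 0.0:  # mu*mu must not underflow
            break  # gradient vanished: converged
        alpha = mu / delta
        f_new, g_new = fun_grad(w + alpha * p)
        comp = 2.0 * delta * (f - f_new) / (mu * mu)
        if comp >= 0:
            w = w + alpha * p
            f_prev_r = r
            f, g = f_new, g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ f_prev_r) / mu
                p = r_new + beta * p
            r = r_new
            history.append(f)
            if comp >= 0.75:
                lam = max(lam / 4.0, 1e-15)
            if len(history) > 1 and abs(history[-2] - history[-1]) < tol:
                break
        else:
            lam_bar = lam
            success = False
        if comp < 0.25:
            lam = min(lam + delta * (1.0 - comp) / p2, 1e100)
    return w, history


def _nf_unpack(w: np.ndarray, n_classes: int, n_feat: int):
    m = n_classes * n_feat
    centers = w[:m].reshape(n_classes, n_feat)
    log_sd = w[m : 2 * m].reshape(n_classes, n_feat)
    bias = w[2 * m :]
    return centers, log_sd, bias


def nf_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    epochs: int = 100,
    return_history: bool = False,
):
    """Neuro-fuzzy classifier: one Gaussian cluster per class.

    A pattern's (log-)membership to class k is a product of per-feature
    Gaussians plus a bias; memberships are normalized across clusters
    (softmax) to class scores.  Centers are initialized at the class means,
    widths at the per-feature class standard deviations, biases at log class
    frequencies, then all are refined by scaled conjugate gradient on the
    cross-entropy loss for at most ``epochs`` accepted steps.
    """
    classes = _class_order(y_train)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    n_feat = X_train.shape[1]
    K = len(classes)
    Y = np.stack([(y_train == c).astype(float) for c in classes], axis=1)

    centers0 = np.zeros((K, n_feat))
    sd0 = np.zeros((K, n_feat))
    bias0 = np.zeros(K)
    for ci, c in enumerate(classes):
        Xc = X_train[y_train == c]
        centers0[ci] = Xc.mean(axis=0)
        sd = Xc.std(axis=0, ddof=0) if len(Xc) > 1 else np.zeros(n_feat)
        sd0[ci] = np.maximum(sd, 0.05)
        bias0[ci] = math.log(len(Xc) / len(X_train))
    w0 = np.concatenate([centers0.ravel(), np.log(sd0).ravel(), bias0])

    def forward(w: np.ndarray, X: np.ndarray):
        centers, log_sd, bias = _nf_unpack(w, K, n_feat)
        inv_var = np.exp(-2.0 * log_sd)
        diff = X[:, None, :] - centers[None, :, :]
        logits = bias[None, :] - 0.5 * (diff * diff * inv_var[None, :, :]).sum(axis=2)
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        return probs, diff, inv_var

    def fun_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        probs, diff, inv_var = forward(w, X_train)
        M = len(X_train)
        loss = -float(np.sum(Y * np.log(np.maximum(probs, 1e-300)))) / M
        if not np.isfinite(loss):
            raise FloatingPointError("neuro-fuzzy training loss is not finite")
        dlogit = (probs - Y) / M  # (M, K)
        g_centers = (dlogit[:, :, None] * diff * inv_var[None, :, :]).sum(axis=0)
        g_logsd = (dlogit[:, :, None] * diff * diff * inv_var[None, :, :]).sum(axis=0)
        g_bias = dlogit.sum(axis=0)
        return loss, np.concatenate([g_centers.ravel(), g_logsd.ravel(), g_bias])

    if epochs == 0:
        w, history = w0, [fun_grad(w0)[0]]
    else:
        w, history = scg_minimize(fun_grad, w0, max_epochs=epochs)
    probs, _, _ = forward(w, X_test)
    pred = classes[np.argmax(probs, axis=1)]
    if return_history:
        return pred, history
    return pred


# ---------------------------------------------------------------------------
# Dispatcher


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Train ``spec`` on (X_train, y_train) and label X_test.

    Deterministic given the data, the hyperparameters and ``seed`` (the seed
    only matters for CART's feature tie-breaking).
    """
    _class_order(y_train)  # raises on single-class training sets
    hp = spec.hyperparams
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if spec.name == "LDA":
        return _gaussian_discriminant_predict(
            X_train, y_train, X_test, pooled=True, ridge=hp.get("ridge", 1e-6)
        )
    if spec.name == "QDA":
        return _gaussian_discriminant_predict(
            X_train, y_train, X_test, pooled=False, ridge=hp.get("ridge", 1e-6)
        )
    if spec.name == "KNN":
        return knn_predict(X_train, y_train, X_test, k=hp.get("k", 5))
    if spec.name == "NB":
        return naive_bayes_predict(X_train, y_train, X_test)
    if spec.name == "SVM":
        model = SVC(
            C=hp.get("C", 1.0), kernel="rbf", gamma="scale", tol=hp.get("tol", 1e-3)
        )
        return model.fit(X_train, y_train).predict(X_test)
    if spec.name == "NF":
        return nf_fit_predict(X_train, y_train, X_test, epochs=hp.get("epochs", 100))
    if spec.name == "CART":
        model = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=1, random_state=seed
        )
        return model.fit(X_train, y_train).predict(X_test)
    if spec.name == "PNN":
        return pnn_predict(X_train, y_train, X_test, spread=hp.get("spread", 0.1))
    if spec.name == "FIS":
        return fis_fit_predict(X_train, y_train, X_test, influence=hp.get("influence", 0.5))
    raise ValueError(f"unknown classifier {spec.name!r}")
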