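"""Repeated stratified cross-validation and exhaustive feature-subset search.

The evaluation protocol follows the study design for a 60-pattern cohort:
disjoint stratified test folds of 10 patterns each (6 folds on 60 patterns,
50 training patterns per fold), accuracy pooled over folds, the whole
partition redrawn and re-evaluated 10 times, and the mean/std over repeats
reported.  Every classifier is scored on all 2^5 - 1 = 31 non-empty feature
subsets; the winner is the subset with the highest mean accuracy, ties
broken first by fewer features then by the lexicographic order of the mask
in canonical feature order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import CLASSIFIER_NAMES, ClassifierSpec, default_specs, fit_predict
from .features import FEATURE_NAMES

__all__ = [
    "CVProtocol",
    "BenchmarkResult",
    "stratified_folds",
    "evaluate",
    "exhaustive_search",
    "benchmark_all",
    "results_table",
    "masks_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVProtocol:
    """Repeated stratified cross-validation settings."""

    test_size: int = 10  # patterns per test fold
    repeats: int = 10
    stratified: bool = True
    seed: int = 0


@dataclass
class BenchmarkResult:
    """Best-subset outcome for one classifier."""

    classifier: str
    subset_mask: tuple  # 5 binary flags, canonical feature order
    mean_accuracy: float  # %
    std_accuracy: float  # % over repeats
    n_features: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_accuracy <= 100.0:
            raise ValueError("accuracy must lie in [0, 100]")
        if self.n_features != sum(self.subset_mask) or self.n_features < 1:
            raise ValueError("n_features must equal the mask sum and be >= 1")


def stratified_folds(
    labels: np.ndarray, test_size: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint stratified test folds of ~``test_size`` patterns.

    The number of folds is ``ceil(M / test_size)``; per-fold class counts
    stay within +-1 of the proportional share.  Extra members of the first
    class go to the earliest folds and of the second class to the latest,
    which keeps fold sizes as even as possible.
    """
    labels = np.asarray(labels)
    M = len(labels)
    if M < 2 * test_size:
        raise ValueError(f"need at least {2 * test_size} patterns, got {M}")
    n_folds = -(-M // test_size)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    for c in classes:
        if (labels == c).sum() < n_folds:
            logger.warning(
                "class %r has fewer members than folds; stratification is best-effort", c
            )

    fold_members: list[list[int]] = [[] for _ in range(n_folds)]
    for ci, c in enumerate(classes):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        base, extra = divmod(len(idx), n_folds)
        sizes = np.full(n_folds, base)
        if ci % 2 == 0:
            sizes[:extra] += 1
        else:
            sizes[n_folds - extra :] += 1
        stop = np.cumsum(sizes)
        start = stop - sizes
        for f in range(n_folds):
            fold_members[f].extend(idx[start[f] : stop[f]])

    folds = []
    all_idx = np.arange(M)
    for members in fold_members:
        test = np.sort(np.asarray(members, dtype=int))
        train = np.setdiff1d(all_idx, test)
        folds.append((train, test))
    return folds


def evaluate(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    subset_mask,
    protocol: CVProtocol,
) -> tuple[float, float]:
    """Mean and std of pooled CV accuracy (%) over the protocol's repeats.

    Each repeat draws a fresh seeded fold partition; accuracy is the pooled
    fraction of correctly classified test patterns across folds
    (micro-average — identical to the mean of fold accuracies when folds are
    equal-sized).  With a single repeat the std is 0 by convention.
    """
    mask = np.asarray(subset_mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("subset mask must select at least one feature")
    X = np.asarray(X, dtype=float)[:, mask]
    y = np.asarray(y)
    accs = []
    for r in range(protocol.repeats):
        fold_seed = (protocol.seed + 1_000_003 * r) % (2**31)
        folds = stratified_folds(y, protocol.test_size, seed=fold_seed)
        correct = 0
        for train, test in folds:
            try:
                pred = fit_predict(spec, X[train], y[train], X[test], seed=fold_seed)
            except Exception as exc:
                raise RuntimeError(
                    f"{spec.name} failed on repeat {r}, mask {tuple(int(m) for m in mask)}: {exc}"
                ) from exc
            correct += int((pred == y[test]).sum())
        accs.append(100.0 * correct / len(y))
    if protocol.repeats == 1:
        logger.info("single repeat: reporting std 0 by convention")
        return float(accs[0]), 0.0
    return float(np.mean(accs)), float(np.std(accs, ddof=1))


def _all_masks(n_features: int) -> list[tuple[int, ...]]:
    return [
        mask
        for mask in itertools.product((0, 1), repeat=n_features)
        if any(mask)
    ]


def exhaustive_search(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    protocol: CVProtocol,
    return_all: bool = False,
):
    """Evaluate all 2^N - 1 non-empty feature subsets and pick the winner.

    Ties in mean accuracy go to the subset with fewer features (a
    regularization choice), then to the lexicographically smaller mask in
    canonical feature order.  A subset whose evaluation fails is recorded
    and skipped; the search fails only if every subset fails.
    """
    n_features = np.asarray(X).shape[1]
    results: list[BenchmarkResult] = []
    failures: list[tuple[tuple, str]] = []
    for mask in _all_masks(n_features):
        try:
            mean, std = evaluate(spec, X, y, mask, protocol)
        except Exception as exc:  # recorded, run continues
            logger.warning("subset %s failed for %s: %s", mask, spec.name, exc)
            failures.append((mask, str(exc)))
            continue
        results.append(
            BenchmarkResult(
                classifier=spec.name,
                subset_mask=mask,
                mean_accuracy=mean,
                std_accuracy=std,
                n_features=int(sum(mask)),
            )
        )
    if not results:
        raise RuntimeError(f"all {len(failures)} subsets failed for {spec.name}")
    best = min(results, key=lambda r: (-r.mean_accuracy, r.n_features, r.subset_mask))
    if return_all:
        return best, results, failures
    return best


def benchmark_all(
    X: np.ndarray,
    y: np.ndarray,
    protocol: CVProtocol,
    specs: dict[str, ClassifierSpec] | None = None,
) -> dict[str, BenchmarkResult]:
    """Exhaustive best-subset search for every classifier.

    Per-classifier failures are reported and skipped so one broken model
    does not void the whole benchmark.
    """
    specs = specs if specs is not None else default_specs()
    out: dict[str, BenchmarkResult] = {}
    for name, spec in specs.items():
        try:
            out[name] = exhaustive_search(spec, X, y, protocol)
        except Exception as exc:
            logger.error("classifier %s failed: %s", name, exc)
    if not out:
        raise RuntimeError("every classifier failed")
    return out


def results_table(results: dict[str, BenchmarkResult]) -> pd.DataFrame:
    """Accuracy summary: one row per classifier (accuracy ± std, #features)."""
    rows = [
        {
            "classifier": r.classifier,
            "mean_accuracy_pct": r.mean_accuracy,
            "std_accuracy_pct": r.std_accuracy,
            "n_features": r.n_features,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows).set_index("classifier")


def masks_table(results: dict[str, BenchmarkResult]) -> pd.DataFrame:
    """Subset grid: features x classifiers 0/1 flags plus occurrence counts."""
    df = pd.DataFrame(
        {name: list(r.subset_mask) for name, r in results.items()},
        index=list(FEATURE_NAMES)[: len(next(iter(results.values())).subset_mask)],
    )
    df["occurrences"] = df.sum(axis=1)
    return df
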