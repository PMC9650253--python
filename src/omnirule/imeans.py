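"""i-means: choosing a cluster number by classifier accuracy.

The procedure combines two learners.  For each candidate K, samples
are provisionally partitioned with K-means; the partition is then
treated as a label set and scored by how accurately a random forest
can recover it on held-out samples, repeated over several stratified
train/test splits.  A partition that reflects real structure is easy
to classify (accuracy near 1); as K grows past the true group number,
clusters split noise and the correct-answer rate drops.  The chosen K
is the largest candidate whose mean accuracy stays at or above a
threshold (default 0.9); if none qualifies the procedure falls back
to K = 2 with a warning.  The evaluation forests also yield an
importance ranking of the variables that drive the grouping.

By default features are standardised (zero mean, unit variance)
before K-means, while the classifier sees the raw table; both are
toggleable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

__all__ = [
    "AccuracyCurve",
    "EvaluationResult",
    "KSelection",
    "IMeansResult",
    "kmeans_partition",
    "evaluate_partition",
    "select_k",
    "run_imeans",
]


@dataclass(frozen=True)
class AccuracyCurve:
    """Mean/sd held-out accuracy per candidate K.

    An sd of 0 simply means the repeats did not vary.  A NaN mean
    marks a K whose partition could not be evaluated (a cluster with a
    single member cannot be stratified) — such K never qualify for
    selection.
    """

    ks: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    repeats: int

    def __post_init__(self) -> None:
        if len(self.ks) != len(self.mean) or len(self.ks) != len(self.sd):
            raise ValueError("ks, mean and sd must have equal length")
        for m, s in zip(self.mean, self.sd):
            if not np.isnan(m) and not (0.0 <= m <= 1.0 and s >= 0.0):
                raise ValueError("accuracies must be in [0,1] with sd >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "mean_accuracy": self.mean, "sd": self.sd}
        ).set_index("k")


@dataclass(frozen=True)
class EvaluationResult:
    """Accuracy of one partition under repeated held-out classification."""

    mean_accuracy: float
    sd: float
    accuracies: tuple[float, ...]
    importances: pd.Series  # mean over repeats, original feature order

    def __iter__(self):  # allows: mean, sd = evaluate_partition(...)
        return iter((self.mean_accuracy, self.sd))


@dataclass(frozen=True)
class KSelection:
    chosen_k: int
    fallback: bool  # True when no K met the threshold


@dataclass(frozen=True)
class IMeansResult:
    chosen_k: int
    labels: pd.Series  # classes 1..chosen_k, renumbered by descending size
    curve: AccuracyCurve
    importances: list[tuple[str, float]]  # sorted descending
    fallback: bool


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending class size (ties: old label)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[v] for v in labels])


def kmeans_partition(
    X: pd.DataFrame | np.ndarray,
    k: int,
    seed: int | None = None,
    n_init: int = 10,
    scale: bool = True,
) -> pd.Series | np.ndarray:
    """Partition samples (rows) into k clusters with K-means.

    Lloyd iterations with k-means++ seeding and ``n_init`` restarts,
    keeping the lowest-inertia solution; deterministic given ``seed``.
    Labels are 1-based and renumbered by descending cluster size.
    ``scale=True`` standardises each feature before clustering.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-D sample-by-feature matrix")
    if np.isnan(arr).any():
        raise ValueError("X contains missing values")
    n = arr.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n_samples={n}], got {k}")
    if scale:
        arr = StandardScaler().fit_transform(arr)
        arr = np.nan_to_num(arr)  # constant features scale to 0
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = _renumber_by_size(km.fit_predict(arr))
    if isinstance(X, pd.DataFrame):
        return pd.Series(labels, index=X.index, name="class")
    return labels


def evaluate_partition(
    X: pd.DataFrame | np.ndarray,
    labels: pd.Series | np.ndarray,
    repeats: int = 5,
    seed: int | None = None,
    test_size: float = 0.3,
    n_estimators: int = 100,
    importance: str = "impurity",
) -> EvaluationResult:
    """Score a partition by repeated held-out random-forest accuracy.

    Each repeat draws a stratified train/test split, fits a forest to
    predict ``labels`` from ``X`` and records test accuracy; the
    result aggregates mean and sd over repeats (default 5, matching
    the study design this emulates) together with the averaged
    variable importances (``"impurity"`` = mean decrease in impurity,
    the classic randomForest default; ``"permutation"`` available).

    Raises if any class has fewer than 2 members (stratification is
    impossible).
    """
    Xdf = pd.DataFrame(X)
    y = np.asarray(labels)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to evaluate a partition")
    small = classes[counts < 2]
    if len(small) > 0:
        raise ValueError(
            f"class(es) with fewer than 2 members cannot be stratified: "
            f"{small.tolist()}"
        )
    if importance not in ("impurity", "permutation"):
        raise ValueError(f"importance must be impurity|permutation, got {importance!r}")
    rng = np.random.default_rng(seed)
    accs = []
    imps = np.zeros(Xdf.shape[1])
    for _ in range(repeats):
        split_seed = int(rng.integers(2**31))
        Xtr, Xte, ytr, yte = train_test_split(
            Xdf, y, test_size=test_size, stratify=y, random_state=split_seed
        )
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=split_seed
        )
        clf.fit(Xtr, ytr)
        accs.append(float(clf.score(Xte, yte)))
        if importance == "impurity":
            imps += clf.feature_importances_
        else:
            imps += permutation_importance(
                clf, Xte, yte, n_repeats=5, random_state=split_seed
            ).importances_mean
    imps /= repeats
    return EvaluationResult(
        mean_accuracy=float(np.mean(accs)),
        sd=float(np.std(accs)),
        accuracies=tuple(accs),
        importances=pd.Series(imps, index=Xdf.columns, name="importance"),
    )


def select_k(curve: AccuracyCurve, threshold: float = 0.9) -> KSelection:
    """Largest K whose mean accuracy meets ``threshold``; else 2 (fallback).

    The curve must cover a contiguous K range starting at 2.  The rule
    formalises the trade-off between more groups and a falling
    correct-answer rate: take as many groups as remain reliably
    classifiable.
    """
    if len(curve.ks) == 0:
        raise ValueError("empty accuracy curve")
    if curve.ks[0] != 2 or list(curve.ks) != list(
        range(curve.ks[0], curve.ks[0] + len(curve.ks))
    ):
        raise ValueError("curve must cover contiguous K starting at 2")
    qualifying = [
        k for k, m in zip(curve.ks, curve.mean)
        if not np.isnan(m) and m >= threshold
    ]
    if qualifying:
        return KSelection(chosen_k=max(qualifying), fallback=False)
    warnings.warn(
        f"no K reached accuracy threshold {threshold}; falling back to K=2",
        stacklevel=2,
    )
    return KSelection(chosen_k=2, fallback=True)


def run_imeans(
    X: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    repeats: int = 5,
    seed: int | None = None,
    threshold: float = 0.9,
    test_size: float = 0.3,
    n_estimators: int = 100,
    scale_for_kmeans: bool = True,
    importance: str = "impurity",
) -> IMeansResult:
    """Full i-means: scan K, score each partition, pick K, rank variables.

    Parameters
    ----------
    X
        Sample-by-feature table (e.g. the transpose of a composition
        table).
    k_range
        Inclusive (k_min, k_max); k_min must be 2.
    repeats, test_size, n_estimators
        Passed to :func:`evaluate_partition`.
    threshold
        Accuracy bar for :func:`select_k`.
    scale_for_kmeans
        Standardise features for the K-means step only; the evaluation
        classifier always sees ``X`` as given.

    Returns
    -------
    IMeansResult with the chosen K, per-sample class labels (1-based,
    renumbered by descending class size), the accuracy-vs-K curve and
    the importance ranking from the evaluation forests at the chosen K.
    """
    k_min, k_max = k_range
    if k_min != 2 or k_max < k_min:
        raise ValueError(f"k_range must be (2, k_max>=2), got {k_range}")
    rng = np.random.default_rng(seed)
    ks = list(range(k_min, k_max + 1))
    means, sds = [], []
    partitions: dict[int, pd.Series] = {}
    evaluations: dict[int, EvaluationResult] = {}
    for k in ks:
        part_seed = int(rng.integers(2**31))
        eval_seed = int(rng.integers(2**31))
        labels = kmeans_partition(X, k, seed=part_seed, scale=scale_for_kmeans)
        partitions[k] = labels
        counts = labels.value_counts()
        if (counts < 2).any():
            warnings.warn(
                f"K={k}: cluster with <2 members; accuracy recorded as NaN",
                stacklevel=2,
            )
            means.append(float("nan"))
            sds.append(float("nan"))
            continue
        res = evaluate_partition(
            X, labels, repeats=repeats, seed=eval_seed, test_size=test_size,
            n_estimators=n_estimators, importance=importance,
        )
        evaluations[k] = res
        means.append(res.mean_accuracy)
        sds.append(res.sd)
    curve = AccuracyCurve(ks=tuple(ks), mean=tuple(means), sd=tuple(sds),
                          repeats=repeats)
    sel = select_k(curve, threshold=threshold)
    chosen = sel.chosen_k
    if chosen in evaluations:
        imp = evaluations[chosen].importances
    else:  # fallback K whose own evaluation was degenerate
        imp = pd.Series(0.0, index=pd.DataFrame(X).columns)
    ranked = sorted(
        ((str(f), float(v)) for f, v in imp.items()), key=lambda t: (-t[1], t[0])
    )
    return IMeansResult(
        chosen_k=chosen,
        labels=partitions[chosen],
        curve=curve,
        importances=ranked,
        fallback=sel.fallback,
    )
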