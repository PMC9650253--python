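"""Two-group supervised comparison with repeated accuracy estimation.

Compares one clade's samples against a pooled reference group (e.g.
salmonids versus all other fishes) on a shared feature table: repeated
stratified train/test splits, a random-forest fit per repeat, held-out
accuracy aggregated over repeats (default 5), and a ranked variable
importance averaged over the repeats.  Five-number summaries per group
support boxplot-style reporting of the top-ranked features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = ["GroupComparisonResult", "classify_two_groups", "group_boxplot_table"]


@dataclass(frozen=True)
class GroupComparisonResult:
    mean_accuracy: float
    sd: float
    accuracies: tuple[float, ...]
    per_class_accuracy: dict[str, float]  # mean held-out accuracy per group
    importances: list[tuple[str, float]]  # sorted descending

    def top_features(self, n: int = 20) -> list[str]:
        return [f for f, _ in self.importances[:n]]


def _as_sample_by_feature(X: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(X)
    if df.ndim != 2:
        raise ValueError("expected a 2-D sample-by-feature table")
    return df


def classify_two_groups(
    X_a: pd.DataFrame,
    X_b: pd.DataFrame,
    repeats: int = 5,
    seed: int | None = None,
    test_size: float = 0.3,
    n_estimators: int = 100,
    group_names: tuple[str, str] = ("a", "b"),
) -> GroupComparisonResult:
    """Held-out accuracy and importance ranking for group A vs group B.

    ``X_a`` and ``X_b`` are sample-by-feature tables over an identical
    feature set (a mismatch raises, listing the symmetric difference).
    Each group needs at least 4 samples so every stratified 70/30
    split keeps both classes on both sides.  The overall accuracy is
    the weighted combination of the per-class accuracies by class
    share of the test set.
    """
    A = _as_sample_by_feature(X_a)
    B = _as_sample_by_feature(X_b)
    diff = set(A.columns) ^ set(B.columns)
    if diff:
        raise ValueError(f"feature sets differ between groups: {sorted(diff)}")
    if len(A) < 4 or len(B) < 4:
        raise ValueError("each group needs at least 4 samples")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    B = B[A.columns]
    X = pd.concat([A, B], axis=0)
    y = np.array([group_names[0]] * len(A) + [group_names[1]] * len(B))

    rng = np.random.default_rng(seed)
    accs: list[float] = []
    class_accs: dict[str, list[float]] = {g: [] for g in group_names}
    imps = np.zeros(X.shape[1])
    for _ in range(repeats):
        split_seed = int(rng.integers(2**31))
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=split_seed
        )
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=split_seed
        )
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        accs.append(float(np.mean(pred == yte)))
        for g in group_names:
            mask = yte == g
            class_accs[g].append(float(np.mean(pred[mask] == yte[mask])))
        imps += clf.feature_importances_
    imps /= repeats
    ranked = sorted(
        zip(map(str, X.columns), imps.astype(float)), key=lambda t: (-t[1], t[0])
    )
    return GroupComparisonResult(
        mean_accuracy=float(np.mean(accs)),
        sd=float(np.std(accs)),
        accuracies=tuple(accs),
        per_class_accuracy={g: float(np.mean(v)) for g, v in class_accs.items()},
        importances=ranked,
    )


def group_boxplot_table(
    X_a: pd.DataFrame,
    X_b: pd.DataFrame,
    features: Sequence[str],
    group_names: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Five-number summary per group for selected features.

    Quantiles use linear interpolation.  Returns one row per
    (group, feature) with min, q1, median, q3, max — the numbers a
    boxplot of the top discriminating features is drawn from.
    """
    out_rows = []
    for name, X in zip(group_names, (X_a, X_b)):
        df = _as_sample_by_feature(X)
        if len(df) == 0:
            raise ValueError(f"group {name!r} is empty")
        unknown = [f for f in features if f not in df.columns]
        if unknown:
            raise ValueError(f"unknown feature(s): {unknown}")
        for f in features:
            v = df[f].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            out_rows.append(
                {
                    "group": name,
                    "feature": f,
                    "min": float(v.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(v.max()),
                }
            )
    return pd.DataFrame(out_rows)
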