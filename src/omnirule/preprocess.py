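"""Normalisation of raw measurement tables and phenotype feature extraction.

Raw NMR intensity tables are scaled to an internal standard (DSS) and
then, like taxon count tables, converted to composition ratios: each
sample column is divided by its total so samples live on the
probability simplex.  Muscle cutting-strength curves are summarised by
a logarithmic fit ``force = A*ln(x) + B`` whose coefficients serve as
texture phenotypes.  An outlier rule drops samples whose composition
is concentrated on one or two features (e.g. a gut profile consisting
of essentially a single phylum).

Tables are pandas DataFrames with features as rows and samples as
columns throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ABValues",
    "normalize_to_standard",
    "composition_normalize",
    "validate_composition",
    "fit_log_curve",
    "drop_extreme_samples",
]


@dataclass(frozen=True)
class ABValues:
    """Slope and intercept of the cutting-strength log fit.

    A is the slope of force against ln(displacement); B the intercept
    (the force at unit displacement).
    """

    A: float
    B: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and np.isfinite(self.B)):
            raise ValueError("A and B must be finite")


def _check_nonnegative(table: pd.DataFrame, what: str) -> None:
    if (table.to_numpy() < 0).any():
        raise ValueError(f"{what} contains negative entries")
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")


def normalize_to_standard(
    table: pd.DataFrame, standard_feature: str
) -> pd.DataFrame:
    """Scale each sample so the internal-standard feature equals 1.

    The standard row (e.g. DSS for NMR) is then removed from the
    returned table: after scaling it is constant and carries no
    information.

    Raises if the standard is absent or non-positive in any sample,
    naming the offending sample.
    """
    _check_nonnegative(table, "intensity table")
    if standard_feature not in table.index:
        raise ValueError(f"standard feature {standard_feature!r} not in table")
    std = table.loc[standard_feature]
    bad = std.index[~(std > 0)]
    if len(bad) > 0:
        raise ValueError(
            f"standard {standard_feature!r} non-positive in sample(s) "
            f"{sorted(map(str, bad))}"
        )
    return table.drop(index=standard_feature).div(std, axis=1)


def composition_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its total (composition ratios).

    Every column of the result sums to 1; an all-zero sample raises,
    naming the sample.  Idempotent on its own output.
    """
    _check_nonnegative(table, "table")
    totals = table.sum(axis=0)
    bad = totals.index[~(totals > 0)]
    if len(bad) > 0:
        raise ValueError(f"sample(s) with zero total: {sorted(map(str, bad))}")
    return table.div(totals, axis=1)


def validate_composition(table: pd.DataFrame, atol: float = 1e-9) -> None:
    """Assert the composition-table contract: entries in [0,1], columns sum to 1."""
    vals = table.to_numpy()
    if (vals < 0).any() or (vals > 1 + atol).any():
        raise ValueError("composition entries must lie in [0, 1]")
    sums = vals.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=atol, rtol=0):
        off = table.columns[~np.isclose(sums, 1.0, atol=atol, rtol=0)]
        raise ValueError(f"columns do not sum to 1: {sorted(map(str, off))}")


def fit_log_curve(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> ABValues:
    """Ordinary-least-squares fit of ``force = A*ln(x) + B``.

    ``points`` are (displacement, force) pairs from a cutting-strength
    test; displacements must be strictly positive (log domain) and at
    least two distinct values are required.  With exactly two points
    the fit reduces to the closed-form line through them in (ln x, f)
    space.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (displacement, force) points")
    x, f = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in force curve")
    if np.any(x <= 0):
        raise ValueError("displacements must be strictly positive")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct displacement values")
    a, b = np.polyfit(np.log(x), f, 1)
    return ABValues(A=float(a), B=float(b))


def drop_extreme_samples(
    table: pd.DataFrame,
    max_mass_features: int = 2,
    mass_threshold: float = 0.99,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove samples dominated by very few features.

    A sample is dropped when its ``max_mass_features`` largest entries
    together carry at least ``mass_threshold`` of its total — e.g. a
    gut-microbiota profile consisting of essentially one phylum, which
    would distort clustering.  Returns the filtered table and the
    dropped sample ids; dropping everything only warns.
    """
    if max_mass_features < 1:
        raise ValueError("max_mass_features must be >= 1")
    if not 0.0 < mass_threshold <= 1.0:
        raise ValueError("mass_threshold must be in (0, 1]")
    vals = table.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("sample(s) with zero total; normalise or drop first")
    k = min(max_mass_features, vals.shape[0])
    top = np.sort(vals, axis=0)[-k:, :].sum(axis=0)
    extreme = (top / totals) >= mass_threshold - 1e-12
    dropped = [str(s) for s in table.columns[extreme]]
    kept = table.loc[:, ~extreme]
    if kept.shape[1] == 0:
        warnings.warn("all samples flagged as extreme; result is empty", stacklevel=2)
    return kept, dropped
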