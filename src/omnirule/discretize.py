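"""Rank-quartile discretisation of numeric tables into transaction items.

Numeric variables are reduced to three levels by ranking: the top
quarter of a ranking scope becomes ``High``, the bottom quarter
``Low``, and everything else ``NULL`` (dropped from transactions).
Two ranking scopes are used:

* phenotypes (length, weight, cutting-strength A/B, lipid, collagen)
  are ranked *within strain*, so "High" means high relative to
  conspecifics;
* omics compositions are ranked *within each individual sample*
  across features, so "High" means the feature is among that fish's
  most abundant signals.

A quarter is ``floor(n / 4)`` entries (``ceil`` available), which
guarantees the High and Low sets never overlap.  Ties that straddle a
quartile boundary suppress High/Low for the whole tied block — a
conservative policy that keeps the encoding independent of input
order — and emit a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apriori import Transactions

__all__ = [
    "QuartileEncoding",
    "quartile_encode",
    "encode_within_strata",
    "encode_within_sample",
    "build_transactions",
]

HIGH = "High"
LOW = "Low"


@dataclass(frozen=True)
class QuartileEncoding:
    """Sample-by-variable label table with values High / Low / NaN (NULL).

    ``namespace`` prefixes items built from this encoding
    (``"nmr:Anserine=High"``) so variables from different tables never
    collide.
    """

    labels: pd.DataFrame
    namespace: str

    def counts(self) -> pd.DataFrame:
        """High/Low counts per variable (column)."""
        return pd.DataFrame(
            {
                HIGH: (self.labels == HIGH).sum(),
                LOW: (self.labels == LOW).sum(),
            }
        )


def _quarter(n: int, mode: str) -> int:
    if mode == "floor":
        return n // 4
    if mode == "ceil":
        return math.ceil(n / 4)
    raise ValueError(f"quarter mode must be 'floor' or 'ceil', got {mode!r}")


def quartile_encode(
    values: Sequence[float] | pd.Series, quarter: str = "floor"
) -> list[str | None]:
    """Label a numeric vector: top quarter High, bottom quarter Low, rest None.

    Ranking is by value descending.  With fewer than 4 values (or a
    zero-sized quarter) everything is None and a warning is emitted.
    NaN values are never labelled and do not count toward n.
    """
    arr = np.asarray(pd.Series(values, dtype=float))
    n_total = len(arr)
    labels: list[str | None] = [None] * n_total
    valid = np.flatnonzero(~np.isnan(arr))
    n = len(valid)
    q = _quarter(n, quarter)
    if n < 4 or q == 0:
        warnings.warn(
            f"fewer than 4 values in ranking scope (n={n}); all labels NULL",
            stacklevel=2,
        )
        return labels
    vals = arr[valid]
    order_desc = np.argsort(-vals, kind="stable")

    def assign(order: np.ndarray, sorted_vals: np.ndarray, label: str) -> None:
        cut_val = sorted_vals[q - 1]
        if q < n and sorted_vals[q] == cut_val:
            # tied block straddles the cut: suppress it entirely
            warnings.warn(
                f"ties straddle the {label} quartile boundary; "
                "tied block left NULL",
                stacklevel=3,
            )
            chosen = order[:q][sorted_vals[:q] != cut_val]
        else:
            chosen = order[:q]
        for i in chosen:
            labels[valid[i]] = label

    assign(order_desc, vals[order_desc], HIGH)
    order_asc = np.argsort(vals, kind="stable")
    assign(order_asc, vals[order_asc], LOW)
    return labels


def encode_within_strata(
    pheno: pd.DataFrame,
    strata: pd.Series | Mapping[str, str],
    namespace: str = "pheno",
    quarter: str = "floor",
) -> QuartileEncoding:
    """Quartile-encode a sample-by-variable table within strain strata.

    Each variable is ranked independently inside each stratum, so a
    fish is "High" in weight only relative to its own strain.  Strata
    with fewer than 4 samples yield all-NULL labels (with a warning).

    Parameters
    ----------
    pheno
        Samples as rows, numeric variables as columns.
    strata
        Strain identifier per sample; must cover every sample in
        ``pheno``.
    """
    strata = pd.Series(strata)
    missing = pheno.index.difference(strata.index)
    if len(missing) > 0:
        raise ValueError(f"samples without a stratum: {sorted(map(str, missing))}")
    strata = strata.loc[pheno.index]
    out = pd.DataFrame(index=pheno.index, columns=pheno.columns, dtype=object)
    for _, idx in sorted(pheno.groupby(strata).groups.items()):
        block = pheno.loc[idx]
        for var in pheno.columns:
            out.loc[idx, var] = quartile_encode(block[var], quarter=quarter)
    return QuartileEncoding(labels=out, namespace=namespace)


def encode_within_sample(
    comp: pd.DataFrame,
    namespace: str,
    quarter: str = "floor",
    mode: str = "within_sample",
) -> QuartileEncoding:
    """Quartile-encode a feature-by-sample composition table.

    ``mode="within_sample"`` (default, the literal "ranking within an
    individual"): for each sample, features are ranked against each
    other, so every sample gets exactly floor(n_features/4) High and
    Low features (ties permitting).  ``mode="across_samples"`` ranks
    each feature's values across samples instead — the alternative
    reading, provided for comparison.

    Parameters
    ----------
    comp
        Features as rows, samples as columns (the composition-table
        orientation used throughout the package).

    Returns
    -------
    QuartileEncoding with samples as rows and features as columns.
    """
    if mode not in ("within_sample", "across_samples"):
        raise ValueError(f"mode must be within_sample|across_samples, got {mode!r}")
    if mode == "within_sample":
        if comp.shape[0] < 4:
            warnings.warn("fewer than 4 features; all labels NULL", stacklevel=2)
        data = {
            sample: quartile_encode(comp[sample], quarter=quarter)
            for sample in comp.columns
        }
        labels = pd.DataFrame.from_dict(data, orient="index", columns=comp.index)
    else:
        data = {
            feat: quartile_encode(comp.loc[feat], quarter=quarter)
            for feat in comp.index
        }
        labels = pd.DataFrame.from_dict(data, orient="columns")
        labels.index = comp.columns
    return QuartileEncoding(labels=labels, namespace=namespace)


def build_transactions(
    encodings: Sequence[QuartileEncoding],
    metadata: pd.DataFrame | None = None,
    classes: Mapping[str, pd.Series] | None = None,
    drop_empty: bool = False,
) -> Transactions:
    """Assemble per-sample transactions from encodings, metadata and classes.

    Items are namespaced strings: ``"<ns>:<variable>=<High|Low>"`` from
    each encoding, ``"<key>=<value>"`` from metadata columns, and
    ``"<name>=<label>"`` from cluster-class series (e.g.
    ``"NMR_class=2"``).  NULL labels and missing metadata values
    produce no item.  Every table must share one sample index.

    Parameters
    ----------
    encodings
        QuartileEncodings with identical sample indices.
    metadata
        Optional samples-as-rows table of categorical columns.
    classes
        Optional mapping of class-variable name to per-sample labels.
    drop_empty
        Drop samples whose transaction ends up empty (default: keep).
    """
    if not encodings and metadata is None and not classes:
        raise ValueError("nothing to encode: no encodings, metadata or classes")
    index = None
    for enc in encodings:
        if index is None:
            index = enc.labels.index
        elif not enc.labels.index.equals(index):
            missing = index.symmetric_difference(enc.labels.index)
            raise ValueError(
                f"sample index mismatch across tables: {sorted(map(str, missing))}"
            )
    if index is None:
        index = metadata.index if metadata is not None else pd.Index(
            next(iter(classes.values())).index
        )
    for name, tbl in [("metadata", metadata)] + [
        (f"classes[{k}]", v) for k, v in (classes or {}).items()
    ]:
        if tbl is None:
            continue
        missing = index.difference(tbl.index)
        if len(missing) > 0:
            raise ValueError(
                f"{name} is missing samples: {sorted(map(str, missing))}"
            )

    sample_ids: list[str] = []
    itemsets: list[frozenset[str]] = []
    for sample in index:
        items: set[str] = set()
        for enc in encodings:
            row = enc.labels.loc[sample]
            for var, label in row.items():
                if label in (HIGH, LOW):
                    items.add(f"{enc.namespace}:{var}={label}")
        if metadata is not None:
            for key, value in metadata.loc[sample].items():
                if pd.notna(value):
                    items.add(f"{key}={value}")
        for name, series in (classes or {}).items():
            value = series.loc[sample]
            if pd.notna(value):
                items.add(f"{name}={value}")
        if items or not drop_empty:
            sample_ids.append(str(sample))
            itemsets.append(frozenset(items))
    return Transactions(tuple(sample_ids), tuple(itemsets))
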