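"""Frequent-itemset mining and association rules (Apriori).

Classic level-wise Apriori over per-sample transactions: candidate
generation by (k-1)-prefix join, pruning by downward closure, exact
support counting on a boolean incidence matrix.  Rules are scored by
support, confidence and lift, and the pipeline keeps rules whose lift
is strictly greater than 1 (positive association between antecedent
and consequent).

Definitions, for a transaction set T and itemsets A, C (disjoint):

    support(A)        = |{t in T : A subset t}| / |T|
    confidence(A->C)  = support(A u C) / support(A)
    lift(A->C)        = confidence(A->C) / support(C)

The result set is complete and exact for the given thresholds; the
test suite checks it against a brute-force enumeration oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Transactions",
    "FrequentItemset",
    "AssociationRule",
    "frequent_itemsets",
    "generate_rules",
    "filter_by_lift",
    "rules_for_item",
    "mine_rules",
    "rules_to_frame",
    "write_rules_csv",
    "read_rules_csv",
]


@dataclass(frozen=True)
class Transactions:
    """Per-sample item sets (market-basket data).

    ``sample_ids[i]`` owns ``itemsets[i]``; items are plain strings such
    as ``"nmr:Anserine=High"`` or ``"habitat=lake_or_pond"``.
    """

    sample_ids: tuple[str, ...]
    itemsets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.itemsets):
            raise ValueError("sample_ids and itemsets must have equal length")

    def __len__(self) -> int:
        return len(self.itemsets)

    def __iter__(self):
        return iter(self.itemsets)

    @classmethod
    def from_itemsets(
        cls, itemsets: Iterable[Iterable[str]], sample_ids: Sequence[str] | None = None
    ) -> "Transactions":
        sets = tuple(frozenset(s) for s in itemsets)
        if sample_ids is None:
            sample_ids = tuple(f"s{i}" for i in range(len(sets)))
        return cls(tuple(str(s) for s in sample_ids), sets)

    def vocabulary(self) -> list[str]:
        """All distinct items, sorted."""
        vocab: set[str] = set()
        for t in self.itemsets:
            vocab |= t
        return sorted(vocab)

    def to_incidence(self) -> pd.DataFrame:
        """Boolean sample-by-item incidence matrix."""
        vocab = self.vocabulary()
        mat = np.zeros((len(self), len(vocab)), dtype=bool)
        col = {item: j for j, item in enumerate(vocab)}
        for i, t in enumerate(self.itemsets):
            for item in t:
                mat[i, col[item]] = True
        return pd.DataFrame(mat, index=list(self.sample_ids), columns=vocab)

    @classmethod
    def from_incidence(cls, df: pd.DataFrame) -> "Transactions":
        itemsets = [
            frozenset(df.columns[row.to_numpy(dtype=bool)]) for _, row in df.iterrows()
        ]
        return cls.from_itemsets(itemsets, [str(i) for i in df.index])

    def write_basket(self, path: str | Path) -> None:
        """One line per sample: ``sample_id<TAB>item1,item2,...``."""
        with open(path, "w") as fh:
            for sid, t in zip(self.sample_ids, self.itemsets):
                fh.write(f"{sid}\t{','.join(sorted(t))}\n")

    @classmethod
    def read_basket(cls, path: str | Path) -> "Transactions":
        ids: list[str] = []
        sets: list[frozenset[str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                sid, _, rest = line.partition("\t")
                items = [x for x in rest.split(",") if x]
                ids.append(sid)
                sets.append(frozenset(items))
        return cls(tuple(ids), tuple(sets))


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support: float

    def __post_init__(self) -> None:
        if not 0.0 < self.support <= 1.0:
            raise ValueError(f"support must be in (0, 1], got {self.support}")


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        a = ",".join(sorted(self.antecedent))
        c = ",".join(sorted(self.consequent))
        return (
            f"{{{a}}} -> {{{c}}} (supp={self.support:.3f}, "
            f"conf={self.confidence:.3f}, lift={self.lift:.3f})"
        )


def _sorted_key(items: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(items))


def frequent_itemsets(
    transactions: Transactions,
    min_support: float,
    max_len: int | None = None,
) -> list[FrequentItemset]:
    """All itemsets with support >= ``min_support`` (complete and exact).

    Level-wise Apriori: level-k candidates are built by joining level
    (k-1) itemsets sharing a (k-2)-prefix, pruned by downward closure
    (every (k-1)-subset must itself be frequent), then counted against
    a boolean incidence matrix.

    Parameters
    ----------
    transactions
        Non-empty transaction set; at least one transaction must be
        non-empty.
    min_support
        Fraction in (0, 1].
    max_len
        Optional cap on itemset cardinality.

    Returns
    -------
    list of FrequentItemset, sorted by (cardinality, items).
    """
    if len(transactions) == 0 or all(len(t) == 0 for t in transactions):
        raise ValueError("transaction set is empty")
    if not 0.0 < min_support <= 1.0:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")

    n = len(transactions)
    vocab = transactions.vocabulary()
    col = {item: j for j, item in enumerate(vocab)}
    mat = np.zeros((n, len(vocab)), dtype=bool)
    for i, t in enumerate(transactions):
        for item in t:
            mat[i, col[item]] = True

    min_count = min_support * n - 1e-9  # tolerate float representation of k/n

    # level 1: (key tuple) -> boolean coverage vector
    covers: dict[tuple[str, ...], np.ndarray] = {}
    supports: dict[tuple[str, ...], float] = {}
    level = []
    for item in vocab:
        v = mat[:, col[item]]
        cnt = int(v.sum())
        if cnt >= min_count:
            key = (item,)
            covers[key] = v
            supports[key] = cnt / n
            level.append(key)

    result = [FrequentItemset(frozenset(k), supports[k]) for k in level]
    k = 1
    while level and (max_len is None or k < max_len):
        level_set = set(level)
        level.sort()
        candidates: list[tuple[str, ...]] = []
        # prefix join: two frequent k-itemsets sharing the first k-1 items
        for i, a in enumerate(level):
            for b in level[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted, so no later b shares the prefix
                cand = a + (b[-1],)
                # downward closure: every k-subset must be frequent
                if all(
                    cand[:j] + cand[j + 1 :] in level_set for j in range(len(cand))
                ):
                    candidates.append(cand)
        next_level = []
        for cand in candidates:
            v = covers[cand[:-1]] & mat[:, col[cand[-1]]]
            cnt = int(v.sum())
            if cnt >= min_count:
                covers[cand] = v
                supports[cand] = cnt / n
                next_level.append(cand)
        result.extend(FrequentItemset(frozenset(c), supports[c]) for c in next_level)
        level = next_level
        k += 1

    result.sort(key=lambda fi: (len(fi.items), _sorted_key(fi.items)))
    return result


def _support_counter(transactions: Transactions):
    """Exact support function with memoisation."""
    n = len(transactions)
    cache: dict[frozenset[str], float] = {}

    def supp(items: frozenset[str]) -> float:
        if items not in cache:
            cache[items] = sum(1 for t in transactions if items <= t) / n
        return cache[items]

    return supp


def generate_rules(
    itemsets: Sequence[FrequentItemset],
    transactions: Transactions,
    min_confidence: float = 0.5,
) -> list[AssociationRule]:
    """Association rules from frequent itemsets.

    For every frequent itemset Z with |Z| >= 2 and every non-empty
    proper subset A of Z, the rule A -> Z\\A is emitted when its
    confidence reaches ``min_confidence``.  Support, confidence and
    lift are recomputed exactly from transaction counts; a mismatch
    between a supplied itemset support and the recount raises.

    Rules are ordered by lift (desc), then support (desc), then
    lexicographically — a stable order for reproducible output files.
    """
    if not 0.0 < min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in (0, 1], got {min_confidence}")
    supp = _support_counter(transactions)
    rules: list[AssociationRule] = []
    for fi in itemsets:
        actual = supp(fi.items)
        if abs(actual - fi.support) > 1e-9:
            raise ValueError(
                f"itemset {sorted(fi.items)} support {fi.support} inconsistent "
                f"with transactions (recount {actual})"
            )
        if len(fi.items) < 2:
            continue
        z = sorted(fi.items)
        for r in range(1, len(z)):
            for ante in itertools.combinations(z, r):
                a = frozenset(ante)
                c = fi.items - a
                conf = fi.support / supp(a)
                if conf >= min_confidence - 1e-12:
                    rules.append(
                        AssociationRule(
                            antecedent=a,
                            consequent=c,
                            support=fi.support,
                            confidence=conf,
                            lift=conf / supp(c),
                        )
                    )
    rules.sort(
        key=lambda r: (
            -r.lift,
            -r.support,
            _sorted_key(r.antecedent),
            _sorted_key(r.consequent),
        )
    )
    return rules


def filter_by_lift(
    rules: Sequence[AssociationRule], min_lift: float = 1.0
) -> list[AssociationRule]:
    """Keep rules with lift strictly greater than ``min_lift``.

    The default reproduces the pipeline's "lift over 1" selection;
    lift exactly 1 (statistical independence) is dropped.  Input order
    is preserved.
    """
    return [r for r in rules if r.lift > min_lift]


def rules_for_item(
    rules: Sequence[AssociationRule], item: str, side: str = "either"
) -> list[AssociationRule]:
    """Rules whose antecedent / consequent / either side contains ``item``."""
    if side not in ("antecedent", "consequent", "either"):
        raise ValueError(f"side must be antecedent|consequent|either, got {side!r}")
    out = []
    for r in rules:
        in_a = item in r.antecedent
        in_c = item in r.consequent
        keep = {"antecedent": in_a, "consequent": in_c, "either": in_a or in_c}[side]
        if keep:
            out.append(r)
    return out


def mine_rules(
    transactions: Transactions,
    min_support: float = 0.1,
    min_confidence: float = 0.5,
    min_lift: float = 1.0,
    max_len: int | None = 4,
) -> list[AssociationRule]:
    """Frequent itemsets -> rules -> lift filter, in one call.

    ``min_support`` / ``min_confidence`` defaults (0.1 / 0.5) are
    package assumptions and should be set explicitly for real studies;
    ``max_len`` caps total rule length (antecedent + consequent).
    """
    itemsets = frequent_itemsets(transactions, min_support, max_len=max_len)
    rules = generate_rules(itemsets, transactions, min_confidence)
    return filter_by_lift(rules, min_lift)


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Rules as a DataFrame with semicolon-joined itemsets."""
    return pd.DataFrame(
        {
            "antecedent": [";".join(sorted(r.antecedent)) for r in rules],
            "consequent": [";".join(sorted(r.consequent)) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
        }
    )


def write_rules_csv(rules: Sequence[AssociationRule], path: str | Path) -> None:
    rules_to_frame(rules).to_csv(path, index=False)


def read_rules_csv(path: str | Path) -> list[AssociationRule]:
    df = pd.read_csv(path)
    return [
        AssociationRule(
            antecedent=frozenset(str(row.antecedent).split(";")),
            consequent=frozenset(str(row.consequent).split(";")),
            support=float(row.support),
            confidence=float(row.confidence),
            lift=float(row.lift),
        )
        for row in df.itertuples()
    ]
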