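"""Independent oracles and small generators shared across tests.

The brute-force miner enumerates every itemset and every rule
directly from the definitions, with no candidate generation or
pruning, so it is an independent check on the level-wise Apriori
implementation (feasible for <= 8 items).
"""

from __future__ import annotations

import itertools

import numpy as np

from omnirule.apriori import Transactions

ITEM_POOL = list("ABCDEFGH")


def brute_force_itemsets(
    transactions: Transactions, min_support: float
) -> dict[frozenset[str], float]:
    """Support of every itemset meeting min_support, by full enumeration."""
    vocab = sorted(set().union(*transactions.itemsets))
    n = len(transactions)
    out: dict[frozenset[str], float] = {}
    for r in range(1, len(vocab) + 1):
        for combo in itertools.combinations(vocab, r):
            s = frozenset(combo)
            support = sum(1 for t in transactions if s <= t) / n
            if support >= min_support - 1e-12 and support > 0:
                out[s] = support
    return out


def brute_force_rules(
    transactions: Transactions, min_support: float, min_confidence: float
) -> dict[tuple[frozenset[str], frozenset[str]], tuple[float, float, float]]:
    """(antecedent, consequent) -> (support, confidence, lift), enumerated."""
    freq = brute_force_itemsets(transactions, min_support)
    n = len(transactions)

    def supp(s: frozenset[str]) -> float:
        return sum(1 for t in transactions if s <= t) / n

    out = {}
    for z, sz in freq.items():
        if len(z) < 2:
            continue
        items = sorted(z)
        for r in range(1, len(items)):
            for ante in itertools.combinations(items, r):
                a = frozenset(ante)
                c = z - a
                conf = sz / supp(a)
                if conf >= min_confidence - 1e-12:
                    out[(a, c)] = (sz, conf, conf / supp(c))
    return out


def random_transactions(
    rng: np.random.Generator, max_items: int = 8, max_transactions: int = 25
) -> Transactions:
    """A small random basket set with at least one non-empty transaction."""
    n_items = int(rng.integers(3, max_items + 1))
    n_tx = int(rng.integers(4, max_transactions + 1))
    items = ITEM_POOL[:n_items]
    probs = rng.uniform(0.2, 0.7, size=n_items)
    sets = []
    for _ in range(n_tx):
        sets.append(frozenset(i for i, p in zip(items, probs) if rng.random() < p))
    if all(len(s) == 0 for s in sets):
        sets[0] = frozenset(items[:1])
    return Transactions.from_itemsets(sets)
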