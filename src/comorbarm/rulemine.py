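"""Class-association-rule mining with imbalance-aware metrics.

Frequent itemsets are mined per timeframe class with an FP-growth
implementation (prefix tree of item counts, conditional pattern bases, no
candidate generation).  Each surviving antecedent ``A`` is scored against
every class ``c`` with the metric set designed for strongly imbalanced class
sizes:

* ``local support(A -> c) = support(Ac) / support(c)`` — the within-class
  frequency of ``A``, so a single minimum threshold prunes all classes at
  comparable strength;
* ``lift(A -> c) = support(Ac) / (support(A) * support(c))`` — association
  strength insensitive to class share;
* ``exclusiveness(lift)(A -> c_i) = lift(A -> c_i) / sum_j lift(A -> c_j)``
  — a [0, 1] share expressing how specific ``A`` is to one timeframe.

Confidence is computed and reported but never used for pruning.
"""

from __future__ import annotations

import csv
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cohort import CLASS_LABELS, TransactionDB
from .errors import EmptyInputError, ParameterError, UndefinedRuleError


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemsetCount:
    """A frequent itemset with its exact transaction count."""

    items: tuple[str, ...]
    count: int
    scope: str = "global"


@dataclass
class ClassRule:
    """One antecedent -> timeframe rule with the full metric set."""

    antecedent: tuple[str, ...]
    consequent: str
    support: float
    local_support: float
    confidence: float
    lift: float
    excl_lift: float
    lift_vector: dict[str, float] = field(default_factory=dict)


@dataclass
class MiningParams:
    """Mining thresholds and selection parameters."""

    min_local_support: float = 0.03
    antecedent_size: int | None = 1
    top_k: int = 15
    threshold_grid: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)

    def __post_init__(self) -> None:
        if not 0.0 < self.min_local_support <= 1.0:
            raise ParameterError("min_local_support must be in (0, 1]")
        if self.top_k < 1:
            raise ParameterError("top_k must be >= 1")
        if self.antecedent_size is not None and self.antecedent_size < 1:
            raise ParameterError("antecedent_size must be >= 1 or None")
        if any(not 0.0 < t <= 1.0 for t in self.threshold_grid):
            raise ParameterError("threshold grid values must be in (0, 1]")


# ---------------------------------------------------------------------------
# FP-growth
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _Node] = {}


def _build_tree(
    weighted: Sequence[tuple[Sequence[str], int]], min_count: int
) -> tuple[dict[str, list[_Node]], Counter]:
    counts: Counter = Counter()
    for items, w in weighted:
        for item in items:
            counts[item] += w
    # frequent items, heaviest first; ties broken lexicographically for a
    # deterministic tree shape
    rank = {
        item: pos
        for pos, (item, _) in enumerate(
            sorted(
                ((i, c) for i, c in counts.items() if c >= min_count),
                key=lambda ic: (-ic[1], ic[0]),
            )
        )
    }
    root = _Node(None, None)
    header: dict[str, list[_Node]] = defaultdict(list)
    for items, w in weighted:
        path = sorted((i for i in items if i in rank), key=rank.get)
        node = root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = _Node(item, node)
                node.children[item] = child
                header[item].append(child)
            child.count += w
            node = child
    return header, counts


def _mine(
    weighted: Sequence[tuple[Sequence[str], int]],
    min_count: int,
    suffix: frozenset,
    out: dict[frozenset, int],
) -> None:
    header, counts = _build_tree(weighted, min_count)
    for item, nodes in header.items():
        support = counts[item]
        out[suffix | {item}] = support
        base: list[tuple[list[str], int]] = []
        for node in nodes:
            path = []
            p = node.parent
            while p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                base.append((path, node.count))
        if base:
            _mine(base, min_count, suffix | {item}, out)


def fp_growth(
    transactions: Iterable[Iterable[str]], min_count: int
) -> list[ItemsetCount]:
    """All itemsets occurring in at least ``min_count`` transactions.

    Returns every frequent itemset with its exact count, in canonical order
    (by size, then lexicographically).  Equivalent to exhaustive enumeration;
    the prefix-tree recursion merely avoids candidate generation.

    Raises
    ------
    ParameterError
        If ``min_count`` is below 1.
    """
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    weighted = [(tuple(set(t)), 1) for t in transactions]
    found: dict[frozenset, int] = {}
    if weighted:
        _mine(weighted, min_count, frozenset(), found)
    return sorted(
        (
            ItemsetCount(items=tuple(sorted(k)), count=v)
            for k, v in found.items()
        ),
        key=lambda ic: (len(ic.items), ic.items),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def class_supports(db: TransactionDB) -> dict[str, float]:
    """Each class's share of all transactions: the support(c) denominators."""
    total = sum(db.class_sizes.values())
    if total == 0:
        raise EmptyInputError("empty transaction database")
    return {c: n / total for c, n in db.class_sizes.items()}


class _TxIndex:
    """Inverted index: (class, item) -> set of transaction row ids."""

    def __init__(self, db: TransactionDB):
        self.n_total = len(db.transactions)
        self.class_sizes = dict(db.class_sizes)
        self.postings: dict[str, dict[str, set[int]]] = {
            c: defaultdict(set) for c in self.class_sizes
        }
        for row, t in enumerate(db.transactions):
            post = self.postings[t.timeframe]
            for item in t.items:
                post[item].add(row)

    def class_count(self, items: Sequence[str], label: str) -> int:
        post = self.postings.get(label)
        if post is None:
            return 0
        sets = [post.get(i) for i in items]
        if any(s is None for s in sets):
            return 0
        sets.sort(key=len)
        acc = sets[0]
        for s in sets[1:]:
            acc = acc & s
            if not acc:
                return 0
        return len(acc)


def score_rule(
    antecedent: Sequence[str],
    db: TransactionDB,
    index: _TxIndex | None = None,
) -> dict[str, ClassRule]:
    """Score one antecedent itemset against every timeframe class.

    Returns a rule per class sharing a common ``lift_vector``; classes where
    the antecedent never occurs get lift 0 and still sit in the exclusiveness
    denominator (absence is informative).

    Raises
    ------
    UndefinedRuleError
        If the antecedent occurs in no transaction at all (support 0), which
        also makes the exclusiveness denominator vanish.
    """
    items = tuple(sorted(set(antecedent)))
    if not items:
        raise UndefinedRuleError("empty antecedent")
    if index is None:
        index = _TxIndex(db)
    n_total = index.n_total
    if n_total == 0:
        raise EmptyInputError("empty transaction database")

    class_counts = {c: index.class_count(items, c) for c in index.class_sizes}
    count_a = sum(class_counts.values())
    if count_a == 0:
        raise UndefinedRuleError(f"antecedent {items} has zero support")

    support_a = count_a / n_total
    lift_vector: dict[str, float] = {}
    for c, n_c in index.class_sizes.items():
        support_ac = class_counts[c] / n_total
        support_c = n_c / n_total
        lift_vector[c] = support_ac / (support_a * support_c)
    lift_sum = sum(lift_vector.values())
    if lift_sum == 0:
        raise UndefinedRuleError(f"zero lift sum for antecedent {items}")

    rules: dict[str, ClassRule] = {}
    for c, n_c in index.class_sizes.items():
        count_ac = class_counts[c]
        rules[c] = ClassRule(
            antecedent=items,
            consequent=c,
            support=count_ac / n_total,
            local_support=count_ac / n_c,
            confidence=count_ac / count_a,
            lift=lift_vector[c],
            excl_lift=lift_vector[c] / lift_sum,
            lift_vector=lift_vector,
        )
    return rules


def mine_class_rules(
    db: TransactionDB, params: MiningParams | None = None
) -> list[ClassRule]:
    """Mine class rules: per-class FP-growth at the local-support threshold.

    For each class ``c`` the frequent itemsets of the class partition are
    mined with ``min_count = ceil(min_local_support * class_size(c))`` — the
    ceiling makes the fractional criterion exact at the boundary — and every
    survivor is scored against all classes; the rule with consequent ``c`` is
    kept when its local support clears the threshold.
    """
    params = params or MiningParams()
    if not db.transactions:
        raise EmptyInputError("empty transaction database")
    index = _TxIndex(db)
    rules: list[ClassRule] = []
    for label in CLASS_LABELS:
        n_c = db.class_sizes.get(label, 0)
        if n_c == 0:
            continue
        min_count = math.ceil(params.min_local_support * n_c)
        class_tx = [t.items for t in db.transactions if t.timeframe == label]
        for itemset in fp_growth(class_tx, max(min_count, 1)):
            rule = score_rule(itemset.items, db, index)[label]
            if rule.local_support >= params.min_local_support - 1e-12:
                rules.append(rule)
    return rules


def filter_and_rank(
    rules: Sequence[ClassRule], params: MiningParams | None = None
) -> dict[str, list[ClassRule]]:
    """Apply the antecedent-size filter and the per-class top-k ranking.

    Rules are sorted by lift descending (tie-break: antecedent codes
    ascending, for run-to-run stability) and truncated to exactly ``top_k``
    rows — no tie expansion, unlike the network node selection.
    """
    params = params or MiningParams()
    out: dict[str, list[ClassRule]] = {}
    for label in CLASS_LABELS:
        pool = [
            r
            for r in rules
            if r.consequent == label
            and (
                params.antecedent_size is None
                or len(r.antecedent) == params.antecedent_size
            )
        ]
        pool.sort(key=lambda r: (-r.lift, r.antecedent))
        out[label] = pool[: params.top_k]
    return out


def threshold_grid_counts(
    db: TransactionDB, params: MiningParams | None = None
) -> dict[str, dict[float, int]]:
    """Rule counts per class across the local-support threshold grid.

    Counts are of size-filtered rules (the shape reported per class per
    threshold); they are non-increasing along an increasing grid.  Mining runs
    once at the smallest threshold; higher thresholds are counted by
    filtering, which is exact because a rule frequent at ``t`` is frequent at
    every ``t' <= t``.
    """
    params = params or MiningParams()
    grid = sorted(params.threshold_grid)
    if not grid:
        raise ParameterError("threshold grid must be non-empty")
    base_params = MiningParams(
        min_local_support=grid[0],
        antecedent_size=params.antecedent_size,
        top_k=params.top_k,
        threshold_grid=params.threshold_grid,
    )
    mined = mine_class_rules(db, base_params)
    sized = [
        r
        for r in mined
        if params.antecedent_size is None
        or len(r.antecedent) == params.antecedent_size
    ]
    table: dict[str, dict[float, int]] = {}
    for label in CLASS_LABELS:
        if label not in db.class_sizes:
            continue
        row = {}
        for t in grid:
            row[t] = sum(
                1
                for r in sized
                if r.consequent == label and r.local_support >= t - 1e-12
            )
        table[label] = row
    return table


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_RULE_FIELDS = [
    "class",
    "antecedent",
    "local_support",
    "confidence",
    "lift",
    "excl_lift",
]


def write_rules_csv(rules: Iterable[ClassRule], path) -> None:
    """Rule table in the per-timeframe layout (6-decimal fixed point)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_RULE_FIELDS)
        writer.writeheader()
        for r in rules:
            writer.writerow(
                {
                    "class": r.consequent,
                    "antecedent": ";".join(r.antecedent),
                    "local_support": f"{r.local_support:.6f}",
                    "confidence": f"{r.confidence:.6f}",
                    "lift": f"{r.lift:.6f}",
                    "excl_lift": f"{r.excl_lift:.6f}",
                }
            )


def read_rules_csv(path) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [
            {
                "class": row["class"],
                "antecedent": tuple(row["antecedent"].split(";")),
                "local_support": float(row["local_support"]),
                "confidence": float(row["confidence"]),
                "lift": float(row["lift"]),
                "excl_lift": float(row["excl_lift"]),
            }
            for row in csv.DictReader(fh)
        ]
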