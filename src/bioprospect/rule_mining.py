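"""Frequent-itemset mining and association-rule screening.

Rules have the fixed form X ⇒ {anticancer} with X drawn from taxonomy and
nature items.  Support, confidence and lift are kept as exact integer-count
ratios (``fractions.Fraction``) and only rounded at formatting time, so the
strict threshold screens (support > min_support, confidence > min_confidence,
lift > min_lift) are free of float artifacts.

Definitions, for a database of n transactions with n_x containing X, n_y
containing the consequent and n_xy containing both:

    support    = n_xy / n
    confidence = n_xy / n_x
    lift       = confidence / (n_y / n)

Mining is level-wise apriori with anti-monotone pruning; a brute-force
enumerator with an identical output contract serves as the testing oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP, localcontext
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from .transactions import AA_ITEM, Item, TransactionSet, item_count


def _to_fraction(x: float | int | str | Fraction) -> Fraction:
    """Exact decimal reading of a threshold (0.005 means 5/1000, not the float)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True, slots=True)
class MiningParams:
    """Screening thresholds; all comparisons are strict (>)."""

    min_support: float | Fraction = Fraction(5, 1000)
    min_confidence: float | Fraction = Fraction(50, 100)
    min_lift: float | Fraction = Fraction(2)
    max_antecedent_len: int = 2

    def __post_init__(self) -> None:
        for name in ("min_support", "min_confidence", "min_lift"):
            if _to_fraction(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_antecedent_len < 1:
            raise ValueError("max_antecedent_len must be >= 1")


@dataclass(frozen=True, slots=True)
class AssociationRule:
    """A screened rule X ⇒ {anticancer} with its exact counts."""

    antecedent: frozenset
    n_xy: int
    n_x: int
    n_y: int
    n: int

    def __post_init__(self) -> None:
        if AA_ITEM in self.antecedent or not self.antecedent:
            raise ValueError("antecedent must be nonempty and exclude the consequent")
        if not (self.n_xy <= min(self.n_x, self.n_y) <= self.n):
            raise ValueError("inconsistent counts")

    @property
    def consequent(self) -> frozenset:
        return frozenset({AA_ITEM})

    @property
    def support(self) -> Fraction:
        return Fraction(self.n_xy, self.n)

    @property
    def confidence(self) -> Fraction:
        return Fraction(self.n_xy, self.n_x)

    @property
    def lift(self) -> Fraction:
        return self.confidence / Fraction(self.n_y, self.n)


def mine_frequent_itemsets(
    ts: TransactionSet,
    min_support: float | Fraction = Fraction(5, 1000),
    max_len: int = 3,
) -> list[tuple[frozenset, int]]:
    """All itemsets of size <= max_len with support strictly above min_support.

    Level-wise generation: candidates of size k are joins of frequent
    (k-1)-sets and are pruned unless every (k-1)-subset is frequent, which is
    sound because support is anti-monotone.  Output is sorted by
    (size, lexicographic items) and carries exact counts.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if ts.n == 0:
        raise ValueError("empty transaction set")
    minsup = _to_fraction(min_support)
    n = ts.n

    def frequent(count: int) -> bool:
        return Fraction(count, n) > minsup

    counts_1: dict[Item, int] = {}
    for t in ts.transactions:
        for item in t:
            counts_1[item] = counts_1.get(item, 0) + 1
    level: dict[frozenset, int] = {
        frozenset({i}): c for i, c in counts_1.items() if frequent(c)
    }
    out: dict[frozenset, int] = dict(level)

    k = 2
    while level and k <= max_len:
        prev = set(level)
        # join step on sorted-tuple prefixes
        keys = sorted(tuple(sorted(s)) for s in level)
        candidates: set[frozenset] = set()
        for a, b in itertools.combinations(keys, 2):
            if a[:-1] == b[:-1]:
                cand = frozenset(a) | frozenset(b)
                if all(
                    frozenset(sub) in prev
                    for sub in itertools.combinations(sorted(cand), k - 1)
                ):
                    candidates.add(cand)
        level = {}
        for cand in candidates:
            c = item_count(ts, cand)
            if frequent(c):
                level[cand] = c
        out.update(level)
        k += 1

    return sorted(out.items(), key=lambda kv: (len(kv[0]), tuple(sorted(kv[0]))))


def _rule_sort_key(rule: AssociationRule):
    return (len(rule.antecedent), -rule.confidence, tuple(sorted(rule.antecedent)))


def generate_rules(
    ts: TransactionSet, params: MiningParams = MiningParams()
) -> list[AssociationRule]:
    """Mine and screen rules X ⇒ {anticancer} via apriori.

    Frequent itemsets containing the consequent are mined at the support
    threshold up to size max_antecedent_len + 1; each yields the candidate
    rule with antecedent X = itemset \\ {anticancer}, whose n_x is read off
    the (necessarily frequent) subset.  All three screens are strict.
    """
    n_y = item_count(ts, {AA_ITEM})
    if n_y == 0:
        raise ValueError("consequent never occurs; lift is undefined")
    min_conf = _to_fraction(params.min_confidence)
    min_lift = _to_fraction(params.min_lift)

    frequent = dict(
        mine_frequent_itemsets(
            ts, params.min_support, params.max_antecedent_len + 1
        )
    )
    rules: list[AssociationRule] = []
    for itemset, n_xy in frequent.items():
        if AA_ITEM not in itemset or len(itemset) == 1:
            continue
        antecedent = itemset - {AA_ITEM}
        n_x = frequent.get(antecedent)
        if n_x is None:  # antecedent below support threshold: recount directly
            n_x = item_count(ts, antecedent)
        rule = AssociationRule(
            antecedent=antecedent, n_xy=n_xy, n_x=n_x, n_y=n_y, n=ts.n
        )
        if rule.confidence > min_conf and rule.lift > min_lift:
            rules.append(rule)
    return sorted(rules, key=_rule_sort_key)


def brute_force_rules(
    ts: TransactionSet,
    params: MiningParams = MiningParams(),
    max_universe: int = 25,
) -> list[AssociationRule]:
    """Testing oracle: enumerate every antecedent over the item universe.

    Counts each candidate directly and applies the same strict screens;
    output contract identical to :func:`generate_rules`.  Guarded to small
    item universes since enumeration is exponential in max_antecedent_len.
    """
    universe = sorted(ts.universe() - {AA_ITEM})
    if len(universe) > max_universe:
        raise ValueError(
            f"item universe of {len(universe)} exceeds brute-force guard "
            f"({max_universe})"
        )
    n_y = item_count(ts, {AA_ITEM})
    if n_y == 0:
        raise ValueError("consequent never occurs; lift is undefined")
    minsup = _to_fraction(params.min_support)
    min_conf = _to_fraction(params.min_confidence)
    min_lift = _to_fraction(params.min_lift)

    rules: list[AssociationRule] = []
    for size in range(1, params.max_antecedent_len + 1):
        for combo in itertools.combinations(universe, size):
            antecedent = frozenset(combo)
            n_x = item_count(ts, antecedent)
            if n_x == 0:
                continue
            n_xy = item_count(ts, antecedent | {AA_ITEM})
            rule = AssociationRule(
                antecedent=antecedent, n_xy=n_xy, n_x=n_x, n_y=n_y, n=ts.n
            )
            if (
                rule.support > minsup
                and rule.confidence > min_conf
                and rule.lift > min_lift
            ):
                rules.append(rule)
    return sorted(rules, key=_rule_sort_key)


def round_half_up(x: Fraction, dp: int = 2) -> Decimal:
    """Round an exact fraction half-up to dp decimal places."""
    with localcontext() as ctx:
        ctx.prec = 50
        d = Decimal(x.numerator) / Decimal(x.denominator)
        return d.quantize(Decimal(1).scaleb(-dp), rounding=ROUND_HALF_UP)


def format_pct(x: Fraction, dp: int = 2, sign: bool = True) -> str:
    """Format a fraction as a percentage, half-up at dp decimals."""
    s = str(round_half_up(x * 100, dp))
    return s + "%" if sign else s


def format_rule(rule: AssociationRule) -> dict[str, str]:
    antecedent = "{" + ", ".join(sorted(rule.antecedent)) + "}"
    return {
        "rule": f"{antecedent}=>{{{AA_ITEM}}}",
        "support": format_pct(rule.support),
        "confidence": format_pct(rule.confidence),
        "lift": str(round_half_up(rule.lift)),
    }


def format_rule_table(rules: Sequence[AssociationRule]) -> list[dict[str, str]]:
    """Render rules the way the screened-rule table is printed: percentages
    at 2 dp with a % sign, lift at 2 dp, rounding applied only here."""
    return [format_rule(r) for r in rules]


def write_rule_table(rules: Sequence[AssociationRule], path: str | Path) -> None:
    """Tab-separated export with both formatted metrics and raw counts."""
    header = "antecedent\tconsequent\tn_x\tn_xy\tsupport_pct\tconfidence_pct\tlift\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for r in rules:
            fh.write(
                "\t".join(
                    [
                        ", ".join(sorted(r.antecedent)),
                        AA_ITEM,
                        str(r.n_x),
                        str(r.n_xy),
                        format_pct(r.support, sign=False),
                        format_pct(r.confidence, sign=False),
                        str(round_half_up(r.lift)),
                    ]
                )
                + "\n"
            )
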