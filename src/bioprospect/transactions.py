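"""Itemset encoding of species records.

Each species becomes one transaction over the item universe
``{rank:taxon, nature:label, anticancer}``.  Items are canonical strings:
``"kingdom:Metazoa"``, ``"nature:cold"``, and the bare consequent token
``"anticancer"``.  Species with nature "none" emit no nature item — they can
never appear in a nature antecedent but still count in every denominator,
which is the convention that reproduces the published supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .data_model import Dataset, RANKS, SpeciesRecord

#: The consequent item: reported anticancer activity.
AA_ITEM = "anticancer"

Item = str
Transaction = frozenset


def make_item(namespace: str, value: str) -> Item:
    """Canonical string form of an item, e.g. ``make_item("genus", "Sargassum")``."""
    if namespace == "aa":
        return AA_ITEM
    if namespace not in (*RANKS, "nature"):
        raise ValueError(f"unknown item namespace {namespace!r}")
    return f"{namespace}:{value}"


@dataclass(slots=True)
class TransactionSet:
    """The transaction database D: one itemset per species, order preserved."""

    transactions: list[Transaction] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.transactions)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[Transaction]:
        return iter(self.transactions)

    def universe(self) -> set[Item]:
        out: set[Item] = set()
        for t in self.transactions:
            out |= t
        return out


def encode_record(
    rec: SpeciesRecord,
    ranks: Sequence[str] = RANKS,
    include_nature: bool = True,
) -> Transaction:
    items = {
        f"{r}:{rec.lineage[r]}" for r in ranks if r in rec.lineage
    }
    if include_nature and rec.nature != "none":
        items.add(f"nature:{rec.nature}")
    if rec.aa:
        items.add(AA_ITEM)
    return frozenset(items)


def encode_transactions(
    ds: Dataset,
    ranks: Sequence[str] = RANKS,
    include_nature: bool = True,
) -> TransactionSet:
    """Encode a dataset as the transaction database for rule mining."""
    if len(ds) == 0:
        raise ValueError("cannot encode an empty dataset")
    bad = set(ranks) - set(RANKS)
    if bad:
        raise ValueError(f"unknown ranks {sorted(bad)}")
    return TransactionSet(
        [encode_record(rec, ranks, include_nature) for rec in ds]
    )


def decode_transaction(t: Transaction) -> tuple[dict[str, str], str, bool]:
    """Recover (lineage-at-encoded-ranks, nature, aa) from a transaction.

    The inverse of :func:`encode_record` up to the "none" convention: a
    transaction without a nature item decodes to nature "none".
    """
    lineage: dict[str, str] = {}
    nature = "none"
    aa = False
    for item in t:
        if item == AA_ITEM:
            aa = True
            continue
        namespace, _, value = item.partition(":")
        if namespace == "nature":
            nature = value
        else:
            lineage[namespace] = value
    return lineage, nature, aa


def item_count(ts: TransactionSet, itemset: Iterable[Item]) -> int:
    """Number of transactions containing every item of ``itemset``.

    The empty itemset is contained in every transaction, so
    ``item_count(ts, ()) == ts.n``.
    """
    needed = frozenset(itemset)
    return sum(1 for t in ts.transactions if needed <= t)


def write_basket(ts: TransactionSet, path: str | Path) -> None:
    """Export one transaction per line, items space-separated and sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in ts.transactions:
            fh.write(" ".join(sorted(t)) + "\n")
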