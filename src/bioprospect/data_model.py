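"""Domain types and I/O for marine-species trait tables.

The unit of analysis is the *species*: one record per Latin binomial carrying
a partial NCBI-style taxonomic lineage (superkingdom … genus), a traditional
cold/hot/neutral "nature" label, and a binary anticancer-activity (AA) flag
derived from literature reports.  A medicinal preparation may comprise several
species; preparation identity is deliberately not modelled because every
downstream statistic is species-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

#: Canonical ranks, outermost first.  Lineages are maps from a subset of
#: these ranks to taxon names; ranks not applicable to an organism are absent.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
)

#: Allowed nature labels.  "none" encodes the absence of a recorded nature;
#: such species still count in every denominator.
NATURES: tuple[str, ...] = ("cold", "hot", "neutral", "none")

#: Fixed column layout of the tab-separated species table.
TABLE_COLUMNS: tuple[str, ...] = ("latin_name", *RANKS, "nature", "aa")

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


class SchemaError(ValueError):
    """A species table is missing a mandatory column."""


class DuplicateSpeciesError(ValueError):
    """The same Latin name appears more than once in a dataset."""


@dataclass(frozen=True, slots=True)
class SpeciesRecord:
    """One marine organism with its lineage, nature label, and AA flag."""

    latin_name: str
    lineage: Mapping[str, str] = field(default_factory=dict)
    nature: str = "none"
    aa: bool = False

    def __post_init__(self) -> None:
        if not self.latin_name:
            raise ValueError("latin_name must be nonempty")
        if self.nature not in NATURES:
            raise ValueError(
                f"nature must be one of {NATURES}, got {self.nature!r}"
            )
        for rank, taxon in self.lineage.items():
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r}")
            if not taxon:
                raise ValueError(f"empty taxon name at rank {rank!r}")
        # freeze the lineage so records are safely hashable/shareable
        object.__setattr__(self, "lineage", dict(self.lineage))

    def with_nature(self, nature: str) -> "SpeciesRecord":
        return replace(self, nature=nature)


@dataclass(slots=True)
class Dataset:
    """An ordered collection of unique species records (the database D)."""

    records: list[SpeciesRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.latin_name in seen:
                raise DuplicateSpeciesError(
                    f"duplicate species {rec.latin_name!r}"
                )
            seen.add(rec.latin_name)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.records == other.records

    @property
    def n_aa(self) -> int:
        return sum(r.aa for r in self.records)


def _parse_aa(token: str, row: int) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise ValueError(f"row {row}: unparseable aa value {token!r}")


def _parse_nature(token: str, row: int) -> str:
    low = token.strip().lower()
    if low == "":
        return "none"
    if low not in NATURES:
        raise ValueError(f"row {row}: unparseable nature value {token!r}")
    return low


def read_species_table(path: str | Path, *, sep: str = "\t") -> Dataset:
    """Read a species trait table into a :class:`Dataset`.

    The header must name at least ``latin_name``, ``nature``, ``aa`` and one
    rank column; columns are recognized by name, not position, and extra
    columns are ignored.  Empty lineage cells become absent ranks.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    present_ranks = [r for r in RANKS if r in frame.columns]
    for col in ("latin_name", "nature", "aa"):
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    if not present_ranks:
        raise SchemaError("missing mandatory column: at least one rank")

    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row_map = dict(zip(frame.columns, row))
        name = row_map["latin_name"].strip()
        if not name:
            raise ValueError(f"row {i}: empty latin_name")
        if name in seen:
            raise DuplicateSpeciesError(
                f"row {i}: duplicate species {name!r}"
            )
        seen.add(name)
        lineage = {
            r: row_map[r].strip()
            for r in present_ranks
            if row_map[r].strip()
        }
        records.append(
            SpeciesRecord(
                latin_name=name,
                lineage=lineage,
                nature=_parse_nature(row_map["nature"], i),
                aa=_parse_aa(row_map["aa"], i),
            )
        )
    return Dataset(records=records, provenance=str(path))


def write_species_table(ds: Dataset, path: str | Path, *, sep: str = "\t") -> None:
    """Write a dataset as a tab-separated table; round-trips via the reader."""
    rows = []
    for rec in ds:
        row = {"latin_name": rec.latin_name}
        for r in RANKS:
            row[r] = rec.lineage.get(r, "")
        row["nature"] = rec.nature
        row["aa"] = "1" if rec.aa else "0"
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    frame.to_csv(path, sep=sep, index=False)


def build_pubmed_query(latin_name: str) -> str:
    """Format the PubMed retrieval string used to flag anticancer reports.

    Reproduces the original formula verbatim, including the historical
    misspelling "antitumer" alongside "antitumor".  No query is executed;
    AA flags are inputs to this package.
    """
    if not latin_name:
        raise ValueError("latin_name must be nonempty")
    return (
        f'"{latin_name}" [All Fields] AND (anticancer [All Fields] '
        "OR antitumer [All Fields] OR antitumor [All Fields])"
    )
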