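"""Rank-wise trait distribution tables and AA cluster statistics.

Distribution tables report, per group (a taxon at one rank, or a nature
label), the species count, its percentage of the whole dataset, the AA
species count, and the AA percentage *within the group* — the two-denominator
layout of the published kingdom and nature tables.  Percentages are kept as
exact fractions and rounded half-up to 2 dp only when formatted.

An "AA cluster" is a maximal run of consecutive AA-positive leaves in the
taxonomy tree's deterministic leaf order — a formalization of how enriched
clades appear as contiguous shaded arcs in circular tree figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from .data_model import Dataset, RANKS
from .rule_mining import format_pct
from .taxonomy import TaxonomyNode, annotate, leaf_order


@dataclass(frozen=True, slots=True)
class DistributionRow:
    """One group's counts; percentages are exact fractions until formatted."""

    group: str
    n: int
    pct_of_total: Fraction
    n_aa: int
    pct_aa_of_group: Fraction

    def formatted(self, sign: bool = True) -> dict[str, str]:
        return {
            "group": self.group,
            "n": str(self.n),
            "pct_of_total": format_pct(self.pct_of_total, sign=sign),
            "n_aa": str(self.n_aa),
            "pct_aa_of_group": format_pct(self.pct_aa_of_group, sign=sign),
        }


@dataclass(frozen=True, slots=True)
class ClusterSummary:
    """Run statistics of AA-positive leaves at one rank."""

    rank: str
    n_positive: int
    n_clusters: int


def _rows_from_groups(
    groups: Mapping[str, list], total_n: int, total_aa: int
) -> list[DistributionRow]:
    rows = [
        DistributionRow(
            group=g,
            n=len(members),
            pct_of_total=Fraction(len(members), total_n),
            n_aa=sum(m.aa for m in members),
            pct_aa_of_group=(
                Fraction(sum(m.aa for m in members), len(members))
                if members
                else Fraction(0)
            ),
        )
        for g, members in groups.items()
    ]
    rows.append(
        DistributionRow(
            group="Total",
            n=total_n,
            pct_of_total=Fraction(1),
            n_aa=total_aa,
            pct_aa_of_group=Fraction(total_aa, total_n),
        )
    )
    return rows


def _sorted_body(rows: list[DistributionRow]) -> list[DistributionRow]:
    body = [r for r in rows if r.group != "Total"]
    total = [r for r in rows if r.group == "Total"]
    body.sort(key=lambda r: (-r.n, r.group))
    return body + total


def distribution_table(ds: Dataset, group_by: str) -> list[DistributionRow]:
    """Distribution of species and AA species across one rank or the nature.

    ``group_by`` is one of the seven canonical ranks or ``"nature"``.
    Species lacking the rank fall into an "Unassigned" group; nature "none"
    appears as group "None".  Rows are ordered by descending count then
    name, with a Total row last.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    if group_by != "nature" and group_by not in RANKS:
        raise ValueError(f"unknown group_by {group_by!r}")

    groups: dict[str, list] = {}
    for rec in ds:
        if group_by == "nature":
            g = rec.nature.capitalize()
        else:
            g = rec.lineage.get(group_by, "Unassigned")
        groups.setdefault(g, []).append(rec)
    return _sorted_body(_rows_from_groups(groups, len(ds), ds.n_aa))


#: Default report-group routing for the kingdom-level rollup: Metazoa and
#: Viridiplantae by kingdom, Bacteria by superkingdom.
DEFAULT_KINGDOM_MAP: dict[str, str] = {
    "Metazoa": "Metazoa",
    "Viridiplantae": "Viridiplantae",
    "Bacteria": "Bacteria",
}

_ROLLUP_ORDER = (
    "Metazoa",
    "Viridiplantae",
    "Others in Eukaryota",
    "Bacteria",
    "Unassigned",
)


def kingdom_rollup(
    ds: Dataset, kingdom_map: Mapping[str, str] | None = None
) -> list[DistributionRow]:
    """The 4-group kingdom/superkingdom rollup of the published headline table.

    Eukaryota species whose kingdom routes to no report group fall into
    "Others in Eukaryota"; anything else unmatched is kept in an
    "Unassigned" row rather than dropped.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    kmap = dict(DEFAULT_KINGDOM_MAP if kingdom_map is None else kingdom_map)
    groups: dict[str, list] = {}
    for rec in ds:
        group = kmap.get(rec.lineage.get("kingdom", ""))
        if group is None:
            group = kmap.get(rec.lineage.get("superkingdom", ""))
        if group is None:
            if rec.lineage.get("superkingdom") == "Eukaryota":
                group = "Others in Eukaryota"
            else:
                group = "Unassigned"
        groups.setdefault(group, []).append(rec)
    rows = _rows_from_groups(groups, len(ds), ds.n_aa)
    order = {g: i for i, g in enumerate(_ROLLUP_ORDER)}
    body = [r for r in rows if r.group != "Total"]
    body.sort(key=lambda r: (order.get(r.group, len(order)), r.group))
    return body + [r for r in rows if r.group == "Total"]


def count_runs(pattern: Sequence[bool]) -> int:
    """Number of maximal runs of True values."""
    runs = 0
    prev = False
    for flag in pattern:
        if flag and not prev:
            runs += 1
        prev = flag
    return runs


def count_aa_clusters(
    root: TaxonomyNode, ds: Dataset, rank: str
) -> ClusterSummary:
    """Count maximal runs of AA-positive leaves along the tree's leaf order.

    The tree must have been built from ``ds`` at ``rank`` (leaves are taxa
    of that rank, or species for rank "species"); a leaf is positive when
    any member species has AA, matching the annotation aggregation.
    """
    if rank != "species" and rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    leaf_ranks = {leaf.rank for leaf in root.leaves()}
    if rank not in leaf_ranks:
        raise ValueError(f"tree has no leaves at rank {rank!r}")
    layer = annotate(root, ds)
    pattern = [layer[leaf].aa for leaf in leaf_order(root)]
    return ClusterSummary(
        rank=rank,
        n_positive=sum(pattern),
        n_clusters=count_runs(pattern),
    )


def write_distribution_table(
    rows: Sequence[DistributionRow], path: str | Path, sign: bool = True
) -> None:
    """Tab-separated export mirroring the published two-denominator layout."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "group\tn\tpct_of_total\tn_aa\tpct_aa_of_group\n"
        )
        for row in rows:
            f = row.formatted(sign=sign)
            fh.write(
                "\t".join(
                    [f["group"], f["n"], f["pct_of_total"], f["n_aa"],
                     f["pct_aa_of_group"]]
                )
                + "\n"
            )
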