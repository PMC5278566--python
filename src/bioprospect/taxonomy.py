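"""Rank-structured taxonomy trees built from lineage labels.

The tree is taxonomy-derived, not sequence-based: root → superkingdom → … →
genus → species, with absent ranks collapsed so a child attaches to its
nearest present ancestor.  There are no meaningful branch lengths.  Children
are kept lexicographically sorted, which makes the tree, its Newick export
and its leaf order deterministic and invariant under input permutation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .data_model import Dataset, RANKS, SpeciesRecord


class AmbiguousTaxonError(ValueError):
    """The same taxon name occurs under two different parents (homonym)."""


@dataclass(slots=True)
class TaxonomyNode:
    """A taxon (internal) or terminal group (leaf) in the taxonomy tree.

    A node is a leaf iff it carries member species iff it has no children.
    """

    name: str
    rank: str
    children: list["TaxonomyNode"] = field(default_factory=list)
    species: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TaxonomyNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> Iterator["TaxonomyNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def _sort(self) -> None:
        self.children.sort(key=lambda c: c.name)
        self.species.sort()
        for child in self.children:
            child._sort()


def _record_path(rec: SpeciesRecord, leaf_rank: str) -> list[tuple[str, str]]:
    if leaf_rank == "species":
        use = RANKS
    else:
        use = RANKS[: RANKS.index(leaf_rank) + 1]
    path = [(r, rec.lineage[r]) for r in use if r in rec.lineage]
    if leaf_rank == "species":
        path.append(("species", rec.latin_name))
    return path


def build_tree(ds: Dataset, leaf_rank: str = "species") -> TaxonomyNode:
    """Build the taxonomy tree of a dataset down to ``leaf_rank``.

    With ``leaf_rank="species"`` every species is its own leaf; at a higher
    rank (e.g. "family") species aggregate under the taxon of that rank.  A
    species whose lineage stops above the leaf rank attaches to its deepest
    present taxon; if that taxon also has subordinate taxa, the species goes
    to a synthetic "<taxon> incertae sedis" leaf so that species only ever
    live at leaves.  Homonymous taxa (one name under two parents) are an
    error rather than a silent merge.
    """
    if len(ds) == 0:
        raise ValueError("cannot build a tree from an empty dataset")
    if leaf_rank != "species" and leaf_rank not in RANKS:
        raise ValueError(f"unknown leaf rank {leaf_rank!r}")

    root = TaxonomyNode(name="root", rank="root")
    index: dict[tuple[int, str], TaxonomyNode] = {}
    parent_of: dict[str, str] = {}

    def child(parent: TaxonomyNode, name: str, rank: str) -> TaxonomyNode:
        key = (id(parent), name)
        node = index.get(key)
        if node is None:
            if name in parent_of and parent_of[name] != parent.name:
                raise AmbiguousTaxonError(
                    f"taxon {name!r} occurs under both "
                    f"{parent_of[name]!r} and {parent.name!r}"
                )
            parent_of[name] = parent.name
            node = TaxonomyNode(name=name, rank=rank)
            parent.children.append(node)
            index[key] = node
        return node

    # pass 1: internal skeleton from all paths
    paths = {rec.latin_name: _record_path(rec, leaf_rank) for rec in ds}
    for path in paths.values():
        node = root
        for rank, name in path:
            node = child(node, name, rank)

    # pass 2: attach species at leaves only
    for rec in ds:
        node = root
        for rank, name in paths[rec.latin_name]:
            node = index[(id(node), name)]
        if node.children:
            node = child(node, f"{node.name} incertae sedis", node.rank)
        node.species.append(rec.latin_name)

    root._sort()
    return root


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]':;,]")


def _newick_label(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick(node: TaxonomyNode) -> str:
    if node.is_leaf:
        return _newick_label(node.name)
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}){_newick_label(node.name)}"


def to_newick(root: TaxonomyNode) -> str:
    """Newick string with internal node labels and no branch lengths."""
    return _newick(root) + ";"


def write_newick(root: TaxonomyNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(root) + "\n", encoding="utf-8")


def leaf_order(root: TaxonomyNode) -> list[str]:
    """Deterministic leaf ordering: depth-first, children lexicographic.

    This is the ordering the cluster statistics are defined on; equal trees
    always give equal orders.
    """
    return [leaf.name for leaf in root.leaves()]


@dataclass(slots=True)
class LeafAnnotation:
    aa: bool
    nature: str
    bar_value: int


@dataclass(slots=True)
class AnnotationLayer:
    """Per-leaf display layer: AA flag, modal nature, member-count bar."""

    values: dict[str, LeafAnnotation] = field(default_factory=dict)

    def __getitem__(self, leaf: str) -> LeafAnnotation:
        return self.values[leaf]


def annotate(root: TaxonomyNode, ds: Dataset) -> AnnotationLayer:
    """Annotate each leaf of a tree built from ``ds``.

    Aggregated leaves are flagged AA when any member species is AA (the
    convention used to shade whole families in circular-tree figures); the
    nature shown is the modal label among members, ties broken
    lexicographically; the bar value is the member count.
    """
    by_name: Mapping[str, SpeciesRecord] = {r.latin_name: r for r in ds}
    layer = AnnotationLayer()
    for leaf in root.leaves():
        members = [by_name[s] for s in leaf.species]
        if not members:
            raise ValueError(f"leaf {leaf.name!r} has no member species")
        natures = Counter(m.nature for m in members)
        top = max(natures.items(), key=lambda kv: (kv[1], kv[0]))
        modal = min(
            (lbl for lbl, c in natures.items() if c == top[1]),
        )
        layer.values[leaf.name] = LeafAnnotation(
            aa=any(m.aa for m in members),
            nature=modal,
            bar_value=len(members),
        )
    return layer


def write_annotation(layer: AnnotationLayer, path: str | Path) -> None:
    """Tab-separated (leaf, aa, nature, bar_value) loadable by tree viewers."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("leaf\taa\tnature\tbar_value\n")
        for leaf, ann in layer.values.items():
            fh.write(
                f"{leaf}\t{int(ann.aa)}\t{ann.nature}\t{ann.bar_value}\n"
            )
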