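"""Synthetic species tables: simulation and marginal-exact fixture building.

Two generators live here.

:func:`simulate_dataset` draws datasets with the statistical structure the
analysis assumes — a multi-rank taxonomy with uneven clade sizes, an i.i.d.
categorical nature trait, and a binary anticancer-activity (AA) trait with a
baseline prevalence plus planted enrichment inside designated clades or
nature groups.  It is the ground-truth source for parameter-recovery tests.

:func:`build_fixture` solves the inverse problem: given a system of marginal
constraints — "this taxon has n species, k of them AA", "this nature label
has n species, k AA", "this taxon ∧ nature combination has n/k" — it
constructs a concrete dataset that satisfies every constraint *exactly*,
verified by an independent counting pass.  :func:`materia_medica_fixture`
instantiates it with the marginal counts reported for the 1,091-species
Chinese Marine Materia Medica collection, so every downstream table and every
screened association rule is exactly reproducible without the (undeposited)
original species list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .data_model import Dataset, NATURES, RANKS, SpeciesRecord


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class FeasibilityError(ValueError):
    """The marginal constraint system admits no dataset."""


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------


@dataclass(slots=True)
class PlantedEffect:
    """Override of the AA probability inside the species matching ``condition``.

    ``condition`` is an itemset over rank/nature items, e.g.
    ``{"family:F", "nature:cold"}``; the last matching effect wins.
    """

    condition: frozenset
    aa_prob: float

    def matches(self, lineage: Mapping[str, str], nature: str) -> bool:
        for item in self.condition:
            namespace, _, value = item.partition(":")
            if namespace == "nature":
                if nature != value:
                    return False
            elif lineage.get(namespace) != value:
                return False
        return True


@dataclass(slots=True)
class SimulationConfig:
    """Study-design knobs for :func:`simulate_dataset`.

    ``taxonomy_shape`` is either an explicit list of lineages (maps
    rank → taxon) sampled uniformly, or a map rank → branching factor from
    which a regular taxonomy is generated and then sampled with uneven
    (Dirichlet-ish, rng-driven) clade weights.
    """

    n_species: int
    taxonomy_shape: Sequence[Mapping[str, str]] | Mapping[str, int]
    nature_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "cold": 0.35, "hot": 0.21, "neutral": 0.34, "none": 0.10
        }
    )
    baseline_aa_prob: float = 0.18
    planted_effects: Sequence[PlantedEffect] = ()
    lineage_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        probs = dict(self.nature_probs)
        if set(probs) - set(NATURES):
            raise ConfigError(f"unknown nature labels {set(probs) - set(NATURES)}")
        if any(not (0.0 <= p <= 1.0) for p in probs.values()):
            raise ConfigError("nature_probs must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigError("nature_probs must sum to 1")
        if not (0.0 <= self.baseline_aa_prob <= 1.0):
            raise ConfigError("baseline_aa_prob must lie in [0, 1]")
        for eff in self.planted_effects:
            if not (0.0 <= eff.aa_prob <= 1.0):
                raise ConfigError("planted aa_prob must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        effects = [
            PlantedEffect(frozenset(e["condition"]), float(e["aa_prob"]))
            for e in d.pop("planted_effects", [])
        ]
        return cls(planted_effects=effects, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _expand_branching(shape: Mapping[str, int]) -> list[dict[str, str]]:
    """Regular taxonomy from per-rank branching factors, outermost first."""
    ranks = [r for r in RANKS if r in shape]
    if not ranks:
        raise ConfigError("taxonomy_shape must name at least one rank")
    lineages: list[dict[str, str]] = [{}]
    for rank in ranks:
        b = int(shape[rank])
        if b < 1:
            raise ConfigError(f"branching factor for {rank} must be >= 1")
        nxt = []
        for lin in lineages:
            stem = lin[ranks[ranks.index(rank) - 1]] if ranks.index(rank) else ""
            for i in range(1, b + 1):
                child = dict(lin)
                child[rank] = f"{stem}{rank[:1].upper()}{i}"
                nxt.append(child)
        lineages = nxt
    return lineages


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """Draw a random species table under a known generative model.

    Lineages are sampled from the taxonomy pool with rng-drawn uneven
    weights, nature labels i.i.d. from ``nature_probs``, and each species'
    AA flag is Bernoulli with the probability of the last matching planted
    effect, falling back to the baseline.  Identical seeds give identical
    datasets.
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(cfg.taxonomy_shape, Mapping):
        pool = _expand_branching(cfg.taxonomy_shape)
    else:
        pool = [dict(lin) for lin in cfg.taxonomy_shape]
        if not pool:
            raise ConfigError("taxonomy_shape lineage list is empty")
    # uneven clade sizes: Dirichlet weights over the lineage pool unless
    # the study design pins the clade proportions explicitly
    if cfg.lineage_weights is not None:
        weights = np.asarray(cfg.lineage_weights, dtype=float)
        if len(weights) != len(pool) or (weights < 0).any():
            raise ConfigError("lineage_weights must be nonnegative, one per lineage")
        weights = weights / weights.sum()
    else:
        weights = rng.dirichlet(np.ones(len(pool)))
    lineage_idx = rng.choice(len(pool), size=cfg.n_species, p=weights)

    labels = sorted(cfg.nature_probs)
    probs = np.array([cfg.nature_probs[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    natures = rng.choice(len(labels), size=cfg.n_species, p=probs)

    records: list[SpeciesRecord] = []
    for i in range(cfg.n_species):
        lineage = pool[lineage_idx[i]]
        nature = labels[natures[i]]
        p = cfg.baseline_aa_prob
        for eff in cfg.planted_effects:
            if eff.matches(lineage, nature):
                p = eff.aa_prob
        records.append(
            SpeciesRecord(
                latin_name=f"Simulatus sp. {i + 1:05d}",
                lineage=lineage,
                nature=nature,
                aa=bool(rng.random() < p),
            )
        )
    return Dataset(records=records, provenance=f"simulated(seed={cfg.seed})")


# --------------------------------------------------------------------------
# marginal-exact fixture construction
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class MarginalConstraint:
    """Required (total, AA) counts for the species satisfying ``condition``.

    ``condition`` is a conjunction of items over ``{rank:name, nature:label}``;
    the empty condition denotes the whole dataset.
    """

    condition: frozenset
    n_total: int
    n_aa: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_aa <= self.n_total):
            raise ValueError(f"need 0 <= n_aa <= n_total in {self}")

    def _split(self) -> tuple[dict[str, str], str | None]:
        taxa: dict[str, str] = {}
        nature: str | None = None
        for item in self.condition:
            namespace, _, value = item.partition(":")
            if namespace == "nature":
                if nature is not None:
                    raise ValueError(f"two nature items in {self}")
                nature = value
            elif namespace in RANKS:
                if namespace in taxa:
                    raise ValueError(f"two {namespace} items in {self}")
                taxa[namespace] = value
            else:
                raise ValueError(f"unknown namespace in item {item!r}")
        return taxa, nature

    def satisfied_by(self, rec: SpeciesRecord) -> bool:
        taxa, nature = self._split()
        if nature is not None and rec.nature != nature:
            return False
        return all(rec.lineage.get(r) == t for r, t in taxa.items())


def verify_constraints(
    ds: Dataset, constraints: Iterable[MarginalConstraint]
) -> list[tuple[MarginalConstraint, int, int]]:
    """Exhaustively count each constraint; return the violations."""
    bad = []
    for c in constraints:
        matches = [r for r in ds if c.satisfied_by(r)]
        n, n_aa = len(matches), sum(r.aa for r in matches)
        if (n, n_aa) != (c.n_total, c.n_aa):
            bad.append((c, n, n_aa))
    return bad


def _complete_lineage(
    taxa: Mapping[str, str], lineages: Mapping[str, Mapping[str, str]]
) -> dict[str, str]:
    """Expand condition taxa to a full partial lineage via known lineages."""
    out: dict[str, str] = {}
    for rank, taxon in taxa.items():
        known = dict(lineages.get(taxon, {})) or {rank: taxon}
        known.setdefault(rank, taxon)
        for r, t in known.items():
            if out.setdefault(r, t) != t:
                raise FeasibilityError(
                    f"conflicting lineages: rank {r} is both {out[r]!r} "
                    f"and {t!r}"
                )
    return out


@dataclass(slots=True)
class _TaxNode:
    constraint: MarginalConstraint
    lineage: dict[str, str]
    children: list["_TaxNode"] = field(default_factory=list)


def build_fixture(
    constraints: Sequence[MarginalConstraint],
    n_total: int,
    n_aa_total: int,
    seed: int = 0,
    lineages: Mapping[str, Mapping[str, str]] | None = None,
) -> Dataset:
    """Construct a dataset satisfying every marginal constraint exactly.

    The taxonomy-only constraints must be pairwise disjoint or nested once
    their conditions are completed through ``lineages`` (a map from taxon
    name to its known partial lineage); they form a forest that is filled
    innermost-first, a parent's remainder becoming direct children of its
    deepest taxon.  Nature-only constraints are dataset-wide marginals.
    Mixed (taxon ∧ nature) constraints are applied afterwards by forcing the
    label onto a seeded choice of matching species with the required AA
    split, barring the taxon's remaining species from that label so the
    joint count is exact.  Species matching no constraint get a reserved
    ZZ_filler lineage.  Every constraint is re-verified by exhaustive
    counting before the dataset is returned.
    """
    lineages = lineages or {}
    rng = np.random.default_rng(seed)
    if not (0 <= n_aa_total <= n_total):
        raise FeasibilityError("need 0 <= n_aa_total <= n_total")

    uniq: dict[frozenset, MarginalConstraint] = {}
    for c in constraints:
        prev = uniq.get(c.condition)
        if prev is not None and (prev.n_total, prev.n_aa) != (c.n_total, c.n_aa):
            raise FeasibilityError(
                f"constraints {prev} and {c} disagree on the same condition"
            )
        uniq[c.condition] = c
    deduped = list(uniq.values())

    tax_nodes: list[_TaxNode] = []
    nature_marg: dict[str, MarginalConstraint] = {}
    mixed: list[tuple[MarginalConstraint, dict[str, str], str]] = []
    for c in deduped:
        taxa, nature = c._split()
        if not taxa and nature is None:
            if (c.n_total, c.n_aa) != (n_total, n_aa_total):
                raise FeasibilityError(
                    f"whole-dataset constraint {c} contradicts totals "
                    f"({n_total}, {n_aa_total})"
                )
        elif not taxa:
            if nature in nature_marg:
                raise FeasibilityError(f"duplicate nature marginal {nature!r}")
            nature_marg[nature] = c
        elif nature is None:
            tax_nodes.append(_TaxNode(c, _complete_lineage(taxa, lineages)))
        else:
            mixed.append((c, _complete_lineage(taxa, lineages), nature))

    # ---- taxonomy forest ------------------------------------------------
    def implies(a: _TaxNode, b: _TaxNode) -> bool:
        """a's members necessarily satisfy b (a nested inside b)."""
        b_taxa, _ = b.constraint._split()
        return all(a.lineage.get(r) == t for r, t in b_taxa.items())

    # strict total order (lineage depth, then condition) so that parenting
    # can never cycle even when two conditions complete to the same lineage
    def node_key(node: _TaxNode):
        return (len(node.lineage), tuple(sorted(node.constraint.condition)))

    roots: list[_TaxNode] = []
    for node in tax_nodes:
        ancestors = [
            other
            for other in tax_nodes
            if other is not node
            and implies(node, other)
            and node_key(other) < node_key(node)
        ]
        if ancestors:
            parent = max(ancestors, key=node_key)
            parent.children.append(node)
        else:
            roots.append(node)

    records: list[SpeciesRecord] = []
    counter = [0]

    def species_name(stem: str) -> str:
        counter[0] += 1
        return f"{stem} sp. {counter[0]:04d}"

    def fill(node: _TaxNode) -> None:
        c = node.constraint
        kid_n = sum(k.constraint.n_total for k in node.children)
        kid_aa = sum(k.constraint.n_aa for k in node.children)
        direct_n = c.n_total - kid_n
        direct_aa = c.n_aa - kid_aa
        if direct_n < 0 or direct_aa < 0 or direct_aa > direct_n:
            raise FeasibilityError(
                f"constraint {c} cannot cover its nested constraints "
                f"(remainder {direct_n} species / {direct_aa} AA)"
            )
        for k in node.children:
            fill(k)
        deepest = node.lineage[max(node.lineage, key=RANKS.index)]
        for i in range(direct_n):
            records.append(
                SpeciesRecord(
                    latin_name=species_name(deepest),
                    lineage=node.lineage,
                    nature="none",
                    aa=i < direct_aa,
                )
            )

    for node in roots:
        fill(node)

    filler_n = n_total - sum(r.constraint.n_total for r in roots)
    filler_aa = n_aa_total - sum(r.constraint.n_aa for r in roots)
    if filler_n < 0 or filler_aa < 0 or filler_aa > filler_n:
        raise FeasibilityError(
            "top-level constraints exceed the dataset totals "
            f"(filler {filler_n} species / {filler_aa} AA)"
        )
    filler_lineage = {r: f"ZZ_filler_{r}" for r in RANKS}
    for i in range(filler_n):
        records.append(
            SpeciesRecord(
                latin_name=species_name("ZZ_filler"),
                lineage=filler_lineage,
                nature="none",
                aa=i < filler_aa,
            )
        )

    # ---- mixed constraints: force natures inside their taxon sets -------
    forced: dict[int, str] = {}          # record index -> forced label
    barred: dict[int, set[str]] = {}     # record index -> labels it must avoid

    for c, lineage_cond, label in mixed:
        taxa, _ = c._split()
        idx = [
            i
            for i, rec in enumerate(records)
            if all(rec.lineage.get(r) == t for r, t in taxa.items())
        ]
        free = [i for i in idx if i not in forced]
        aa_pool = [i for i in free if records[i].aa]
        non_pool = [i for i in free if not records[i].aa]
        need_aa, need_non = c.n_aa, c.n_total - c.n_aa
        if len(aa_pool) < need_aa or len(non_pool) < need_non:
            raise FeasibilityError(
                f"constraint {c}: taxon set has only {len(aa_pool)} free AA "
                f"and {len(non_pool)} free non-AA species"
            )
        chosen = [
            int(i) for i in rng.choice(aa_pool, size=need_aa, replace=False)
        ] + [int(i) for i in rng.choice(non_pool, size=need_non, replace=False)]
        for i in chosen:
            if forced.get(i, label) != label:
                raise FeasibilityError(
                    f"constraint {c}: species already forced to another label"
                )
            forced[i] = label
        for i in idx:
            if i not in forced:
                barred.setdefault(i, set()).add(label)

    # ---- nature marginals ------------------------------------------------
    assigned: dict[int, str] = dict(forced)
    # most-constrained labels (those some species are barred from) first
    bar_counts = {
        lbl: sum(1 for s in barred.values() if lbl in s) for lbl in nature_marg
    }
    for label in sorted(nature_marg, key=lambda l: (-bar_counts[l], l)):
        c = nature_marg[label]
        already = [i for i, l in assigned.items() if l == label]
        got_aa = sum(records[i].aa for i in already)
        need_aa = c.n_aa - got_aa
        need_non = (c.n_total - c.n_aa) - (len(already) - got_aa)
        if need_aa < 0 or need_non < 0:
            raise FeasibilityError(
                f"nature marginal {c} is exceeded by forced assignments"
            )
        free = [
            i
            for i in range(len(records))
            if i not in assigned and label not in barred.get(i, set())
        ]
        aa_pool = [i for i in free if records[i].aa]
        non_pool = [i for i in free if not records[i].aa]
        if len(aa_pool) < need_aa or len(non_pool) < need_non:
            raise FeasibilityError(
                f"nature marginal {c}: only {len(aa_pool)} AA / "
                f"{len(non_pool)} non-AA species remain assignable"
            )
        for i in rng.choice(aa_pool, size=need_aa, replace=False):
            assigned[int(i)] = label
        for i in rng.choice(non_pool, size=need_non, replace=False):
            assigned[int(i)] = label

    records = [
        rec.with_nature(assigned.get(i, "none")) for i, rec in enumerate(records)
    ]

    # ---- shuffle and verify ---------------------------------------------
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    ds = Dataset(records=records, provenance=f"build_fixture(seed={seed})")
    bad = verify_constraints(ds, constraints)
    if bad:
        c, n, n_aa = bad[0]
        raise FeasibilityError(
            f"constraint {c} not satisfied by construction: counted "
            f"({n}, {n_aa})"
        )
    if len(ds) != n_total or ds.n_aa != n_aa_total:
        raise FeasibilityError("dataset totals drifted during construction")
    return ds


# --------------------------------------------------------------------------
# the published-marginal fixture
# --------------------------------------------------------------------------

#: Known partial lineages of the taxa named in the published tables.
REFERENCE_LINEAGES: dict[str, dict[str, str]] = {
    "Bacteria": {"superkingdom": "Bacteria"},
    "Eukaryota": {"superkingdom": "Eukaryota"},
    "Metazoa": {"superkingdom": "Eukaryota", "kingdom": "Metazoa"},
    "Viridiplantae": {"superkingdom": "Eukaryota", "kingdom": "Viridiplantae"},
    "Streptophyta": {
        "superkingdom": "Eukaryota",
        "kingdom": "Viridiplantae",
        "phylum": "Streptophyta",
    },
    "Malpighiales": {
        "superkingdom": "Eukaryota",
        "kingdom": "Viridiplantae",
        "phylum": "Streptophyta",
        "order": "Malpighiales",
    },
    "Rhizophoraceae": {
        "superkingdom": "Eukaryota",
        "kingdom": "Viridiplantae",
        "phylum": "Streptophyta",
        "order": "Malpighiales",
        "family": "Rhizophoraceae",
    },
    # brown algae sit in Eukaryota outside the Metazoa/Viridiplantae kingdoms
    "Phaeophyceae": {"superkingdom": "Eukaryota", "class": "Phaeophyceae"},
    "Fucales": {
        "superkingdom": "Eukaryota",
        "class": "Phaeophyceae",
        "order": "Fucales",
    },
    "Sargassaceae": {
        "superkingdom": "Eukaryota",
        "class": "Phaeophyceae",
        "order": "Fucales",
        "family": "Sargassaceae",
    },
    "Sargassum": {
        "superkingdom": "Eukaryota",
        "class": "Phaeophyceae",
        "order": "Fucales",
        "family": "Sargassaceae",
        "genus": "Sargassum",
    },
    "Holothuroidea": {
        "superkingdom": "Eukaryota",
        "kingdom": "Metazoa",
        "phylum": "Echinodermata",
        "class": "Holothuroidea",
    },
    "Aspidochirotida": {
        "superkingdom": "Eukaryota",
        "kingdom": "Metazoa",
        "phylum": "Echinodermata",
        "class": "Holothuroidea",
        "order": "Aspidochirotida",
    },
    "Holothuria": {
        "superkingdom": "Eukaryota",
        "kingdom": "Metazoa",
        "phylum": "Echinodermata",
        "class": "Holothuroidea",
        "order": "Aspidochirotida",
        "family": "Holothuriidae",
        "genus": "Holothuria",
    },
}

#: Published kingdom/superkingdom marginals: group -> (n species, n AA).
#: "Others in Eukaryota" (123/51) is not listed: it is the residual of the
#: Eukaryota superkingdom after Metazoa and Viridiplantae and falls out of
#: the nested constraints below (1082 - 870 - 89 = 123; 188 - 92 - 45 = 51).
KINGDOM_MARGINALS: dict[str, tuple[int, int]] = {
    "superkingdom:Bacteria": (9, 6),
    "superkingdom:Eukaryota": (1082, 188),
    "kingdom:Metazoa": (870, 92),
    "kingdom:Viridiplantae": (89, 45),
}

#: Published nature marginals: label -> (n species, n AA).
NATURE_MARGINALS: dict[str, tuple[int, int]] = {
    "nature:cold": (380, 99),
    "nature:hot": (233, 24),
    "nature:neutral": (366, 49),
    "nature:none": (112, 22),
}

#: Antecedent counts (n species, n AA) implied by each screened rule's
#: printed support and confidence: n_aa = round(support x 1091),
#: n = round(n_aa / confidence).  Every pair reproduces the printed support,
#: confidence and lift at 2 dp (half-up) — the acceptance guard for using it.
RULE_ANTECEDENT_COUNTS: dict[frozenset, tuple[int, int]] = {
    frozenset({"superkingdom:Bacteria"}): (9, 6),
    frozenset({"phylum:Streptophyta"}): (67, 35),
    frozenset({"class:Phaeophyceae"}): (38, 24),
    frozenset({"class:Holothuroidea"}): (27, 14),
    frozenset({"order:Malpighiales"}): (8, 7),
    frozenset({"order:Fucales"}): (20, 13),
    frozenset({"order:Aspidochirotida"}): (23, 12),
    frozenset({"family:Rhizophoraceae"}): (7, 6),
    frozenset({"family:Sargassaceae"}): (19, 13),
    frozenset({"genus:Sargassum"}): (16, 11),
    frozenset({"genus:Holothuria"}): (13, 8),
    frozenset({"nature:cold", "kingdom:Viridiplantae"}): (50, 28),
}

#: Dataset totals: 1,091 species, 194 with reported AA.
TOTAL_SPECIES = 1091
TOTAL_AA = 194


def reference_constraints() -> list[MarginalConstraint]:
    """The full published constraint system as MarginalConstraints."""
    out: list[MarginalConstraint] = []
    for item, (n, n_aa) in {**KINGDOM_MARGINALS, **NATURE_MARGINALS}.items():
        out.append(MarginalConstraint(frozenset({item}), n, n_aa))
    for cond, (n, n_aa) in RULE_ANTECEDENT_COUNTS.items():
        out.append(MarginalConstraint(cond, n, n_aa))
    return out


def materia_medica_fixture(seed: int = 2017) -> Dataset:
    """The canonical fixture reproducing the published marginal counts.

    1,091 species / 194 AA, with every kingdom, nature, and screened-rule
    antecedent count embedded exactly.  The species list itself is synthetic
    (the original collection is not deposited); only its marginals are real.
    """
    ds = build_fixture(
        reference_constraints(),
        n_total=TOTAL_SPECIES,
        n_aa_total=TOTAL_AA,
        seed=seed,
        lineages=REFERENCE_LINEAGES,
    )
    ds.provenance = f"materia_medica_fixture(seed={seed})"
    return ds
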