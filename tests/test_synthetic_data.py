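"""Simulation and marginal-exact fixture construction."""

import numpy as np
import pytest
from scipy import stats

from bioprospect import (
    FeasibilityError,
    MarginalConstraint,
    PlantedEffect,
    build_fixture,
    materia_medica_fixture,
    verify_constraints,
    write_species_table,
)
from bioprospect.rule_mining import format_pct, round_half_up
from bioprospect.synthetic_data import (
    ConfigError,
    REFERENCE_LINEAGES,
    RULE_ANTECEDENT_COUNTS,
    SimulationConfig,
    TOTAL_AA,
    TOTAL_SPECIES,
    reference_constraints,
    simulate_dataset,
)

SHAPE = {"superkingdom": 2, "phylum": 2, "family": 3}


def test_zero_aa_probability_gives_all_negative():
    cfg = SimulationConfig(n_species=200, taxonomy_shape=SHAPE,
                           baseline_aa_prob=0.0, seed=1)
    assert simulate_dataset(cfg).n_aa == 0


def test_unit_aa_probability_gives_all_positive():
    cfg = SimulationConfig(n_species=200, taxonomy_shape=SHAPE,
                           baseline_aa_prob=1.0, seed=1)
    assert simulate_dataset(cfg).n_aa == 200


def test_same_seed_gives_byte_identical_tables(tmp_path):
    paths = []
    for name in ("a.tsv", "b.tsv"):
        cfg = SimulationConfig(n_species=150, taxonomy_shape=SHAPE, seed=9)
        write_species_table(simulate_dataset(cfg), tmp_path / name)
        paths.append(tmp_path / name)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_invalid_probabilities_are_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(n_species=10, taxonomy_shape=SHAPE,
                         baseline_aa_prob=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(
            n_species=10, taxonomy_shape=SHAPE,
            nature_probs={"cold": 0.5, "hot": 0.6, "neutral": 0.0, "none": 0.0},
        )


def test_planted_effect_hits_its_target_rate():
    # one family enriched to 0.7 against a 0.15 baseline
    pool = [{"superkingdom": "E", "family": "F"},
            {"superkingdom": "E", "family": "G"}]
    cfg = SimulationConfig(
        n_species=2000,
        taxonomy_shape=pool,
        baseline_aa_prob=0.15,
        planted_effects=[PlantedEffect(frozenset({"family:F"}), 0.7)],
        lineage_weights=[0.5, 0.5],
        seed=42,
    )
    ds = simulate_dataset(cfg)
    clade = [r for r in ds if r.lineage.get("family") == "F"]
    m = len(clade)
    k = sum(r.aa for r in clade)
    lo, hi = stats.binom.interval(0.99, m, 0.7)
    assert lo <= k <= hi
    rest = [r for r in ds if r.lineage.get("family") != "F"]
    lo, hi = stats.binom.interval(0.99, len(rest), 0.15)
    assert lo <= sum(r.aa for r in rest) <= hi


def test_planted_confidence_converges_with_clade_size():
    # binomial bounds narrow as the clade grows; the empirical AA rate in
    # the planted clade must track the planted value at every size
    pool = [{"superkingdom": "E", "family": "F"},
            {"superkingdom": "E", "family": "G"}]
    c = 0.7
    for m_target in (50, 500, 5000):
        cfg = SimulationConfig(
            n_species=2 * m_target,
            taxonomy_shape=pool,
            baseline_aa_prob=0.15,
            planted_effects=[PlantedEffect(frozenset({"family:F"}), c)],
            lineage_weights=[0.5, 0.5],
            seed=m_target,
        )
        ds = simulate_dataset(cfg)
        clade = [r for r in ds if r.lineage.get("family") == "F"]
        m, k = len(clade), sum(r.aa for r in clade)
        lo, hi = stats.binom.interval(0.999, m, c)
        assert lo <= k <= hi
        assert abs(k / m - c) <= 5 * np.sqrt(c * (1 - c) / m)


def test_build_fixture_bacteria_example():
    constraints = [MarginalConstraint(frozenset({"superkingdom:Bacteria"}), 9, 6)]
    ds = build_fixture(constraints, n_total=100, n_aa_total=20, seed=0)
    bact = [r for r in ds if r.lineage.get("superkingdom") == "Bacteria"]
    assert len(bact) == 9
    assert sum(r.aa for r in bact) == 6
    assert len(ds) == 100 and ds.n_aa == 20


def test_build_fixture_all_negative_whole_dataset():
    ds = build_fixture(
        [MarginalConstraint(frozenset(), 50, 0)], n_total=50, n_aa_total=0, seed=1
    )
    assert ds.n_aa == 0 and len(ds) == 50


def test_build_fixture_rejects_infeasible_nesting():
    constraints = [
        MarginalConstraint(frozenset({"family:F"}), 5, 5),
        MarginalConstraint(frozenset({"genus:G"}), 9, 2),
    ]
    lineages = {"G": {"family": "F", "genus": "G"}}
    with pytest.raises(FeasibilityError):
        build_fixture(constraints, 100, 20, seed=0, lineages=lineages)


def test_build_fixture_rejects_contradictory_duplicates():
    constraints = [
        MarginalConstraint(frozenset({"family:F"}), 5, 2),
        MarginalConstraint(frozenset({"family:F"}), 6, 2),
    ]
    with pytest.raises(FeasibilityError):
        build_fixture(constraints, 100, 20, seed=0)


def test_build_fixture_rejects_overfull_totals():
    constraints = [MarginalConstraint(frozenset({"family:F"}), 50, 10)]
    with pytest.raises(FeasibilityError):
        build_fixture(constraints, 20, 15, seed=0)


def test_fixture_satisfies_every_reference_constraint(fixture_ds):
    assert verify_constraints(fixture_ds, reference_constraints()) == []
    assert len(fixture_ds) == TOTAL_SPECIES
    assert fixture_ds.n_aa == TOTAL_AA


def test_fixture_is_deterministic_under_seed(tmp_path):
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_species_table(materia_medica_fixture(), a)
    write_species_table(materia_medica_fixture(), b)
    assert a.read_bytes() == b.read_bytes()


def test_filler_taxa_never_satisfy_reference_conditions(fixture_ds):
    named = {
        taxon for lin in REFERENCE_LINEAGES.values() for taxon in lin.values()
    }
    for rec in fixture_ds:
        if any(t.startswith("ZZ_filler") for t in rec.lineage.values()):
            assert not named & set(rec.lineage.values())


# printed (support, confidence, lift) strings for each screened rule, used
# to re-validate the frozen antecedent counts the fixture embeds
PRINTED_RULES = {
    frozenset({"superkingdom:Bacteria"}): ("0.55%", "66.67%", "3.75"),
    frozenset({"phylum:Streptophyta"}): ("3.21%", "52.24%", "2.94"),
    frozenset({"class:Phaeophyceae"}): ("2.20%", "63.16%", "3.55"),
    frozenset({"class:Holothuroidea"}): ("1.28%", "51.85%", "2.92"),
    frozenset({"order:Malpighiales"}): ("0.64%", "87.50%", "4.92"),
    frozenset({"order:Fucales"}): ("1.19%", "65.00%", "3.66"),
    frozenset({"order:Aspidochirotida"}): ("1.10%", "52.17%", "2.93"),
    frozenset({"family:Rhizophoraceae"}): ("0.55%", "85.71%", "4.82"),
    frozenset({"family:Sargassaceae"}): ("1.19%", "68.42%", "3.85"),
    frozenset({"genus:Sargassum"}): ("1.01%", "68.75%", "3.87"),
    frozenset({"genus:Holothuria"}): ("0.73%", "61.54%", "3.46"),
    frozenset({"nature:cold", "kingdom:Viridiplantae"}): ("2.57%", "56.00%", "3.15"),
}


def test_embedded_rule_counts_reproduce_printed_metrics():
    """Anti-hallucination guard: each frozen (n, n_aa) pair must re-print the
    published support, confidence AND lift at 2 dp half-up."""
    from fractions import Fraction

    assert set(RULE_ANTECEDENT_COUNTS) == set(PRINTED_RULES)
    for cond, (n, n_aa) in RULE_ANTECEDENT_COUNTS.items():
        sup, conf, lift = PRINTED_RULES[cond]
        assert format_pct(Fraction(n_aa, TOTAL_SPECIES)) == sup
        assert format_pct(Fraction(n_aa, n)) == conf
        assert (
            str(round_half_up(Fraction(n_aa, n) / Fraction(TOTAL_AA, TOTAL_SPECIES)))
            == lift
        )
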