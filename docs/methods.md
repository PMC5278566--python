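# Methods

## Data model

The unit of analysis is the species, identified by its Latin name. Each
record carries a partial lineage over the seven canonical ranks
(superkingdom, kingdom, phylum, class, order, family, genus — ranks not
applicable to an organism are simply absent), a nature label in
{cold, hot, neutral, none}, and a boolean anticancer-activity (AA) flag.
"none" is a real level: species with no recorded nature stay in every
denominator. A medicinal preparation may derive from several species, but
preparation identity is not modelled because all the statistics this
package computes are species-level. Nature labels are normalized to
lowercase on read; the tab-separated table format recognizes columns by
header name, uses "" for absent ranks, and rejects duplicate Latin names.

## Transaction encoding

A species becomes the itemset of its present lineage entries
(`rank:taxon`), its nature (`nature:label`) and, when flagged, the bare
consequent token `anticancer`. Species with nature "none" emit *no* nature
item rather than an explicit `nature:none` item — they can never appear in
a nature antecedent but still count in every support denominator. This
convention is decisive: it is the one under which the screened-rule
supports recompute to the published values.

## Rule mining

Frequent itemsets are mined level-wise (apriori): candidates of size k are
prefix-joins of frequent (k−1)-sets, pruned unless every (k−1)-subset is
frequent, which is sound because support is anti-monotone. Rules have the
fixed consequent {anticancer}; general consequents are out of scope. All
three screens are strict inequalities ("larger than" the thresholds):
support > 0.005, confidence > 0.50, lift > 2, antecedents of at most two
items by default (the published screened rules are single- or double-item
only; the cap is configurable upward).

Numerical policy: counts are integers; support, confidence and lift are
`fractions.Fraction` ratios, so threshold comparisons are exact — a rule
whose support is exactly the threshold is excluded without float artifacts.
Thresholds given as floats are read through their decimal literal (0.005
means 5/1000). Formatting rounds half-up at 2 decimal places and happens
only at the printing boundary. Lift is defined as confidence divided by the
consequent's support — the standard definition; it reproduces every
published lift value, e.g. (6/9)/(194/1091) = 3.749… → 3.75. Output rules
are sorted by (antecedent size, descending confidence, lexicographic
antecedent); the ordering is presentation, not computation.

`brute_force_rules` enumerates every antecedent over the observed item
universe (guarded to ≤ 25 items) with direct counting and identical
screens; it is the independent oracle the miner is equated against on
randomized instances, never the production path.

## Taxonomy trees

Trees are taxonomy-derived, not sequence-based: root → superkingdom → … →
leaf rank, with absent ranks collapsed so a child attaches to its nearest
present ancestor. There are no branch lengths. Children are kept
lexicographically sorted, making the tree, its Newick export and its leaf
order (depth-first) deterministic and invariant under row permutation. Two
design choices worth noting:

- a species whose lineage stops above the requested leaf rank attaches to
  its deepest present taxon; if that taxon also has subordinate taxa the
  species goes to a synthetic "<taxon> incertae sedis" leaf, preserving the
  invariant that species live only at leaves;
- one taxon name under two different parents (a homonym) is an error, not a
  silent merge.

Aggregated leaves are annotated AA-positive when *any* member species has
AA (mirroring how whole families are shaded in circular-tree figures), with
the modal nature (ties broken lexicographically) and a bar value equal to
the member count.

## Cluster statistics

An "AA cluster" is a maximal run of consecutive AA-positive leaves in the
tree's leaf order — a formalization of contiguous shaded arcs in a circular
layout. The original figures' leaf ordering came from external web tools
and is not recoverable, so published cluster counts (61 families in 38
clusters; 52 in 18) are *not* reproduction targets; the definition is
instead validated against a run-length-encoding oracle and by structural
properties (0 ≤ n_clusters ≤ n_positive; inserting a negative leaf between
two positives adds exactly one cluster). Whether "cluster" meant strictly
contiguous arcs is an interpretation this package makes explicitly.

## Synthetic data

`simulate_dataset` draws lineages from a taxonomy pool (explicit lineage
list, or generated from per-rank branching factors) with Dirichlet-weighted
uneven clade sizes (or pinned weights when a test needs a known clade
size), natures i.i.d. from a categorical distribution, and AA flags
Bernoulli with a baseline probability overridden inside planted
clade/nature conditions (last match wins). Defaults emulate the real
collection's gross shape: nature probabilities (0.35, 0.21, 0.34, 0.10)
and baseline AA prevalence 0.18, close to the published marginal rates. It
does **not** emulate real correlation between taxonomy and nature, uneven
literature coverage of AA reporting, or taxonomic homonyms, so passing
recovery tests demonstrate correctness of the machinery under the stated
model, not robustness to those real-data features.

`build_fixture` solves the inverse problem: construct a dataset satisfying
a system of (total, AA) marginal constraints exactly. Taxonomy-only
constraints are completed through a table of known lineages and arranged
into a nesting forest (a constraint is a child of the most specific
constraint its lineage implies); each node is filled innermost-first, the
remainder becoming direct members of its deepest taxon, and unconstrained
species get a reserved `ZZ_filler_<rank>` lineage that can never satisfy a
real condition. Mixed taxon∧nature constraints cannot always be forest
nodes (the published cold∧Viridiplantae set overlaps Streptophyta), so they
are applied as a second pass: the label is forced onto a seeded choice of
matching species with the required AA split, and the taxon's remaining
species are barred from that label, making the joint count exact. Nature
marginals are then filled most-constrained-label-first from the free pool.
Every constraint is finally re-verified by exhaustive counting — the
construction is never trusted.

The embedded reference constants derive from the published tables: kingdom
and nature marginals are printed outright; each screened rule's antecedent
counts are implied by its printed support and confidence
(n_AA = round(support × 1091), n = round(n_AA / confidence)) and are
accepted only because every derived pair re-prints the published support,
confidence *and* lift at 2 dp — a guard asserted in the test suite. One
inconsistency in the source is recorded rather than reconciled: the prose
gives Phaeophyceae 23 AA species while its rule's support/confidence imply
24 of 38; the fixture uses the rule-consistent 24. "Others in Eukaryota"
is not a conjunctive condition, so the fixture constrains Eukaryota
(1082/188) with Metazoa and Viridiplantae nested inside and lets the
123/51 residual fall out of the rollup. The fixture's filler structure can
admit screened rules beyond the published twelve (e.g. ancestors sharing a
constrained clade's counts), so "exactly 12 rules" is not claimed — the
published rows themselves are reproduced exactly.

## Problem sizes

The canonical fixture is 1,091 species and builds in well under a second;
randomized oracle-equivalence tests use a few hundred instances of ≤ 40
transactions over ≤ 8 items; planted-recovery tests use 20 seeds of
1,000-species datasets with a ~500-species enriched clade (the planted
lift, 0.7 / 0.425 ≈ 1.6, sits below the default lift screen, so recovery
tests mine at min_lift 1.2). These sizes give stable statistics while
keeping the full suite in a few seconds.

## Limitations

- The fixture reproduces marginals, not the true species list; statistics
  not pinned by a constraint (e.g. cluster counts, supplementary-table
  values) are fixture-dependent and are not treated as reproduction
  targets.
- The PubMed query formatter reproduces the original retrieval string
  (including its "antitumer" spelling) but performs no retrieval; AA flags
  are inputs.
- No statistical significance testing or redundancy pruning of rules is
  performed, matching the original screening procedure.
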