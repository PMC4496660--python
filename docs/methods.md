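# Methods

## Model

The package treats a food knowledge base as a graph over ingredient,
additive and compound concepts with three typed relation families:
directed **subclass** (is-a) edges, undirected **synonym** edges, and
directed **group** membership edges (a group behaves as a superclass of
its members for traversal). Synonym edges induce an equivalence relation;
all hierarchy queries run on the quotient graph with one node per synonym
class, so "Vitamin C" inherits the subclasses of "Ascorbic Acid" without
any special-casing.

### Distance weighting

A direct subclass (or group) edge under a parent with *n* direct children
carries weight 1/*n*; an ontology developer may override any single edge
with an explicit weight in (0, 1], and overrides are never renormalized —
the remaining siblings keep their 1/*n* shares. A chain's weight is the
product of its edge weights and its distance is its edge count; identical
concepts are (1, 0) and synonym-equivalent ones (1, 1). `path_weight`
finds the shortest chain by BFS over the undirected quotient hierarchy;
among chains of equal edge count it keeps the maximum weight product, and
among those the lexicographically least node sequence, making the result
deterministic. Traversing an edge upward or downward contributes the same
parent-side 1/*n* weight: the weight describes how discriminating the
parent's fan-out is, not a direction.

### Matchmaking degrees

Two concepts are **Exact** (degree 1) when identical or synonym-
equivalent, **Plugin** (0.75) or **Subsume** (0.5) when hierarchy-
connected, and **Dissimilar** (0, weight 0, no distance) otherwise. The
assignment of Plugin vs Subsume to the two hierarchy directions is
genuinely ambiguous in the method's published descriptions: the prose
definitions make a consumer concept *below* the product concept Plugin,
while every quantitative worked result uses the opposite. Both are kept
behind `MatchConfig.convention`:

* `example` (default) — consumer concept above the product concept ⇒
  Plugin; below ⇒ Subsume. Reproduces the worked product scores.
* `definition` — the mirror image, matching the prose definitions.

Sibling concepts below a common ancestor are Subsume in both modes
(the worked sibling pair is scored 0.5), and a mode switch provably
changes nothing but the Plugin/Subsume labels on ancestor/descendant
pairs (property-tested).

### Enhancement

Consumer terms expand through synonyms (full closure) plus group and is-a
links one hop from the seed's synonym class; a `hops` knob allows deeper
expansion. One hop is the depth that keeps an ascorbic-acid seed's
expansion at {Ascorbic Acid, E300, L-Ascorbic Acid, Vitamin C, Ascorbate}
without dragging in broad classes like "Antioxidant", whose inclusion
would make nearly every product pair-related. Unresolvable terms warn and
are recorded rather than failing: free-text label data is noisy.

`MatchConfig.enhance_relations` defaults to the *empty* set, i.e.
`evaluate` treats the consumer's term list as an already-enhanced list C.
This keeps list sizes — and hence n_C in the Jaro factor — under the
caller's control; opting into enhancement multiplies n_C by the synonym
density of the ontology and correspondingly dilutes d_j.

### Matching and aggregation

The matcher is deliberately greedy-sequential, not an optimal assignment:
consumer concepts are visited in list order and each takes the
highest-degree remaining ingredient (ties: larger contribution term
degree·weight/distance, then lowest ingredient index — deterministic and
favouring the stronger link). The shorter list is then padded with null
partners at degree 0 so the pair list has max(n_C, n_P) entries.

With m = Σ degrees and l = the count of non-Dissimilar pairs,

    d_j = (m/n_C + m/n_P)/2,   d_w = d_j + l·k·(1 − d_j)  (clamped to 1)

with Winkler constant k = 0.1 by default. l counts *matched pairs*, not
all pairs: this is the only reading consistent with both published worked
computations (one uses 2 with one unmatched pair, the other 3 with all
matched). The aggregate is

    score = (Σ degree·weight/distance) / ((n_C/n_P)·d_w)

defined as 0 when m = 0, absorbing the division singularity — a product
with no related ingredient carries no signal. The integer percentage is
floor(score·100/n_pairs) clamped to [0, 100]; floor (not rounding) is
what reproduces the published 33% and 56%. When n_P > n_C the n_C/n_P
ratio inflates the score; this literal behaviour is retained as specified.
All arithmetic is double precision; tests compare printed reference
values at ±0.002 because the reference rounds intermediates to 3–4
decimals.

## Rule layer

Rules are conjunctions of unary/binary atoms with `?`-variables, parsed
from one-rule-per-line text files. DL-safety (every head variable occurs
in the body; variables bind only to named individuals in the fact base)
makes the least fixpoint finite; the engine is a naive semi-naive loop
with a derivation cap of |individuals|²·|predicates| as a bug guard. Only
the `greaterThan`/`lessThan` numeric builtins are supported; other
builtins are rejected at parse time. The packaged rule set covers the
four risk families (lactose, gluten, fish, egg) representatively rather
than reproducing a full production rule base.

`expand_rule_concepts` substitutes each ontology-resolvable constant by
every concept with a non-zero matchmaking degree against it — synonyms,
sub/superclasses and group relatives — consistently across body and head,
keeping the original rule first. The CME scoring and the rule layer are
presented side by side in reports without reconciliation: a fired risk
rule and a low intolerance score can coexist, and the report shows both.

## Verdict and profile bands

The traffic light is a function of the pair-relation multiset only: RED
iff ≥ 1 Exact pair, YELLOW iff related-but-no-Exact, GREEN otherwise; the
YELLOW report carries a fixed seek-professional-advice advisory. Profile
band tables (BMI, basal metabolic rate, activity level, blood pressure)
are printed with touching or overlapping endpoints in their source form,
so one convention is imposed: closed lower bound, open upper bound, final
band open-ended (so BMI 19.0 is "normal overweight" and BMR 1600 "very
active"). The blood-pressure classifier takes a (low, high) pair, bands
each component in its own column and reports the worse of the two — the
usual clinical convention when diastolic and systolic disagree. Values
below the first band report "unclassified".

## Synthetic generator

`random_ontology` emulates the fixture scale the engine targets: layered
forests 3 levels deep with 1–3 children per class, E-code-style synonym
aliases on ~30% of concepts and occasional group nodes — the shape of
small additive taxonomies. It is seeded and byte-reproducible, and
acyclic by construction. It does *not* emulate ingredient co-occurrence
statistics, multilingual labels, typos, or the size of a production
knowledge base (hundreds of classes, ~1,500 individuals), so passing
property tests demonstrate algebraic correctness of the engine, not
recall on real packaging data.

## Test oracles and problem sizes

Three deliberately naive re-derivations back the property tests:
exhaustive simple-chain enumeration for `path_weight`, per-step
brute-force maximality checking for the greedy matcher, and
try-every-grounding saturation for the rule engine. The default suite
runs the matcher oracle on 200 seeded instances with lists up to 8×8,
the Jaro–Winkler bounds on 1,000 draws, and chaining properties on 100
random fact bases — sizes at which the exponential oracles stay well
under a second while exercising every branch of the production code.

## Known limitations

* OWL support is restricted to the four element kinds the fixture dialect
  uses (Declaration, ClassAssertion, SubClassOf, ObjectPropertyAssertion);
  restrictions, data properties and imports are out of scope, as is
  reasoner integration.
* Labels are matched after normalization (case, whitespace, underscores)
  but never fuzzily; a misspelled ingredient simply fails to resolve and
  is reported as unresolved.
* The greedy matcher can be order-sensitive when two consumer concepts
  compete for the same best ingredient; this mirrors the specified
  sequential algorithm and is intentional.
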