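"""Packaged worked-example data, synthetic generators and test oracles.

``worked_example`` rebuilds the small vitamin/alginate ontology used
throughout the documentation: ascorbic acid with three direct subclasses
and three synonyms, algin with two subclasses and one synonym, vitamin B3
with two synonyms, and folic acid as an unrelated bystander.  The consumer
is intolerant to D-Isoascorbic Acid, Algin and Vitamin B3; product 1
contains sodium alginate, ascorbic acid and folic acid; product 2 ascorbyl
palmitate, niacin and sodium alginate (an alternate variant swaps the
third ingredient for alginic acid).

``random_ontology`` produces seeded layered hierarchies for property
tests, and the ``oracle_*`` functions are deliberately naive re-derivations
used to cross-check the production code paths.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .cme import MatchConfig, PairMatch, Relation, classify_relation, pair_term
from .enhancement import ConsumerProfile, EnhancedList, Product
from .ontology import OntologyGraph, graph_from_dict
from .rules import Atom, FactBase, Rule, parse_rule

__all__ = [
    "GeneratorParams",
    "worked_example",
    "fig3_graph",
    "allergy_rules_graph",
    "packaged_rules",
    "lactose_fact_base",
    "random_ontology",
    "random_fact_base",
    "oracle_match",
    "oracle_path",
    "oracle_saturate",
]


# ---------------------------------------------------------------------
# worked example
# ---------------------------------------------------------------------

_WORKED = {
    "concepts": [
        {"label": "Ascorbic Acid", "annotations": {"rda": "90.0 mg", "solubility": "Water"}},
        {"label": "E300", "kind": "individual"},
        {"label": "Vitamin C"},
        {"label": "L-Ascorbic Acid"},
        {"label": "Ascorbate"},
        {"label": "Ester-C"},
        {"label": "Ascorbyl Palmitate"},
        {"label": "D-Isoascorbic Acid", "annotations": {"also_known_as": "Dehydroascorbic Acid; Erythorbic Acid"}},
        {"label": "Algin"},
        {"label": "Alginic Acid"},
        {"label": "Calcium Alginate"},
        {"label": "Sodium Alginate"},
        {"label": "Vitamin B3", "annotations": {"rda": "16.0 mg", "solubility": "Water"}},
        {"label": "Niacin"},
        {"label": "Niacinamide"},
        {"label": "Folic Acid"},
    ],
    "subclass": [
        ["Ascorbic Acid", "Ester-C"],
        ["Ascorbic Acid", "Ascorbyl Palmitate"],
        ["Ascorbic Acid", "D-Isoascorbic Acid"],
        ["Algin", "Calcium Alginate"],
        ["Algin", "Sodium Alginate"],
    ],
    "synonyms": [
        ["Ascorbic Acid", "E300"],
        ["Ascorbic Acid", "Vitamin C"],
        ["Ascorbic Acid", "L-Ascorbic Acid"],
        ["Algin", "Alginic Acid"],
        ["Vitamin B3", "Niacin"],
        ["Vitamin B3", "Niacinamide"],
    ],
    "groups": [["Ascorbic Acid", "Ascorbate"]],
}


def worked_example(
    variant: str = "default",
) -> tuple[OntologyGraph, ConsumerProfile, Product, Product]:
    """The packaged worked example: (graph, consumer, product1, product2).

    ``variant="default"`` gives product 2 the ingredient list behind the
    published pair relations (third ingredient Sodium Alginate);
    ``variant="table11"`` gives the literal printed ingredient table
    (third ingredient Alginic Acid, a synonym of Algin, hence Exact).
    """
    if variant not in ("default", "table11"):
        raise ValueError(f"unknown variant: {variant!r}")
    graph = graph_from_dict(_WORKED)
    consumer = ConsumerProfile(
        id="worked-consumer",
        intolerances=["D-Isoascorbic Acid", "Algin", "Vitamin B3"],
    )
    p1 = Product(ean="8690000000017", name="Product 1",
                 ingredients=["Sodium Alginate", "Ascorbic Acid", "Folic Acid"])
    third = "Sodium Alginate" if variant == "default" else "Alginic Acid"
    p2 = Product(ean="8690000000024", name="Product 2",
                 ingredients=["Ascorbyl Palmitate", "Niacin", third])
    return graph, consumer, p1, p2


def fig3_graph() -> OntologyGraph:
    """The synonym/group/is-a neighbourhood of ascorbic acid.

    The is-a chain to the broader classes hangs off the Ascorbate group
    node (Ascorbate is an Antioxidant is a Food Additive), so a one-hop
    expansion from an ascorbic-acid seed stops at Ascorbate.
    """
    return graph_from_dict(
        {
            "concepts": [
                "Ascorbic Acid", "Vitamin C", "E300", "L-Ascorbic Acid",
                "Ascorbate", "Antioxidant", "Food Additive",
            ],
            "subclass": [
                ["Antioxidant", "Ascorbate"],
                ["Food Additive", "Antioxidant"],
            ],
            "synonyms": [
                ["Ascorbic Acid", "Vitamin C"],
                ["Ascorbic Acid", "E300"],
                ["Ascorbic Acid", "L-Ascorbic Acid"],
            ],
            "groups": [["Ascorbic Acid", "Ascorbate"]],
        }
    )


# ---------------------------------------------------------------------
# allergy-rule fixture
# ---------------------------------------------------------------------

LACTOSE_RULE = (
    "Consumer(?c), Has_Allergy(?c, Lactose_Allergy), Has_Ean_No(?c, ?p), "
    "Has_Product_Additives_Name(?p, Aluminium_Silicate) "
    "-> HAS_LACTOSE_RISK(?c, Aluminium_Silicate)"
)

_PACKAGED_RULE_TEXTS = [
    LACTOSE_RULE,
    "Consumer(?c), Has_Allergy(?c, Gluten_Allergy), Has_Ean_No(?c, ?p), "
    "Has_Product_Ingredient_Name(?p, Wheat_Starch) -> HAS_GLUTEN_RISK(?c, Wheat_Starch)",
    "Consumer(?c), Has_Allergy(?c, Gluten_Allergy), Has_Ean_No(?c, ?p), "
    "Has_Product_Ingredient_Name(?p, Malt_Extract) -> HAS_GLUTEN_RISK(?c, Malt_Extract)",
    "Consumer(?c), Has_Allergy(?c, Fish_Allergy), Has_Ean_No(?c, ?p), "
    "Has_Product_Ingredient_Name(?p, Fish_Gelatine) -> HAS_FISH_RISK(?c, Fish_Gelatine)",
    "Consumer(?c), Has_Allergy(?c, Egg_Allergy), Has_Ean_No(?c, ?p), "
    "Has_Product_Ingredient_Name(?p, Albumen) -> HAS_EGG_RISK(?c, Albumen)",
    "Consumer(?c), Has_Allergy(?c, Egg_Allergy), Has_Ean_No(?c, ?p), "
    "Has_Product_Ingredient_Name(?p, Lysozyme) -> HAS_EGG_RISK(?c, Lysozyme)",
]


def packaged_rules() -> list[Rule]:
    """Representative rule set covering the four allergy-risk families."""
    return [parse_rule(t) for t in _PACKAGED_RULE_TEXTS]


def allergy_rules_graph() -> OntologyGraph:
    """Additive neighbourhood used for rule-concept expansion.

    Aluminium silicate (synonym Kaolin) with the three E-coded salt
    subclasses — sodium (E554), potassium (E555) and calcium (E556)
    aluminium silicate.
    """
    return graph_from_dict(
        {
            "concepts": [
                "Aluminium Silicate", "Kaolin",
                "Sodium Aluminium Silicate", "E554",
                "Potassium Aluminium Silicate", "E555",
                "Calcium Aluminium Silicate", "E556",
            ],
            "subclass": [
                ["Aluminium Silicate", "Sodium Aluminium Silicate"],
                ["Aluminium Silicate", "Potassium Aluminium Silicate"],
                ["Aluminium Silicate", "Calcium Aluminium Silicate"],
            ],
            "synonyms": [
                ["Aluminium Silicate", "Kaolin"],
                ["Sodium Aluminium Silicate", "E554"],
                ["Potassium Aluminium Silicate", "E555"],
                ["Calcium Aluminium Silicate", "E556"],
            ],
        }
    )


def lactose_fact_base(additive: str = "Aluminium_Silicate") -> FactBase:
    """Ground facts of the lactose-allergy scenario for one additive."""
    return FactBase(
        [
            Atom("Consumer", ("c",)),
            Atom("Has_Allergy", ("c", "Lactose_Allergy")),
            Atom("Has_Ean_No", ("c", "p")),
            Atom("Has_Product_Additives_Name", ("p", additive)),
        ]
    )


# ---------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic ontology/product generator.

    The defaults emulate the fixture scale the matching engine is designed
    for: shallow hierarchies (food-additive taxonomies are 2-4 levels
    deep), a couple of direct children per class, and synonym/E-code
    aliasing on roughly a third of concepts.
    """

    depth: int = 3
    branching: tuple[int, int] = (1, 3)
    synonym_rate: float = 0.3
    group_rate: float = 0.1
    n_products: int = 2
    ingredients_per_product: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.synonym_rate, self.group_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth < 1 or self.branching[0] < 1:
            raise ValueError("depth and branching must be positive")


def random_ontology(params: GeneratorParams) -> OntologyGraph:
    """Seeded layered hierarchy with synonym and group edges.

    The subclass relation is a forest built layer by layer (acyclic by
    construction); synonyms alias concepts with generated E-code-style
    names; groups attach a fraction of layer-one concepts to fresh group
    nodes.  Identical params (including seed) give identical graphs.
    """
    rng = random.Random(params.seed)
    graph = OntologyGraph()
    counter = itertools.count()

    def fresh(prefix: str) -> str:
        return f"{prefix}{next(counter):03d}"

    layers: list[list[str]] = [[graph.add_concept(fresh("Root")).label]]
    for _ in range(params.depth):
        layer: list[str] = []
        for parent in layers[-1]:
            for _ in range(rng.randint(*params.branching)):
                child = graph.add_concept(fresh("Concept")).label
                graph.add_subclass(parent, child)
                layer.append(child)
        if not layer:
            break
        layers.append(layer)
    for node in [n for layer in layers for n in layer]:
        if rng.random() < params.synonym_rate:
            alias = graph.add_concept(fresh("E"), kind="individual").label
            graph.add_synonym(node, alias)
    for node in layers[min(1, len(layers) - 1)]:
        if rng.random() < params.group_rate:
            group = graph.add_concept(fresh("Group")).label
            graph.add_group(node, group)
    graph.validate()
    return graph


def random_concept_lists(
    graph: OntologyGraph, rng: random.Random, max_size: int = 8
) -> tuple[list[str], list[str]]:
    """Two random concept lists over *graph* for matcher property tests."""
    labels = sorted(c.label for c in graph.concepts)
    n_c = rng.randint(1, min(max_size, len(labels)))
    n_p = rng.randint(1, min(max_size, len(labels)))
    return rng.sample(labels, n_c), rng.sample(labels, n_p)


def random_fact_base(rng: random.Random, n_facts: int = 12) -> FactBase:
    """Small random ground-atom set over a handful of individuals."""
    preds1 = ["Consumer", "Product", "Additive"]
    preds2 = ["Has_Allergy", "Has_Ean_No", "Has_Product_Additives_Name", "Likes"]
    individuals = [f"i{k}" for k in range(rng.randint(2, 6))]
    facts = FactBase()
    for _ in range(n_facts):
        if rng.random() < 0.4:
            facts.add(Atom(rng.choice(preds1), (rng.choice(individuals),)))
        else:
            facts.add(
                Atom(rng.choice(preds2), (rng.choice(individuals), rng.choice(individuals)))
            )
    return facts


# ---------------------------------------------------------------------
# oracles (naive re-derivations for cross-checking)
# ---------------------------------------------------------------------


def oracle_match(
    graph: OntologyGraph,
    consumer: Sequence[str],
    product: Sequence[str],
    config: MatchConfig = MatchConfig(),
) -> list[PairMatch]:
    """Reference pairing for the greedy matcher, brute-force per step.

    At every step the chosen partner's degree is verified to be maximal
    over *all* remaining candidates by explicit enumeration (an
    ``AssertionError`` would flag a broken greedy step).  Independent of
    :func:`semfood.cme.greedy_match`'s selection logic.
    """
    c_left = [graph.resolve(t) for t in consumer]
    p_left = [(j, graph.resolve(t)) for j, t in enumerate(product)]
    pairs: list[PairMatch] = []
    for cc in c_left:
        if not p_left:
            break
        scored = []
        for j, pc in p_left:
            relation, weight, distance = classify_relation(graph, cc, pc, config)
            scored.append((relation.degree, pair_term(relation, weight, distance), -j,
                           (j, pc, relation, weight, distance)))
        scored.sort(key=lambda s: s[:3])
        best = scored[-1]
        assert all(s[0] <= best[0] for s in scored), "greedy step not maximal"
        j, pc, relation, weight, distance = best[3]
        pairs.append(PairMatch(cc, pc, relation, weight, distance))
        p_left = [(jj, q) for jj, q in p_left if jj != j]
    for cc in c_left[len(pairs):]:
        pairs.append(PairMatch(cc, None, Relation.DISSIMILAR, 0.0, None))
    for _, pc in p_left:
        pairs.append(PairMatch(None, pc, Relation.DISSIMILAR, 0.0, None))
    return pairs


def oracle_path(graph: OntologyGraph, a: str, z: str) -> Optional[tuple[float, int]]:
    """Exhaustive simple-chain search through the hierarchy.

    Enumerates every simple path in the undirected view of the
    subclass+group quotient graph and picks minimum edge count, breaking
    ties by maximum weight product.  Returns ``None`` when no chain
    exists.  Exponential — only for graphs of a few dozen concepts.
    """
    ca = graph._canon(graph.resolve(a).id)
    cz = graph._canon(graph.resolve(z).id)
    if graph.resolve(a).id == graph.resolve(z).id:
        return 1.0, 0
    if ca == cz:
        return 1.0, 1
    best: Optional[tuple[int, float]] = None

    def neighbours(node: str) -> list[tuple[str, float]]:
        out = [(c, graph._canon_edge_weight(node, c)) for c in graph._hier_children(node)]
        out += [(p, graph._canon_edge_weight(p, node)) for p in graph._hier_parents(node)]
        return out

    def walk(node: str, seen: frozenset[str], weight: float, length: int) -> None:
        nonlocal best
        if node == cz:
            cand = (length, weight)
            if best is None or length < best[0] or (length == best[0] and weight > best[1]):
                best = cand
            return
        if best is not None and length >= best[0]:
            return
        for neigh, w in neighbours(node):
            if neigh not in seen:
                walk(neigh, seen | {neigh}, weight * w, length + 1)

    walk(ca, frozenset({ca}), 1.0, 0)
    return None if best is None else (best[1], best[0])


def oracle_saturate(facts: FactBase, rules: Sequence[Rule]) -> FactBase:
    """Naive saturation: try every grounding over the individuals.

    Instantiates each rule with every tuple of known individuals (plus
    numeric literals already present) and asserts heads whose bodies hold,
    looping until stable.  Much slower than the engine's pattern matcher
    but shares no code with it.
    """
    from .rules import _eval_builtin

    result = facts.copy()
    while True:
        individuals = sorted(result.individuals())
        added = False
        for rule in rules:
            variables = sorted({v for a in rule.body for v in a.variables})
            for combo in itertools.product(individuals, repeat=len(variables)):
                binding = dict(zip(variables, combo))

                def ground(atom: Atom) -> Atom:
                    return Atom(atom.predicate, tuple(binding.get(x, x) for x in atom.args))

                ok = True
                for atom in rule.body:
                    if atom.is_builtin:
                        if not _eval_builtin(atom, binding):
                            ok = False
                            break
                    elif ground(atom) not in result:
                        ok = False
                        break
                if not ok:
                    continue
                for head in rule.head:
                    fact = ground(head)
                    if fact not in result:
                        result.add(fact)
                        added = True
        if not added:
            return result
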