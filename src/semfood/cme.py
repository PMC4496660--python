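"""Concept matching engine: relation degrees, greedy matching, scoring.

Two concept lists are compared: the semantically enhanced consumer
intolerance list C and the product ingredient list P.  Each candidate pair
(C_i, P_j) receives one of four matchmaking degrees

    Exact = 1,  Plugin = 0.75,  Subsume = 0.5,  Dissimilar = 0

and a hierarchy weight/distance.  A greedy pass over C picks, per consumer
concept, the remaining product concept with the highest degree.  The
matched degrees aggregate through a modified Jaro–Winkler factor

    d_j = (m/n_C + m/n_P) / 2
    d_w = d_j + l * k * (1 - d_j)

with m the summed degrees, l the number of non-Dissimilar pairs and
k the Winkler scaling constant (0.1).  The final intolerance score is

    IntoleranceScore(C, P) = sum_i degree_i * weight_i / distance_i
                             -----------------------------------
                                      (n_C / n_P) * d_w

and the integer intolerance percentage is floor(score * 100 / n_pairs).

Two direction conventions are supported for Plugin/Subsume because the
source material uses both: in ``example`` mode a consumer concept *above*
the product concept is Plugin and one *below* is Subsume (the convention
behind the worked product scores); ``definition`` mode swaps them.
Sibling concepts under a common ancestor are Subsume in both modes.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .enhancement import ConsumerProfile, EnhancedList, Product, enhance
from .ontology import Concept, NotConnected, OntologyGraph

__all__ = [
    "Relation",
    "MatchConfig",
    "PairMatch",
    "MatchResult",
    "classify_relation",
    "pair_term",
    "greedy_match",
    "jaro",
    "winkler",
    "intolerance_score",
    "percentage",
    "evaluate",
]


@functools.total_ordering
class Relation(Enum):
    """Degree of match between two concepts, ordered by strength."""

    DISSIMILAR = 0.0
    SUBSUME = 0.5
    PLUGIN = 0.75
    EXACT = 1.0

    @property
    def degree(self) -> float:
        return self.value

    def __lt__(self, other: "Relation") -> bool:
        return self.value < other.value

    def __str__(self) -> str:
        return self.name.capitalize()


@dataclass(frozen=True)
class MatchConfig:
    """Tunable knobs of the matching engine.

    winkler_k: Winkler scaling constant; 0.1 is the standard value.
    convention: "example" or "definition" Plugin/Subsume direction.
    enhance_relations: relations applied to the consumer terms before
        matching; empty means the terms are used verbatim (they are then
        taken to be an already-enhanced list C).
    """

    winkler_k: float = 0.1
    convention: str = "example"
    enhance_relations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.winkler_k < 0:
            raise ValueError("winkler_k must be >= 0")
        if self.convention not in ("example", "definition"):
            raise ValueError(f"unknown convention: {self.convention!r}")


@dataclass(frozen=True)
class PairMatch:
    """One matched (C_i, P_j) pair with its scoring ingredients."""

    c_concept: Optional[Concept]  # None on the padded side
    p_concept: Optional[Concept]
    relation: Relation
    d_weight: float
    distance: Optional[int]  # None for Dissimilar (no connecting chain)

    @property
    def term(self) -> float:
        """Contribution degree * weight / distance, 0 for Dissimilar."""
        if self.relation is Relation.DISSIMILAR:
            return 0.0
        d = max(self.distance or 0, 1)  # identical concepts count one step
        return self.relation.degree * self.d_weight / d


@dataclass
class MatchResult:
    """Everything the engine derives for one consumer/product comparison."""

    pairs: list[PairMatch]
    n_c: int
    n_p: int
    m: float
    l: int
    d_j: float
    d_w: float
    score: float
    percentage: int
    enhanced: Optional[EnhancedList] = None
    unresolved_ingredients: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------
# relation classification
# ---------------------------------------------------------------------


def classify_relation(
    graph: OntologyGraph,
    c: str | Concept,
    p: str | Concept,
    config: MatchConfig = MatchConfig(),
) -> tuple[Relation, float, Optional[int]]:
    """Classify the degree of match of consumer concept *c* vs product *p*.

    Returns ``(relation, d_weight, distance)``.  Identical or
    synonym-equivalent concepts are Exact; hierarchy-connected ones are
    Plugin or Subsume depending on direction and convention; unconnected
    ones are Dissimilar with weight 0 and no distance.
    """
    cc = graph.resolve(c if isinstance(c, str) else c.id)
    pc = graph.resolve(p if isinstance(p, str) else p.id)
    if cc.id == pc.id:
        return Relation.EXACT, 1.0, 0
    if graph.are_synonyms(cc.id, pc.id):
        return Relation.EXACT, 1.0, 1
    try:
        weight, distance = graph.path_weight(cc.id, pc.id)
    except NotConnected:
        return Relation.DISSIMILAR, 0.0, None
    c_above = graph.is_ancestor(cc.id, pc.id)
    p_above = graph.is_ancestor(pc.id, cc.id)
    if not c_above and not p_above:
        # siblings below a common ancestor: Subsume either way round
        return Relation.SUBSUME, weight, distance
    if config.convention == "example":
        relation = Relation.PLUGIN if c_above else Relation.SUBSUME
    else:
        relation = Relation.PLUGIN if p_above else Relation.SUBSUME
    return relation, weight, distance


def pair_term(relation: Relation, d_weight: float, distance: Optional[int]) -> float:
    """Scoring contribution of one pair: degree * weight / distance."""
    return PairMatch(None, None, relation, d_weight, distance).term


# ---------------------------------------------------------------------
# greedy max matching
# ---------------------------------------------------------------------


def greedy_match(
    graph: OntologyGraph,
    consumer: EnhancedList | Sequence[str | Concept],
    product: Sequence[str | Concept],
    config: MatchConfig = MatchConfig(),
) -> list[PairMatch]:
    """Sequential best-degree matching of C against P.

    Walks C in order; each C_i is classified against every still-unmatched
    P_j and paired with the highest-degree one (ties: larger contribution
    term, then lowest P index); both are then removed.  Afterwards the
    shorter side is padded with null partners so the pair list has
    ``max(|C|, |P|)`` entries.
    """
    c_list = list(consumer.concepts) if isinstance(consumer, EnhancedList) else [
        graph.resolve(t if isinstance(t, str) else t.id) for t in consumer
    ]
    p_list = [graph.resolve(t if isinstance(t, str) else t.id) for t in product]

    remaining = list(enumerate(p_list))
    pairs: list[PairMatch] = []
    for cc in c_list:
        if not remaining:
            break
        best_idx = None
        best_key: tuple[float, float, float] | None = None
        best_cls = None
        for slot, (j, pc) in enumerate(remaining):
            relation, weight, distance = classify_relation(graph, cc, pc, config)
            term = pair_term(relation, weight, distance)
            key = (relation.degree, term, -j)
            if best_key is None or key > best_key:
                best_key, best_idx, best_cls = key, slot, (pc, relation, weight, distance)
        assert best_cls is not None and best_idx is not None
        pc, relation, weight, distance = best_cls
        pairs.append(PairMatch(cc, pc, relation, weight, distance))
        del remaining[best_idx]
    matched_c = len(pairs)
    # pad: leftover consumer concepts and leftover product concepts each
    # pair with a null partner at degree 0
    for cc in c_list[matched_c:]:
        pairs.append(PairMatch(cc, None, Relation.DISSIMILAR, 0.0, None))
    for _, pc in remaining:
        pairs.append(PairMatch(None, pc, Relation.DISSIMILAR, 0.0, None))
    return pairs


# ---------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------


def jaro(m: float, n_c: int, n_p: int) -> float:
    """Modified Jaro factor over summed degrees: (m/n_C + m/n_P) / 2."""
    if n_c < 1 or n_p < 1:
        raise ValueError("jaro undefined for empty lists")
    return 0.5 * (m / n_c + m / n_p)


def winkler(d_j: float, l: int, k: float = 0.1) -> float:
    """Winkler adjustment d_w = d_j + l*k*(1 - d_j), clamped to 1."""
    if l < 0 or k < 0:
        raise ValueError("l and k must be nonnegative")
    return min(1.0, d_j + l * k * (1.0 - d_j))


def intolerance_score(
    pairs: Sequence[PairMatch], d_w: float, n_c: int, n_p: int
) -> float:
    """Aggregate score: sum of pair terms over ((n_C/n_P) * d_w).

    A comparison with no matched pair at all (m = 0, hence d_w = 0 when
    k*l contributes nothing) scores 0 — the singular division is defined
    away because an all-Dissimilar product carries no intolerance signal.
    """
    total = sum(p.term for p in pairs)
    denom = (n_c / n_p) * d_w
    if denom == 0:
        return 0.0
    return total / denom


def percentage(score: float, n_pairs: int) -> int:
    """Integer intolerance percentage: floor(score*100 / n_pairs), in [0,100]."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return max(0, min(100, math.floor(score * 100.0 / n_pairs)))


# ---------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------


def evaluate(
    graph: OntologyGraph,
    consumer: ConsumerProfile | Sequence[str],
    product: Product | Sequence[str],
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Run the full pipeline: enhance, match, aggregate, summarize.

    With ``config.enhance_relations`` empty the consumer's intolerance
    terms are taken as the already-enhanced list C; otherwise they are
    expanded first.  Product ingredients that the ontology does not know
    are reported in ``unresolved_ingredients`` and matched as nothing.
    """
    import warnings

    terms = consumer.intolerances if isinstance(consumer, ConsumerProfile) else list(consumer)
    ingredients = product.ingredients if isinstance(product, Product) else list(product)

    if config.enhance_relations:
        enhanced = enhance(graph, terms, config.enhance_relations)
    else:
        enhanced = enhance(graph, terms, frozenset())

    p_concepts: list[Concept] = []
    unresolved: list[str] = []
    for term in ingredients:
        try:
            p_concepts.append(graph.resolve(term))
        except Exception:
            unresolved.append(term)
            warnings.warn(f"product ingredient not in ontology: {term!r}")

    pairs = greedy_match(graph, enhanced, p_concepts, config)
    n_c = max(len(enhanced), 1)
    n_p = max(len(p_concepts), 1)
    m = sum(p.relation.degree for p in pairs)
    l = sum(1 for p in pairs if p.relation is not Relation.DISSIMILAR)
    d_j = jaro(m, n_c, n_p)
    d_w = winkler(d_j, l, config.winkler_k) if m > 0 else 0.0
    score = intolerance_score(pairs, d_w, n_c, n_p)
    n_pairs = max(len(pairs), 1)
    pct = percentage(score, n_pairs)
    return MatchResult(
        pairs=pairs,
        n_c=n_c,
        n_p=n_p,
        m=m,
        l=l,
        d_j=d_j,
        d_w=d_w,
        score=score,
        percentage=pct,
        enhanced=enhanced,
        unresolved_ingredients=unresolved,
    )
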