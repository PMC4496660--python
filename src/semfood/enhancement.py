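"""Semantic enhancement of a consumer's intolerance terms.

Packaging labels rarely use one canonical name per substance: "Vitamin C",
"E300", "L-Ascorbic Acid" and "Ascorbate" all point at ascorbic acid.  The
first stage of the matching engine therefore expands the raw intolerance
terms into the *semantically enhanced consumer intolerance list* C by
following synonym links (to their full closure), group membership and
direct is-a parents (one hop each by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .ontology import Concept, ConceptNotFound, OntologyGraph

__all__ = ["EnhancedList", "ConsumerProfile", "Product", "enhance", "EmptyEnhancedList"]

DEFAULT_RELATIONS = frozenset({"synonym", "group", "is_a"})


class EmptyEnhancedList(Exception):
    """No source term resolved against the ontology."""


@dataclass
class EnhancedList:
    """The list C: seed concepts plus their semantic expansions.

    ``provenance`` records, per concept id, which relation introduced it
    (``seed``, ``synonym``, ``group`` or ``is_a``); seeds always win when a
    concept is reachable more than one way.
    """

    source_terms: list[str]
    concepts: list[Concept]
    provenance: dict[str, str]
    unresolved: list[str] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [c.id for c in self.concepts]

    def __len__(self) -> int:
        return len(self.concepts)


def enhance(
    graph: OntologyGraph,
    terms: Sequence[str],
    relations: Iterable[str] = DEFAULT_RELATIONS,
    hops: int = 1,
) -> EnhancedList:
    """Expand intolerance *terms* into the enhanced list C.

    Synonyms are always chased to their full equivalence class; ``group``
    and ``is_a`` expansion walk *hops* levels up (default one, which stops
    an ascorbic-acid seed at "Ascorbate" without dragging in "Antioxidant").
    Terms absent from the ontology are recorded in ``unresolved`` and
    warned about rather than raised — free-text labels are noisy.
    """
    if not terms:
        raise ValueError("terms must be nonempty")
    relations = frozenset(relations)
    unknown = relations - DEFAULT_RELATIONS
    if unknown:
        raise ValueError(f"unknown enhancement relations: {sorted(unknown)}")

    ordered: list[str] = []  # concept ids in insertion order
    provenance: dict[str, str] = {}
    unresolved: list[str] = []

    def add(cid: str, how: str) -> None:
        if cid not in provenance:
            provenance[cid] = how
            ordered.append(cid)

    for term in terms:
        try:
            seed = graph.resolve(term)
        except ConceptNotFound:
            unresolved.append(term)
            warnings.warn(f"intolerance term not in ontology: {term!r}")
            continue
        add(seed.id, "seed")
        frontier = {seed.id}
        if "synonym" in relations:
            for cid in sorted(graph.synonym_class(seed.id)):
                add(cid, "synonym")
            frontier = set(graph.synonym_class(seed.id))
        for _ in range(hops):
            nxt: set[str] = set()
            for cid in sorted(frontier):
                if "group" in relations:
                    for _, member, group in sorted(
                        (0, m, g) for m, g in graph.group_edges if m == cid
                    ):
                        add(group, "group")
                        nxt.add(group)
                if "is_a" in relations:
                    for parent, child in sorted(graph.subclass_edges):
                        if child == cid:
                            add(parent, "is_a")
                            nxt.add(parent)
            frontier = nxt

    concepts = [graph.resolve(cid) for cid in ordered]
    if not concepts:
        raise EmptyEnhancedList(f"none of {list(terms)!r} resolved")
    return EnhancedList(list(terms), concepts, provenance, unresolved)


# ---------------------------------------------------------------------
# consumer profile / product records
# ---------------------------------------------------------------------


@dataclass
class ConsumerProfile:
    """A consumer: intolerance terms, declared allergies, optional vitals."""

    id: str
    intolerances: list[str] = field(default_factory=list)
    allergies: list[str] = field(default_factory=list)
    bmi: Optional[float] = None
    bmr: Optional[float] = None
    activity_level: Optional[float] = None
    blood_pressure: Optional[tuple[float, float]] = None  # (low, high)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ConsumerProfile":
        bp = data.get("blood_pressure")
        return cls(
            id=str(data.get("id", "consumer")),
            intolerances=list(data.get("intolerances", [])),
            allergies=list(data.get("allergies", [])),
            bmi=data.get("bmi"),
            bmr=data.get("bmr"),
            activity_level=data.get("activity_level"),
            blood_pressure=tuple(bp) if bp else None,  # type: ignore[arg-type]
        )

    def to_dict(self) -> dict:
        out: dict = {"id": self.id, "intolerances": self.intolerances}
        if self.allergies:
            out["allergies"] = self.allergies
        for key in ("bmi", "bmr", "activity_level"):
            if getattr(self, key) is not None:
                out[key] = getattr(self, key)
        if self.blood_pressure is not None:
            out["blood_pressure"] = list(self.blood_pressure)
        return out

    @classmethod
    def load(cls, path) -> "ConsumerProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class Product:
    """A packaged product: EAN barcode string plus ingredient terms."""

    ean: str
    ingredients: list[str]
    name: Optional[str] = None

    @classmethod
    def from_dict(cls, data: Mapping) -> "Product":
        return cls(
            ean=str(data.get("ean", "")),
            ingredients=list(data.get("ingredients", [])),
            name=data.get("name"),
        )

    def to_dict(self) -> dict:
        out: dict = {"ean": self.ean, "ingredients": self.ingredients}
        if self.name:
            out["name"] = self.name
        return out

    @classmethod
    def load(cls, path) -> "Product":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
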