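"""Food ontology graph: concepts, hierarchy, synonyms and weighted distances.

The knowledge base is a small graph over food ingredients, additives and
compounds.  Three relation families matter for matching:

* **subclass** (is-a) edges, directed parent -> child;
* **synonym** edges, undirected — "Ascorbic Acid", "E300" and "Vitamin C"
  denote the same substance;
* **group** edges, member -> group ("Ascorbic Acid" belongs to the
  "Ascorbate" group); for traversal a group behaves like a superclass of
  its members.

Every direct subclass edge of a parent with *n* direct children carries the
weight ``1/n`` unless the ontology developer supplied an explicit override.
The weight of a path is the product of its edge weights and its distance is
its edge count; synonym-equivalent concepts are one step apart at weight 1.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import yaml
from lxml import etree

__all__ = [
    "Concept",
    "OntologyGraph",
    "OntologyError",
    "ConceptNotFound",
    "NotConnected",
    "ValidationError",
    "normalize",
    "load_owlxml",
    "save_owlxml",
    "load_fixture",
    "save_fixture",
]

# Object properties of the knowledge base that the loaders map onto typed
# edges; anything else lands in ``property_assertions`` untouched.
SYNONYM_PROPERTIES = frozenset({"has synonym", "hassynonym"})
GROUP_PROPERTIES = frozenset({"has group", "hasgroup"})

_WS = re.compile(r"\s+")


class OntologyError(Exception):
    """Base class for ontology-layer failures."""


class ConceptNotFound(OntologyError, KeyError):
    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"unknown concept: {self.term!r}"


class NotConnected(OntologyError):
    """Raised when two concepts share no chain through the hierarchy."""


class ValidationError(OntologyError):
    pass


def normalize(term: str) -> str:
    """Canonical form of a concept name.

    Case-folds, trims, collapses internal whitespace and maps underscores
    to spaces, so ``"Ascorbic_Acid"``, ``"ascorbic  acid"`` and
    ``"Ascorbic Acid"`` all share one key.
    """
    return _WS.sub(" ", term.replace("_", " ").strip()).casefold()


@dataclass(frozen=True)
class Concept:
    """A named class or individual of the food ontology."""

    id: str  # normalized key, unique per graph
    label: str  # display form as first declared
    kind: str = "class"  # "class" | "individual"
    annotations: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __str__(self) -> str:
        return self.label


class OntologyGraph:
    """Concepts plus typed edges, with Eq.-style distance weighting.

    Synonym edges induce an equivalence relation; hierarchy traversal works
    on the quotient graph (one node per synonym class), which is what lets
    "Vitamin C" inherit the subclasses of "Ascorbic Acid".
    """

    def __init__(self) -> None:
        self._concepts: dict[str, Concept] = {}
        self.subclass_edges: set[tuple[str, str]] = set()  # (parent, child)
        self.synonym_edges: set[tuple[str, str]] = set()  # stored sorted
        self.group_edges: set[tuple[str, str]] = set()  # (member, group)
        self.property_assertions: set[tuple[str, str, str]] = set()
        self.weight_overrides: dict[tuple[str, str], float] = {}
        self._syn_root: dict[str, str] | None = None  # lazy union-find cache

    # -- construction -------------------------------------------------

    def add_concept(
        self,
        label: str,
        kind: str = "class",
        annotations: Optional[Mapping[str, str]] = None,
    ) -> Concept:
        cid = normalize(label)
        existing = self._concepts.get(cid)
        if existing is not None:
            # individual+class double declarations collapse onto one node
            if annotations:
                merged = dict(existing.annotations)
                merged.update(annotations)
                existing = Concept(cid, existing.label, existing.kind, merged)
                self._concepts[cid] = existing
            return existing
        concept = Concept(cid, label.replace("_", " ").strip(), kind, dict(annotations or {}))
        self._concepts[cid] = concept
        return concept

    def _require(self, label: str) -> str:
        cid = normalize(label)
        if cid not in self._concepts:
            raise ValidationError(f"edge endpoint not declared: {label!r}")
        return cid

    def add_subclass(self, parent: str, child: str) -> None:
        self.subclass_edges.add((self._require(parent), self._require(child)))

    def add_synonym(self, a: str, b: str) -> None:
        edge = tuple(sorted((self._require(a), self._require(b))))
        self.synonym_edges.add(edge)  # type: ignore[arg-type]
        self._syn_root = None

    def add_group(self, member: str, group: str) -> None:
        self.group_edges.add((self._require(member), self._require(group)))

    def add_property(self, prop: str, subject: str, obj: str) -> None:
        self.property_assertions.add(
            (normalize(prop), self._require(subject), self._require(obj))
        )

    def set_weight(self, parent: str, child: str, weight: float) -> None:
        """Developer-scored distance for one hierarchy edge; wins over 1/n."""
        edge = (self._require(parent), self._require(child))
        if edge not in self.subclass_edges and (edge[1], edge[0]) not in self.group_edges:
            raise ValidationError(f"weight override on non-hierarchy edge {edge}")
        if not 0 < weight <= 1:
            raise ValidationError(f"edge weight must be in (0, 1]: {weight}")
        self.weight_overrides[edge] = weight

    # -- queries ------------------------------------------------------

    @property
    def concepts(self) -> Iterator[Concept]:
        return iter(self._concepts.values())

    def __len__(self) -> int:
        return len(self._concepts)

    def __contains__(self, term: str) -> bool:
        return normalize(term) in self._concepts

    def resolve(self, term: str) -> Concept:
        """Look up a concept by (normalized) name.

        Does not cross synonym edges: "E300" resolves to the E300 node, not
        to Ascorbic Acid — synonym handling belongs to the matching engine.
        """
        try:
            return self._concepts[normalize(term)]
        except KeyError:
            raise ConceptNotFound(term) from None

    def synonym_class(self, term: str) -> frozenset[str]:
        """All concept ids synonym-equivalent to *term* (reflexive closure)."""
        cid = self.resolve(term).id
        root = self._synonym_roots()[cid]
        return frozenset(c for c, r in self._synonym_roots().items() if r == root)

    def are_synonyms(self, a: str, b: str) -> bool:
        roots = self._synonym_roots()
        return roots[self.resolve(a).id] == roots[self.resolve(b).id]

    def _synonym_roots(self) -> dict[str, str]:
        if self._syn_root is None:
            parent = {c: c for c in self._concepts}

            def find(x: str) -> str:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in self.synonym_edges:
                ra, rb = find(a), find(b)
                if ra != rb:
                    # deterministic representative: lexicographic min
                    lo, hi = sorted((ra, rb))
                    parent[hi] = lo
            self._syn_root = {c: find(c) for c in self._concepts}
        return self._syn_root

    # hierarchy edges on the synonym-quotient graph ---------------------

    def _canon(self, cid: str) -> str:
        return self._synonym_roots()[cid]

    def _hier_children(self, root: str) -> set[str]:
        """Canonical children of a canonical node via subclass/group edges."""
        roots = self._synonym_roots()
        out: set[str] = set()
        for p, c in self.subclass_edges:
            if roots[p] == root:
                out.add(roots[c])
        for m, g in self.group_edges:  # group acts as parent of member
            if roots[g] == root:
                out.add(roots[m])
        out.discard(root)
        return out

    def _hier_parents(self, root: str) -> set[str]:
        roots = self._synonym_roots()
        out: set[str] = set()
        for p, c in self.subclass_edges:
            if roots[c] == root:
                out.add(roots[p])
        for m, g in self.group_edges:
            if roots[m] == root:
                out.add(roots[g])
        out.discard(root)
        return out

    def edge_weight(self, parent: str, child: str) -> float:
        """Weight of one direct hierarchy edge.

        Returns the developer override when present, else ``1/n`` where *n*
        is the parent's number of direct children (subclass plus group
        members), so sibling edges share one weight and sum to 1.
        """
        p, c = self.resolve(parent).id, self.resolve(child).id
        override = self.weight_overrides.get((p, c))
        if override is not None:
            return override
        roots = self._synonym_roots()
        rp, rc = roots[p], roots[c]
        children = self._hier_children(rp)
        if rc not in children:
            raise OntologyError(f"{parent!r} -> {child!r} is not a direct hierarchy edge")
        # an override on any same-class representation of the edge wins
        for pp, cc in self.weight_overrides:
            if roots[pp] == rp and roots[cc] == rc:
                return self.weight_overrides[(pp, cc)]
        return 1.0 / len(children)

    def _canon_edge_weight(self, rp: str, rc: str) -> float:
        for (pp, cc), w in self.weight_overrides.items():
            roots = self._synonym_roots()
            if roots[pp] == rp and roots[cc] == rc:
                return w
        return 1.0 / len(self._hier_children(rp))

    def path_weight(self, a: str, z: str) -> tuple[float, int]:
        """Weight and distance of the shortest hierarchy chain from a to z.

        Identical concepts give ``(1, 0)``; synonym-equivalent ones
        ``(1, 1)``.  Otherwise the chain runs through subclass/group edges
        (traversed in either direction, each contributing its parent-side
        1/n weight); the weight is the product along the chain and the
        distance its edge count.  Ties on edge count resolve to the maximum
        weight product, then lexicographically on the node sequence.

        Raises :class:`NotConnected` when no chain exists.
        """
        ca, cz = self.resolve(a).id, self.resolve(z).id
        if ca == cz:
            return 1.0, 0
        ra, rz = self._canon(ca), self._canon(cz)
        if ra == rz:
            return 1.0, 1
        # BFS by edge count; among equal-length paths keep max product,
        # breaking residual ties on the lexicographically least path.
        best: dict[str, tuple[int, float, tuple[str, ...]]] = {
            ra: (0, 1.0, (ra,))
        }
        frontier = {ra}
        dist = 0
        while frontier and rz not in best:
            dist += 1
            nxt: dict[str, tuple[float, tuple[str, ...]]] = {}
            for node in frontier:
                _, wt, path = best[node]
                steps = [(c, wt * self._canon_edge_weight(node, c)) for c in self._hier_children(node)]
                steps += [(p, wt * self._canon_edge_weight(p, node)) for p in self._hier_parents(node)]
                for neigh, w in steps:
                    if neigh in best:
                        continue
                    cur = nxt.get(neigh)
                    if (
                        cur is None
                        or w > cur[0]
                        or (w == cur[0] and path + (neigh,) < cur[1])
                    ):
                        nxt[neigh] = (w, path + (neigh,))
            for node, (w, path) in nxt.items():
                best[node] = (dist, w, path)
            frontier = set(nxt)
        if rz not in best:
            raise NotConnected(f"no hierarchy chain between {a!r} and {z!r}")
        d, w, _ = best[rz]
        return w, d

    def is_ancestor(self, a: str, b: str) -> bool:
        """True when *a*'s synonym class lies strictly above *b*'s."""
        ra = self._canon(self.resolve(a).id)
        rb = self._canon(self.resolve(b).id)
        if ra == rb:
            return False
        seen = {rb}
        queue = deque([rb])
        while queue:
            node = queue.popleft()
            for p in self._hier_parents(node):
                if p == ra:
                    return True
                if p not in seen:
                    seen.add(p)
                    queue.append(p)
        return False

    def validate(self) -> None:
        """Check structural invariants: acyclic hierarchy, known endpoints."""
        children: dict[str, set[str]] = {}
        for p, c in self.subclass_edges | {(g, m) for m, g in self.group_edges}:
            children.setdefault(p, set()).add(c)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for c in children.get(node, ()):
                if state.get(c) == 1:
                    raise ValidationError(f"subclass cycle through {node!r}")
                if c not in state:
                    visit(c)
            state[node] = 2

        for node in list(children):
            if node not in state:
                visit(node)

    # -- equality (content-wise, for round-trip tests) ------------------

    def content(self) -> tuple:
        return (
            frozenset(self._concepts),
            frozenset(self.subclass_edges),
            frozenset(self.synonym_edges),
            frozenset(self.group_edges),
            frozenset(self.property_assertions),
            frozenset(self.weight_overrides.items()),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return self.content() == other.content()

    def __hash__(self) -> int:  # content is mutable; identity hash
        return id(self)


# ---------------------------------------------------------------------
# OWL/XML subset reader / writer
# ---------------------------------------------------------------------

def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _iri(el) -> str:
    iri = el.get("IRI", "")
    return iri.lstrip("#")


def load_owlxml(path) -> OntologyGraph:
    """Read the OWL/XML dialect used by the knowledge base.

    Supported elements: ``Declaration`` (Class, NamedIndividual),
    ``ClassAssertion``, ``SubClassOf`` (child listed first, parent second)
    and ``ObjectPropertyAssertion``.  ``Has_Synonym`` assertions become
    synonym edges, ``Has_Group`` group edges and everything else is kept as
    a raw property assertion.  Unknown element kinds are skipped with a
    warning; references to undeclared IRIs are a validation error.
    """
    import warnings

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise OntologyError(f"malformed OWL/XML in {path}: {exc}") from exc
    root = tree.getroot()
    graph = OntologyGraph()
    deferred: list[tuple[str, list]] = []
    for el in root:
        kind = _local(el.tag)
        if kind == "Declaration":
            for sub in el:
                skind = _local(sub.tag)
                if skind == "Class":
                    graph.add_concept(_iri(sub), kind="class")
                elif skind == "NamedIndividual":
                    graph.add_concept(_iri(sub), kind="individual")
                else:
                    warnings.warn(f"skipping declaration of unsupported kind {skind!r}")
        elif kind in ("SubClassOf", "ClassAssertion", "ObjectPropertyAssertion"):
            deferred.append((kind, list(el)))
        elif isinstance(el.tag, str):  # skip comments/PIs silently
            warnings.warn(f"skipping unsupported element {kind!r}")

    def require(el) -> str:
        iri = _iri(el)
        if normalize(iri) not in graph._concepts:
            raise ValidationError(f"dangling IRI reference: #{iri}")
        return iri

    for kind, parts in deferred:
        if kind == "SubClassOf":
            child, parent = (require(p) for p in parts[:2])
            graph.add_subclass(parent, child)
        elif kind == "ClassAssertion":
            cls, ind = require(parts[0]), require(parts[1])
            graph.add_property("class assertion", ind, cls)
        else:  # ObjectPropertyAssertion: property, subject, object
            prop = _iri(parts[0])
            subj, obj = require(parts[1]), require(parts[2])
            norm_prop = normalize(prop)
            if norm_prop in SYNONYM_PROPERTIES:
                graph.add_synonym(subj, obj)
            elif norm_prop in GROUP_PROPERTIES:
                graph.add_group(subj, obj)
            else:
                graph.add_property(prop, subj, obj)
    graph.validate()
    return graph


_OWL_NS = "http://www.w3.org/2002/07/owl#"


def save_owlxml(graph: OntologyGraph, path) -> None:
    """Serialize a graph back to the OWL/XML subset (lossy: no overrides)."""
    E = etree.SubElement
    root = etree.Element(f"{{{_OWL_NS}}}Ontology", nsmap={None: _OWL_NS})

    def display(cid: str) -> str:
        return graph._concepts[cid].label.replace(" ", "_")

    for concept in sorted(graph.concepts, key=lambda c: c.id):
        decl = E(root, f"{{{_OWL_NS}}}Declaration")
        tag = "NamedIndividual" if concept.kind == "individual" else "Class"
        E(decl, f"{{{_OWL_NS}}}{tag}", IRI=f"#{display(concept.id)}")
    for parent, child in sorted(graph.subclass_edges):
        el = E(root, f"{{{_OWL_NS}}}SubClassOf")
        E(el, f"{{{_OWL_NS}}}Class", IRI=f"#{display(child)}")
        E(el, f"{{{_OWL_NS}}}Class", IRI=f"#{display(parent)}")
    triples = [("Has_Synonym", a, b) for a, b in sorted(graph.synonym_edges)]
    triples += [("Has_Group", m, g) for m, g in sorted(graph.group_edges)]
    triples += [
        (p, s, o)
        for p, s, o in sorted(graph.property_assertions)
        if p != "class assertion"
    ]
    for prop, subj, obj in triples:
        el = E(root, f"{{{_OWL_NS}}}ObjectPropertyAssertion")
        E(el, f"{{{_OWL_NS}}}ObjectProperty", IRI=f"#{prop}")
        E(el, f"{{{_OWL_NS}}}NamedIndividual", IRI=f"#{display(subj)}")
        E(el, f"{{{_OWL_NS}}}NamedIndividual", IRI=f"#{display(obj)}")
    for prop, subj, obj in sorted(graph.property_assertions):
        if prop == "class assertion":
            el = E(root, f"{{{_OWL_NS}}}ClassAssertion")
            E(el, f"{{{_OWL_NS}}}Class", IRI=f"#{display(obj)}")
            E(el, f"{{{_OWL_NS}}}NamedIndividual", IRI=f"#{display(subj)}")
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------
# structured fixture format (YAML)
# ---------------------------------------------------------------------
#
# concepts:
#   - {label: Ascorbic Acid, kind: class, annotations: {rda: 90.0 mg}}
# subclass: [[Ascorbic Acid, Ester-C], ...]        # [parent, child]
# synonyms: [[Ascorbic Acid, E300], ...]
# groups:   [[Ascorbic Acid, Ascorbate], ...]      # [member, group]
# properties: [[Has_Solubility, Ascorbic Acid, Water], ...]
# weights:  [[Ascorbic Acid, Ester-C, 0.2], ...]   # overrides


def load_fixture(path) -> OntologyGraph:
    """Read the YAML fixture format (same semantics as the OWL loader)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return graph_from_dict(data)


def graph_from_dict(data: Mapping) -> OntologyGraph:
    graph = OntologyGraph()
    seen: set[str] = set()
    for i, entry in enumerate(data.get("concepts", []) or []):
        if isinstance(entry, str):
            entry = {"label": entry}
        label = entry.get("label")
        if not label:
            raise ValidationError(f"concepts[{i}]: missing label")
        cid = normalize(label)
        if cid in seen:
            raise ValidationError(f"concepts[{i}]: duplicate concept id {cid!r}")
        seen.add(cid)
        graph.add_concept(label, entry.get("kind", "class"), entry.get("annotations"))
    try:
        for parent, child in data.get("subclass", []) or []:
            graph.add_subclass(parent, child)
        for a, b in data.get("synonyms", []) or []:
            graph.add_synonym(a, b)
        for member, group in data.get("groups", []) or []:
            graph.add_group(member, group)
        for prop, subj, obj in data.get("properties", []) or []:
            graph.add_property(prop, subj, obj)
        for parent, child, weight in data.get("weights", []) or []:
            graph.set_weight(parent, child, float(weight))
    except ValueError as exc:
        raise ValidationError(f"malformed edge entry: {exc}") from exc
    graph.validate()
    return graph


def graph_to_dict(graph: OntologyGraph) -> dict:
    out: dict = {
        "concepts": [
            {
                "label": c.label,
                **({"kind": c.kind} if c.kind != "class" else {}),
                **({"annotations": dict(c.annotations)} if c.annotations else {}),
            }
            for c in sorted(graph.concepts, key=lambda c: c.id)
        ]
    }
    label = lambda cid: graph._concepts[cid].label  # noqa: E731
    if graph.subclass_edges:
        out["subclass"] = [[label(p), label(c)] for p, c in sorted(graph.subclass_edges)]
    if graph.synonym_edges:
        out["synonyms"] = [[label(a), label(b)] for a, b in sorted(graph.synonym_edges)]
    if graph.group_edges:
        out["groups"] = [[label(m), label(g)] for m, g in sorted(graph.group_edges)]
    props = sorted(p for p in graph.property_assertions)
    if props:
        out["properties"] = [[p, label(s), label(o)] for p, s, o in props]
    if graph.weight_overrides:
        out["weights"] = [
            [label(p), label(c), w] for (p, c), w in sorted(graph.weight_overrides.items())
        ]
    return out


def save_fixture(graph: OntologyGraph, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(graph_to_dict(graph), fh, sort_keys=False, allow_unicode=True)
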