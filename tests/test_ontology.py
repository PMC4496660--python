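"""Ontology graph: loaders, normalization, edge weights, path weights."""

import math
import random

import pytest

from semfood.fixtures import GeneratorParams, oracle_path, random_ontology
from semfood.ontology import (
    ConceptNotFound,
    NotConnected,
    OntologyError,
    ValidationError,
    graph_from_dict,
    load_fixture,
    load_owlxml,
    normalize,
    save_fixture,
    save_owlxml,
)

TABLE9_XML = """<?xml version="1.0"?>
<Ontology xmlns="http://www.w3.org/2002/07/owl#">
  <Declaration><Class IRI="#Antioxidant"/></Declaration>
  <Declaration><Class IRI="#Ascorbic_Acid"/></Declaration>
  <Declaration><Class IRI="#Ascorbyl_Palmitate"/></Declaration>
  <Declaration><Class IRI="#D-Isoascorbic_Acid"/></Declaration>
  <Declaration><Class IRI="#Ester-C"/></Declaration>
  <Declaration><NamedIndividual IRI="#Ascorbic_Acid"/></Declaration>
  <Declaration><NamedIndividual IRI="#E300"/></Declaration>
  <Declaration><NamedIndividual IRI="#C_Vitamin"/></Declaration>
  <Declaration><NamedIndividual IRI="#Scurvy"/></Declaration>
  <ClassAssertion>
    <Class IRI="#Ascorbic_Acid"/><NamedIndividual IRI="#Ascorbic_Acid"/>
  </ClassAssertion>
  <SubClassOf><Class IRI="#Ascorbic_Acid"/><Class IRI="#Antioxidant"/></SubClassOf>
  <SubClassOf><Class IRI="#Ascorbyl_Palmitate"/><Class IRI="#Ascorbic_Acid"/></SubClassOf>
  <SubClassOf><Class IRI="#D-Isoascorbic_Acid"/><Class IRI="#Ascorbic_Acid"/></SubClassOf>
  <SubClassOf><Class IRI="#Ester-C"/><Class IRI="#Ascorbic_Acid"/></SubClassOf>
  <ObjectPropertyAssertion>
    <ObjectProperty IRI="#Has_Synonym"/>
    <NamedIndividual IRI="#Ascorbic_Acid"/><NamedIndividual IRI="#E300"/>
  </ObjectPropertyAssertion>
  <ObjectPropertyAssertion>
    <ObjectProperty IRI="#Has_Synonym"/>
    <NamedIndividual IRI="#Ascorbic_Acid"/><NamedIndividual IRI="#C_Vitamin"/>
  </ObjectPropertyAssertion>
  <ObjectPropertyAssertion>
    <ObjectProperty IRI="#Has_Deficiency_Disease"/>
    <NamedIndividual IRI="#Ascorbic_Acid"/><NamedIndividual IRI="#Scurvy"/>
  </ObjectPropertyAssertion>
</Ontology>
"""


@pytest.fixture
def owl_graph(tmp_path):
    path = tmp_path / "kb.owl.xml"
    path.write_text(TABLE9_XML)
    return load_owlxml(path)


@pytest.mark.parametrize(
    "a,b",
    [
        ("Ascorbic Acid", "Ascorbic_Acid"),
        ("ascorbic acid", "ASCORBIC  ACID"),
        ("  Vitamin C ", "vitamin_c"),
    ],
)
def test_normalization_identifies_spelling_variants(a, b):
    assert normalize(a) == normalize(b)


class TestOwlXmlLoader:
    def test_subclass_and_synonym_edges(self, owl_graph):
        ids = {normalize(x) for x in ("Ascorbic_Acid", "Antioxidant")}
        assert {
            e for e in owl_graph.subclass_edges if set(e) <= {normalize("Ascorbic Acid"), normalize("Antioxidant")}
        } == {(normalize("Antioxidant"), normalize("Ascorbic Acid"))}
        children = {c for p, c in owl_graph.subclass_edges if p == normalize("Ascorbic Acid")}
        assert children == {
            normalize("Ascorbyl_Palmitate"),
            normalize("D-Isoascorbic_Acid"),
            normalize("Ester-C"),
        }
        assert owl_graph.are_synonyms("Ascorbic Acid", "E300")
        assert owl_graph.are_synonyms("Ascorbic Acid", "C_Vitamin")

    def test_other_assertions_kept_as_properties(self, owl_graph):
        assert (
            normalize("Has_Deficiency_Disease"),
            normalize("Ascorbic_Acid"),
            normalize("Scurvy"),
        ) in owl_graph.property_assertions

    def test_declarations_only_gives_isolated_concepts(self, tmp_path):
        xml = (
            '<?xml version="1.0"?><Ontology xmlns="http://www.w3.org/2002/07/owl#">'
            '<Declaration><Class IRI="#A"/></Declaration>'
            '<Declaration><Class IRI="#B"/></Declaration></Ontology>'
        )
        path = tmp_path / "d.owl.xml"
        path.write_text(xml)
        g = load_owlxml(path)
        assert len(g) == 2
        assert not g.subclass_edges and not g.synonym_edges

    def test_dangling_iri_is_validation_error(self, tmp_path):
        xml = (
            '<?xml version="1.0"?><Ontology xmlns="http://www.w3.org/2002/07/owl#">'
            '<Declaration><Class IRI="#A"/></Declaration>'
            '<SubClassOf><Class IRI="#B"/><Class IRI="#A"/></SubClassOf></Ontology>'
        )
        path = tmp_path / "d.owl.xml"
        path.write_text(xml)
        with pytest.raises(ValidationError, match="#B"):
            load_owlxml(path)

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.owl.xml"
        path.write_text("<Ontology><Declaration>")
        with pytest.raises(OntologyError, match="malformed"):
            load_owlxml(path)

    def test_unknown_element_kind_warns_and_skips(self, tmp_path):
        xml = (
            '<?xml version="1.0"?><Ontology xmlns="http://www.w3.org/2002/07/owl#">'
            '<Declaration><Class IRI="#A"/></Declaration>'
            "<DisjointClasses/></Ontology>"
        )
        path = tmp_path / "d.owl.xml"
        path.write_text(xml)
        with pytest.warns(UserWarning, match="DisjointClasses"):
            g = load_owlxml(path)
        assert len(g) == 1


class TestFixtureFormat:
    def test_worked_fixture_structure(self, graph):
        aa_children = {c for p, c in graph.subclass_edges if p == normalize("Ascorbic Acid")}
        assert len(aa_children) == 3
        algin_children = {c for p, c in graph.subclass_edges if p == normalize("Algin")}
        assert len(algin_children) == 2
        assert graph.synonym_class("Vitamin B3") == {
            normalize("Vitamin B3"),
            normalize("Niacin"),
            normalize("Niacinamide"),
        }

    def test_empty_concept_list_gives_empty_graph(self):
        assert len(graph_from_dict({"concepts": []})) == 0

    def test_duplicate_concept_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            graph_from_dict({"concepts": ["Algin", "ALGIN"]})

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            graph_from_dict(
                {"concepts": ["A", "B"], "subclass": [["A", "B"], ["B", "A"]]}
            )

    def test_fixture_round_trip(self, graph, tmp_path):
        path = tmp_path / "g.yaml"
        save_fixture(graph, path)
        assert load_fixture(path) == graph

    def test_owlxml_save_fixture_load_identity(self, owl_graph, tmp_path):
        yml = tmp_path / "g.yaml"
        save_fixture(owl_graph, yml)
        assert load_fixture(yml) == owl_graph

    def test_owlxml_round_trip(self, graph, tmp_path):
        # overrides are not expressible in OWL/XML; graph has none
        path = tmp_path / "g.owl.xml"
        save_owlxml(graph, path)
        re = load_owlxml(path)
        assert re.content()[:4] == graph.content()[:4]


class TestResolve:
    def test_resolves_across_spellings(self, graph):
        assert graph.resolve("ascorbic acid").label == "Ascorbic Acid"

    def test_synonym_nodes_stay_distinct(self, graph):
        assert graph.resolve("E300").id == "e300"
        assert graph.resolve("E300").id != graph.resolve("Ascorbic Acid").id

    def test_unknown_term_raises_carrying_term(self, graph):
        with pytest.raises(ConceptNotFound, match="Phytic acid"):
            graph.resolve("Phytic acid")


class TestEdgeWeight:
    def test_three_children_gives_one_third(self, graph):
        assert graph.edge_weight("Ascorbic Acid", "D-Isoascorbic Acid") == pytest.approx(1 / 3)

    def test_single_child_gives_one(self):
        g = graph_from_dict({"concepts": ["P", "C"], "subclass": [["P", "C"]]})
        assert g.edge_weight("P", "C") == 1.0

    def test_override_wins_without_renormalizing(self, worked):
        g = graph_from_dict(
            {
                "concepts": ["P", "A", "B", "C"],
                "subclass": [["P", "A"], ["P", "B"], ["P", "C"]],
                "weights": [["P", "A", 0.2]],
            }
        )
        assert g.edge_weight("P", "A") == 0.2
        assert g.edge_weight("P", "B") == pytest.approx(1 / 3)

    def test_non_edge_rejected(self, graph):
        with pytest.raises(OntologyError):
            graph.edge_weight("Algin", "Ester-C")


class TestPathWeight:
    @pytest.mark.parametrize(
        "a,z,weight,distance",
        [
            ("Ascorbic Acid", "D-Isoascorbic Acid", 1 / 3, 1),
            ("D-Isoascorbic Acid", "Ascorbyl Palmitate", 1 / 9, 2),
            ("Algin", "Sodium Alginate", 1 / 2, 1),
            ("Vitamin B3", "Niacin", 1.0, 1),  # synonym pair
            ("Algin", "Algin", 1.0, 0),  # identity
        ],
    )
    def test_worked_chains(self, graph, a, z, weight, distance):
        w, d = graph.path_weight(a, z)
        assert w == pytest.approx(weight)
        assert d == distance

    def test_unconnected_raises(self, graph):
        with pytest.raises(NotConnected):
            graph.path_weight("Vitamin C", "Folic Acid")

    def test_symmetric_weight(self, graph):
        for a, z in [("D-Isoascorbic Acid", "Ascorbyl Palmitate"), ("Algin", "Calcium Alginate")]:
            assert graph.path_weight(a, z) == graph.path_weight(z, a)


@pytest.mark.parametrize("seed", range(10))
def test_child_weights_sum_to_one(seed):
    """Eq.-style 1/n weighting: sibling edges of any parent sum to 1."""
    g = random_ontology(GeneratorParams(seed=seed))
    parents = {p for p, _ in g.subclass_edges} | {grp for _, grp in g.group_edges}
    for parent in parents:
        children = g._hier_children(g._canon(parent))
        total = sum(g.edge_weight(parent, c) for c in children)
        assert total == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(15))
def test_path_weight_matches_exhaustive_enumeration(seed):
    """BFS result equals brute-force enumeration of all simple chains."""
    rng = random.Random(seed)
    g = random_ontology(GeneratorParams(depth=2, branching=(1, 3), seed=seed))
    labels = sorted(c.label for c in g.concepts)[:30]
    for _ in range(20):
        a, z = rng.choice(labels), rng.choice(labels)
        expected = oracle_path(g, a, z)
        if expected is None:
            with pytest.raises(NotConnected):
                g.path_weight(a, z)
        else:
            w, d = g.path_weight(a, z)
            assert d == expected[1]
            assert w == pytest.approx(expected[0])
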