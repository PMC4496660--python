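"""DL-safe forward chaining over allergy-risk rules.

Rules follow the SWRL-style textual form

    Consumer(?c), Has_Allergy(?c, Lactose_Allergy),
    Has_Ean_No(?c, ?p), Has_Product_Additives_Name(?p, Aluminium_Silicate)
        -> HAS_LACTOSE_RISK(?c, Aluminium_Silicate)

i.e. a comma-separated conjunction of unary (class) and binary (property)
atoms, an ``->`` separator, and ``?``-prefixed variables.  DL-safety means
variables range only over the named individuals occurring in the fact
base, which makes the least fixpoint finite and cheap.  The two numeric
builtins ``greaterThan`` and ``lessThan`` are supported; any other builtin
is rejected at parse time.

``expand_rule_concepts`` couples the rule layer to the matching engine:
each concept constant in a rule is substituted by every ontology concept
related to it with a non-zero matchmaking degree (synonyms, sub- and
superclasses, group members), so a product declaring "Kaolin" still
triggers the "Aluminium_Silicate" rule.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .cme import MatchConfig, Relation, classify_relation
from .ontology import ConceptNotFound, OntologyGraph, normalize

__all__ = [
    "Atom",
    "Rule",
    "FactBase",
    "RuleSyntaxError",
    "DLSafetyError",
    "parse_rule",
    "parse_rules",
    "parse_fact",
    "forward_chain",
    "expand_rule_concepts",
    "RISK_PREDICATES",
]

RISK_PREDICATES = frozenset(
    {"HAS_LACTOSE_RISK", "HAS_GLUTEN_RISK", "HAS_FISH_RISK", "HAS_EGG_RISK"}
)
BUILTINS = frozenset({"greaterthan", "lessthan"})


class RuleSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class DLSafetyError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    """``predicate(arg)`` or ``predicate(arg, arg)``; ?-args are variables."""

    predicate: str
    args: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.args) not in (1, 2):
            raise ValueError(f"atom arity must be 1 or 2: {self}")

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(a for a in self.args if a.startswith("?"))

    @property
    def is_builtin(self) -> bool:
        return self.predicate.casefold() in BUILTINS

    def __str__(self) -> str:
        return f"{self.predicate}({', '.join(self.args)})"


@dataclass(frozen=True)
class Rule:
    """Conjunctive body implying one or more head atoms (DL-safe)."""

    body: tuple[Atom, ...]
    head: tuple[Atom, ...]

    def __post_init__(self) -> None:
        body_vars = frozenset().union(*(a.variables for a in self.body)) if self.body else frozenset()
        for atom in self.head:
            missing = atom.variables - body_vars
            if missing:
                raise DLSafetyError(
                    f"head variable(s) {sorted(missing)} do not occur in the body"
                )
        for atom in self.body + self.head:
            pred = atom.predicate.casefold()
            if atom.is_builtin and len(atom.args) != 2:
                raise ValueError(f"builtin {atom.predicate} needs two arguments")

    def __str__(self) -> str:
        return f"{', '.join(map(str, self.body))} -> {', '.join(map(str, self.head))}"


class FactBase:
    """A duplicate-free set of ground atoms."""

    def __init__(self, facts: Iterable[Atom] = ()):
        self._facts: set[Atom] = set()
        for f in facts:
            self.add(f)

    def add(self, fact: Atom) -> None:
        if fact.variables:
            raise ValueError(f"facts must be ground: {fact}")
        self._facts.add(fact)

    def __contains__(self, fact: Atom) -> bool:
        return fact in self._facts

    def __iter__(self):
        return iter(self._facts)

    def __len__(self) -> int:
        return len(self._facts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FactBase):
            return NotImplemented
        return self._facts == other._facts

    def individuals(self) -> frozenset[str]:
        return frozenset(a for f in self._facts for a in f.args)

    def copy(self) -> "FactBase":
        return FactBase(self._facts)


# ---------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------

_ATOM_RE = re.compile(r"\s*([A-Za-z_][\w\-]*)\s*\(\s*([^()]*?)\s*\)\s*")


def _parse_atoms(text: str, offset: int) -> list[Atom]:
    atoms: list[Atom] = []
    pos = 0
    while pos < len(text):
        match = _ATOM_RE.match(text, pos)
        if not match:
            raise RuleSyntaxError(f"expected atom in {text[pos:pos + 30]!r}", offset + pos)
        args = tuple(a.strip() for a in match.group(2).split(",") if a.strip())
        if not args:
            raise RuleSyntaxError("atom with no arguments", offset + match.start())
        atoms.append(Atom(match.group(1), args))
        pos = match.end()
        if pos < len(text):
            if text[pos] != ",":
                raise RuleSyntaxError(f"expected ',' between atoms, got {text[pos]!r}", offset + pos)
            pos += 1
    if not atoms:
        raise RuleSyntaxError("empty atom list", offset)
    return atoms


def parse_rule(text: str) -> Rule:
    """Parse one rule in the comma-separated atom syntax."""
    if "->" not in text:
        raise RuleSyntaxError("missing '->' separator", len(text))
    body_text, head_text = text.split("->", 1)
    body = _parse_atoms(body_text, 0)
    head = _parse_atoms(head_text, len(body_text) + 2)
    for atom in body:
        pred = atom.predicate.casefold()
        if pred not in BUILTINS and pred in {"add", "subtract", "matches", "stringconcat"}:
            raise RuleSyntaxError(f"unsupported builtin {atom.predicate!r}", 0)
    return Rule(tuple(body), tuple(head))


def parse_rules(path) -> list[Rule]:
    """Read a rule file: one rule per line, '#' comments, blank lines ok."""
    rules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                rules.append(parse_rule(line))
            except ValueError as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from None
    return rules


def parse_fact(text: str) -> Atom:
    """Parse one ground atom, e.g. ``Has_Allergy(c, Lactose_Allergy)``."""
    atoms = _parse_atoms(text, 0)
    if len(atoms) != 1:
        raise RuleSyntaxError("expected exactly one fact atom", 0)
    if atoms[0].variables:
        raise RuleSyntaxError(f"fact contains variables: {atoms[0]}", 0)
    return atoms[0]


def parse_facts(path) -> FactBase:
    facts = FactBase()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                facts.add(parse_fact(line))
    return facts


# ---------------------------------------------------------------------
# forward chaining
# ---------------------------------------------------------------------


def _as_number(token: str) -> Optional[float]:
    try:
        return float(token)
    except ValueError:
        return None


def _eval_builtin(atom: Atom, binding: Mapping[str, str]) -> bool:
    vals = []
    for arg in atom.args:
        token = binding.get(arg, arg) if arg.startswith("?") else arg
        if token.startswith("?"):
            return False  # unbound variable: defer (treated as failure)
        num = _as_number(token)
        if num is None:
            return False
        vals.append(num)
    if atom.predicate.casefold() == "greaterthan":
        return vals[0] > vals[1]
    return vals[0] < vals[1]


def _match_body(
    body: Sequence[Atom], facts: FactBase, binding: dict[str, str]
) -> Iterable[dict[str, str]]:
    if not body:
        yield dict(binding)
        return
    atom, rest = body[0], body[1:]
    if atom.is_builtin:
        if _eval_builtin(atom, binding):
            yield from _match_body(rest, facts, binding)
        return
    for fact in facts:
        if fact.predicate != atom.predicate or len(fact.args) != len(atom.args):
            continue
        new = dict(binding)
        ok = True
        for pat, val in zip(atom.args, fact.args):
            if pat.startswith("?"):
                if new.get(pat, val) != val:
                    ok = False
                    break
                new[pat] = val
            elif pat != val:
                ok = False
                break
        if ok:
            yield from _match_body(rest, facts, new)


def forward_chain(facts: FactBase, rules: Sequence[Rule]) -> FactBase:
    """Least fixpoint of the rules over the facts.

    Repeatedly instantiates rule bodies against the current fact set
    (variables bind to named individuals only) and asserts the head atoms
    until nothing new derives.  Termination is guaranteed — no function
    symbols, finitely many individuals — but a safety cap of
    ``|individuals|**2 * |predicates|`` derivations guards against bugs.
    """
    result = facts.copy()
    preds = {a.predicate for r in rules for a in r.head} | {f.predicate for f in facts}
    cap = max(1, len(result.individuals()) ** 2 * max(len(preds), 1)) + len(result)
    changed = True
    while changed:
        changed = False
        for rule in rules:
            for binding in list(_match_body(rule.body, result, {})):
                for head in rule.head:
                    ground = Atom(
                        head.predicate,
                        tuple(binding.get(a, a) for a in head.args),
                    )
                    if ground not in result:
                        result.add(ground)
                        changed = True
                        if len(result) > cap:
                            raise RuntimeError("derivation cap exceeded")
    return result


# ---------------------------------------------------------------------
# CME-backed concept expansion
# ---------------------------------------------------------------------


def related_concepts(
    graph: OntologyGraph, term: str, config: MatchConfig = MatchConfig()
) -> list[str]:
    """Labels of all concepts matching *term* with a non-zero degree."""
    seed = graph.resolve(term)
    out = []
    for other in graph.concepts:
        if other.id == seed.id:
            continue
        relation, _, _ = classify_relation(graph, seed, other, config)
        if relation is not Relation.DISSIMILAR:
            out.append(other.label)
    return sorted(out)


def expand_rule_concepts(
    graph: OntologyGraph, rule: Rule, config: MatchConfig = MatchConfig()
) -> list[Rule]:
    """Rule variants covering every concept related to a rule constant.

    Each individual constant that resolves in the ontology is substituted
    (consistently across body and head) by each Exact/Plugin/Subsume
    related concept.  The original rule always stays first; constants not
    in the ontology are left alone with a warning.
    """
    constants: list[str] = []
    seen: set[str] = set()
    for atom in rule.body:
        if atom.is_builtin:
            continue
        for arg in atom.args:
            if arg.startswith("?") or _as_number(arg) is not None:
                continue
            key = normalize(arg)
            if key not in seen:
                seen.add(key)
                constants.append(arg)

    substitutions: dict[str, list[str]] = {}
    for const in constants:
        try:
            related = related_concepts(graph, const, config)
        except ConceptNotFound:
            warnings.warn(f"rule constant not in ontology, left unexpanded: {const!r}")
            continue
        if related:
            substitutions[normalize(const)] = related

    variants: list[Rule] = [rule]
    produced = {str(rule)}

    def substitute(atom: Atom, old: str, new: str) -> Atom:
        return Atom(
            atom.predicate,
            tuple(new if normalize(a) == old else a for a in atom.args),
        )

    for const_key, related in substitutions.items():
        for new in related:
            new_label = new.replace(" ", "_")
            variant = Rule(
                tuple(substitute(a, const_key, new_label) for a in rule.body),
                tuple(substitute(a, const_key, new_label) for a in rule.head),
            )
            if str(variant) not in produced:
                produced.add(str(variant))
                variants.append(variant)
    return variants
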