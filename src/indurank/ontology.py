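"""Ontology representation in a restricted axiom dialect.

An ontology is a signature (classes, roles, individuals) plus a set of
axioms of three kinds:

* ``SubClassOf``       -- C is a subclass of D (named classes only)
* ``SubClassOfSome``   -- C is a subclass of the existential restriction
  "some R D" (e.g. a gene being subsumed by ``has_phenotype some P``)
* ``EquivalentTo``     -- C and D denote the same class (used for
  cross-species phenotype bridges)

Nested class expressions, cardinality restrictions and annotation axioms
are outside the dialect and are rejected at parse time.  This is
deliberately far short of OWL 2: the dialect covers exactly the axiom
shapes needed to express a phenotype taxonomy with cross-species
equivalences plus gene/disease/GDA association axioms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

# Reserved relation names. ``subClassOf`` labels taxonomy edges in the
# projected graph; the other three label association edges.
SUBCLASS_OF = "subClassOf"
HAS_PHENOTYPE = "has_phenotype"
HAS_SYMPTOM = "has_symptom"
ASSOCIATED_WITH = "associated_with"
RESERVED_RELATIONS = frozenset({SUBCLASS_OF, HAS_PHENOTYPE, HAS_SYMPTOM, ASSOCIATED_WITH})

AXIOM_KINDS = ("SubClassOf", "SubClassOfSome", "EquivalentTo")


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """Ontology-level invariant violation (e.g. a subsumption cycle)."""


@dataclass(frozen=True, order=True)
class Axiom:
    """One axiom of the restricted dialect.

    ``relation`` is present exactly when ``kind == "SubClassOfSome"``.
    """

    subject: str
    kind: str
    object: str
    relation: str | None = None

    def __post_init__(self):
        if self.kind not in AXIOM_KINDS:
            raise ValidationError(f"unknown axiom kind {self.kind!r}")
        if (self.relation is not None) != (self.kind == "SubClassOfSome"):
            raise ValidationError(
                f"relation must be present iff kind is SubClassOfSome (got {self})"
            )
        if not self.subject or not self.object:
            raise ValidationError("subject and object must be non-empty")
        if self.subject == self.relation:
            raise ValidationError(f"subject equals relation in {self}")


@dataclass(frozen=True)
class Ontology:
    """Immutable ontology: signature plus axiom sequence.

    The signature is normally inferred from the axioms via
    :meth:`from_axioms`.  The ``SubClassOf`` fragment restricted to
    classes must be acyclic (equivalence axioms are exempt: they
    intentionally create two-way subsumption when projected).
    """

    classes: frozenset[str]
    roles: frozenset[str]
    individuals: frozenset[str]
    axioms: tuple[Axiom, ...]

    @classmethod
    def from_axioms(
        cls,
        axioms: Iterable[Axiom],
        individuals: Iterable[str] = (),
        validate: bool = True,
    ) -> "Ontology":
        axioms = tuple(axioms)
        classes: set[str] = set()
        roles: set[str] = set()
        for ax in axioms:
            classes.add(ax.subject)
            classes.add(ax.object)
            if ax.relation is not None:
                roles.add(ax.relation)
        individuals = frozenset(individuals)
        classes -= individuals
        onto = cls(frozenset(classes), frozenset(roles), individuals, axioms)
        if validate:
            onto.validate()
        return onto

    @property
    def signature(self) -> frozenset[str]:
        return self.classes | self.roles | self.individuals

    def validate(self) -> None:
        sig = self.signature
        for ax in self.axioms:
            for term in (ax.subject, ax.object, ax.relation):
                if term is not None and term not in sig:
                    raise ValidationError(f"term {term!r} not in signature")
        g = nx.DiGraph()
        for ax in self.axioms:
            if ax.kind == "SubClassOf" and ax.subject != ax.object:
                g.add_edge(ax.subject, ax.object)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise ValidationError(f"subsumption cycle: {path}")

    def subsumption_graph(self) -> nx.DiGraph:
        """Directed child -> parent graph over SubClassOf plus both
        directions of EquivalentTo (equivalent classes are mutual
        ancestors)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for ax in self.axioms:
            if ax.kind == "SubClassOf":
                g.add_edge(ax.subject, ax.object)
            elif ax.kind == "EquivalentTo":
                g.add_edge(ax.subject, ax.object)
                g.add_edge(ax.object, ax.subject)
        return g

    def ancestors(self, term: str, reflexive: bool = True) -> frozenset[str]:
        """Ancestor closure of ``term`` in the subsumption graph."""
        closure = ancestor_closure(self)
        anc = closure.get(term)
        if anc is None:
            raise KeyError(f"unknown term {term!r}")
        return anc if reflexive else anc - {term}

    def roots(self) -> frozenset[str]:
        g = self.subsumption_graph()
        return frozenset(n for n in g.nodes if g.out_degree(n) == 0)


# Closure computation is memoized on ontology identity: ontologies are
# frozen, so identity-keyed caching is safe and avoids hashing the axiom
# tuple repeatedly.
_closure_cache: dict[int, tuple[Ontology, Mapping[str, frozenset[str]]]] = {}


def ancestor_closure(ontology: Ontology) -> Mapping[str, frozenset[str]]:
    """Reflexive ancestor closure for every class, as a dict."""
    hit = _closure_cache.get(id(ontology))
    if hit is not None and hit[0] is ontology:
        return hit[1]
    g = ontology.subsumption_graph()
    closure = {n: frozenset(nx.descendants(g, n)) | {n} for n in g.nodes}
    if len(_closure_cache) > 32:
        _closure_cache.clear()
    _closure_cache[id(ontology)] = (ontology, closure)
    return closure


@dataclass(frozen=True)
class AssociationTable:
    """Entity -> phenotype-term profiles under one reserved relation.

    ``relation`` is one of ``has_phenotype`` (genes), ``has_symptom``
    (diseases) or ``associated_with`` (gene-disease associations, in
    which case the "terms" are gene identifiers).
    """

    relation: str
    profiles: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.relation not in RESERVED_RELATIONS - {SUBCLASS_OF}:
            raise ValidationError(f"relation must be a reserved association relation, got {self.relation!r}")
        for entity, terms in self.profiles.items():
            if not terms:
                raise ValidationError(f"empty profile for {entity!r}")

    @classmethod
    def from_pairs(cls, relation: str, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        profiles: dict[str, set[str]] = {}
        for entity, term in pairs:
            profiles.setdefault(entity, set()).add(term)
        return cls(relation, {e: frozenset(t) for e, t in profiles.items()})

    @property
    def entities(self) -> frozenset[str]:
        return frozenset(self.profiles)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted((e, t) for e, terms in self.profiles.items() for t in terms)

    def restrict_to(self, entities: Iterable[str]) -> "AssociationTable":
        keep = set(entities)
        return AssociationTable(
            self.relation, {e: t for e, t in self.profiles.items() if e in keep}
        )

    def filter_terms(self, valid: Iterable[str]) -> tuple["AssociationTable", list[tuple[str, str]]]:
        """Drop (entity, term) pairs whose term is not in ``valid``.

        Returns the filtered table and the dropped pairs; entities left
        with an empty profile are removed entirely.
        """
        valid = set(valid)
        dropped: list[tuple[str, str]] = []
        profiles: dict[str, frozenset[str]] = {}
        for entity in sorted(self.profiles):
            terms = self.profiles[entity]
            kept = frozenset(t for t in terms if t in valid)
            dropped.extend((entity, t) for t in sorted(terms - kept))
            if kept:
                profiles[entity] = kept
        if dropped:
            logger.info(
                "dropped %d association pair(s) with terms absent from the ontology", len(dropped)
            )
        return AssociationTable(self.relation, profiles), dropped


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def parse_axiom_tsv(text: str) -> Ontology:
    """Parse the flat axiom dialect.

    Format: header ``subject<TAB>kind<TAB>relation<TAB>object``; the
    relation column holds ``-`` when absent; ``#`` starts a comment.
    """
    axioms: list[Axiom] = []
    lines = text.splitlines()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            header_seen = True
            if [f.strip() for f in fields] == ["subject", "kind", "relation", "object"]:
                continue
            # headerless files are accepted; fall through and parse the row
        if len(fields) != 4:
            raise ParseError(f"expected 4 tab-separated fields, got {len(fields)}", lineno)
        subject, kind, relation, obj = (f.strip() for f in fields)
        rel = None if relation in ("-", "") else relation
        try:
            axioms.append(Axiom(subject=subject, kind=kind, object=obj, relation=rel))
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from exc
    return Ontology.from_axioms(axioms)


def write_axiom_tsv(ontology: Ontology) -> str:
    rows = ["subject\tkind\trelation\tobject"]
    for ax in ontology.axioms:
        rows.append(f"{ax.subject}\t{ax.kind}\t{ax.relation or '-'}\t{ax.object}")
    return "\n".join(rows) + "\n"


_OBO_SUPPORTED_TAGS = {"name", "is_a", "relationship", "equivalent_to", "namespace", "def", "comment"}


def parse_obo(handle_or_path) -> Ontology:
    """Read the OBO flat-file subset (``id``, ``is_a``, ``relationship``,
    ``equivalent_to``) via :mod:`obonet`; any structural tag outside the
    subset is rejected."""
    import obonet

    graph = obonet.read_obo(handle_or_path, ignore_obsolete=True)
    axioms: list[Axiom] = []
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        unsupported = {
            k for k in data
            if k not in _OBO_SUPPORTED_TAGS and not k.startswith(("created", "xref", "subset", "synonym", "alt_id"))
        }
        if unsupported:
            raise ParseError(
                f"term {node}: unsupported OBO tag(s) {sorted(unsupported)}; "
                "only is_a/relationship/equivalent_to are in the dialect"
            )
        for parent in data.get("is_a", []):
            axioms.append(Axiom(node, "SubClassOf", parent.split("!")[0].strip()))
        for rel_line in data.get("relationship", []):
            parts = rel_line.split("!")[0].split()
            if len(parts) != 2:
                raise ParseError(f"term {node}: malformed relationship {rel_line!r}")
            rel, target = parts
            axioms.append(Axiom(node, "SubClassOfSome", target, relation=rel))
        for eq in data.get("equivalent_to", []):
            axioms.append(Axiom(node, "EquivalentTo", eq.split("!")[0].strip()))
    onto = Ontology.from_axioms(axioms)
    # obonet drops isolated terms from edges but keeps them as nodes
    extra = frozenset(graph.nodes) - onto.classes
    if extra:
        onto = Ontology(onto.classes | extra, onto.roles, onto.individuals, onto.axioms)
    return onto
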