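"""Projection of ontology axioms onto a labeled directed graph.

The projection applies structural rewriting rules (the named-class and
existential-restriction subset of the OWL2Vec* rules):

* ``C SubClassOf D``            -> edge ``(C, subClassOf, D)``
* ``C SubClassOf (R some D)``   -> edge ``(C, R, D)``
* ``C EquivalentTo D``          -> edges ``(C, subClassOf, D)`` and
  ``(D, subClassOf, C)`` (equivalent classes become mutual ancestors;
  this is how cross-species phenotype bridges become navigable)

Association tables are first turned into existential axioms
(``gene SubClassOf has_phenotype some P`` etc.) and then projected like
any other axiom.  Six graph variants of increasing information content
are built on top of the bare ontology graph:

=====  ==========================================================
G1     ontology only (no gene or disease nodes)
G2     G1 + gene--phenotype edges
G3     G2 + training-disease--phenotype edges
G4     G3 + training gene--disease association edges
G3T    G3 + test-disease--phenotype edges (transductive)
G4T    G4 + test-disease--phenotype edges (transductive)
=====  ==========================================================

Test-disease gene associations are never allowed into any variant; the
builders raise :class:`LeakageError` if one is present in the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .ontology import (
    ASSOCIATED_WITH,
    SUBCLASS_OF,
    AssociationTable,
    Axiom,
    Ontology,
    ValidationError,
)

logger = logging.getLogger(__name__)

GRAPH_VARIANTS = ("G1", "G2", "G3", "G4", "G3T", "G4T")


class LeakageError(RuntimeError):
    """A test-disease association reached a training graph."""


@dataclass(frozen=True)
class LabeledGraph:
    """Immutable labeled multidigraph as a set of (head, relation, tail)
    triples plus possibly isolated nodes."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str, str]]

    def __post_init__(self):
        for h, r, t in self.edges:
            if h not in self.nodes or t not in self.nodes:
                raise ValidationError(f"edge endpoint missing from nodes: {(h, r, t)}")
            if r == SUBCLASS_OF and h == t:
                raise ValidationError(f"self-loop under subClassOf: {h}")

    @property
    def relations(self) -> frozenset[str]:
        return frozenset(r for _, r, _ in self.edges)

    def sorted_edges(self) -> list[tuple[str, str, str]]:
        return sorted(self.edges)

    def union(self, other: "LabeledGraph") -> "LabeledGraph":
        return LabeledGraph(self.nodes | other.nodes, self.edges | other.edges)


def project(ontology: Ontology, include_inverse: bool = False) -> LabeledGraph:
    """Project an ontology to a :class:`LabeledGraph`.

    With ``include_inverse=True`` every existential-restriction edge
    ``(C, R, D)`` gains a companion ``(D, R^-1, C)``; the default keeps
    the graph purely structural.
    """
    for role in ontology.roles:
        if role == SUBCLASS_OF:
            raise ValidationError("ontology role collides with reserved relation 'subClassOf'")
    edges: set[tuple[str, str, str]] = set()
    for ax in ontology.axioms:
        if ax.kind == "SubClassOf":
            if ax.subject != ax.object:
                edges.add((ax.subject, SUBCLASS_OF, ax.object))
        elif ax.kind == "SubClassOfSome":
            edges.add((ax.subject, ax.relation, ax.object))
            if include_inverse:
                edges.add((ax.object, f"{ax.relation}^-1", ax.subject))
        elif ax.kind == "EquivalentTo":
            if ax.subject != ax.object:
                edges.add((ax.subject, SUBCLASS_OF, ax.object))
                edges.add((ax.object, SUBCLASS_OF, ax.subject))
    nodes = {h for h, _, _ in edges} | {t for _, _, t in edges}
    nodes |= ontology.classes | ontology.individuals
    return LabeledGraph(frozenset(nodes), frozenset(edges))


def add_association_axioms(ontology: Ontology, assoc: AssociationTable) -> Ontology:
    """Return a new ontology extended with one existential axiom per
    (entity, term) association pair.

    Pairs whose target phenotype term is absent from the ontology are
    dropped with a logged count (association files routinely reference
    terms missing from the ontology release in use).  For GDA tables
    (relation ``associated_with``) the targets are genes, which need not
    pre-exist as ontology classes, so no filtering applies.
    """
    if assoc.relation == ASSOCIATED_WITH:
        filtered = assoc
    else:
        filtered, _dropped = assoc.filter_terms(ontology.classes)
    new_axioms = [
        Axiom(entity, "SubClassOfSome", term, relation=filtered.relation)
        for entity, term in filtered.pairs()
    ]
    if not new_axioms:
        return ontology
    return Ontology.from_axioms(
        ontology.axioms + tuple(new_axioms),
        individuals=ontology.individuals,
        validate=False,
    )


def build_variant(
    ontology: Ontology,
    gene_assoc: AssociationTable | None,
    disease_assoc: AssociationTable | None,
    gda_assoc: AssociationTable | None,
    variant: str,
    test_diseases: frozenset[str] | set[str] = frozenset(),
    include_inverse: bool = False,
) -> LabeledGraph:
    """Build one of the six graph variants.

    ``test_diseases`` drives both the leakage guard (no test-disease GDA
    may appear in ``gda_assoc`` for any variant) and the exclusion of
    test-disease phenotype edges from the inductive variants G3/G4.
    """
    if variant not in GRAPH_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {GRAPH_VARIANTS}")
    test_diseases = frozenset(test_diseases)

    if gda_assoc is not None:
        leaked = test_diseases & gda_assoc.entities
        leaked |= frozenset(
            d for terms in gda_assoc.profiles.values() for d in terms
        ) & test_diseases
        if leaked:
            raise LeakageError(
                f"test disease(s) {sorted(leaked)} present in the GDA table; "
                "GDAs of held-out diseases must never enter a training graph"
            )

    onto = ontology
    if variant != "G1":
        if gene_assoc is not None:
            onto = add_association_axioms(onto, gene_assoc)
    if variant in ("G3", "G4", "G3T", "G4T") and disease_assoc is not None:
        if variant in ("G3", "G4"):
            kept = disease_assoc.restrict_to(disease_assoc.entities - test_diseases)
            n_excluded = len(disease_assoc.entities) - len(kept.entities)
            if n_excluded:
                logger.info("%s: excluded %d test disease(s) from the graph", variant, n_excluded)
        else:
            kept = disease_assoc
        if kept.profiles:
            onto = add_association_axioms(onto, kept)
    if variant in ("G4", "G4T") and gda_assoc is not None and gda_assoc.profiles:
        onto = add_association_axioms(onto, gda_assoc)

    graph = project(onto, include_inverse=include_inverse)

    if variant in ("G1", "G2", "G3", "G4"):
        leaked_nodes = graph.nodes & test_diseases
        if leaked_nodes:  # pragma: no cover - defense in depth
            raise LeakageError(f"test disease node(s) {sorted(leaked_nodes)} in {variant}")
    return graph
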