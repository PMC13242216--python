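"""Gene ranking for a query phenotype profile.

The inductive scorer compares a gene's phenotype set Pg with a query
disease's phenotype set Pd through the pairwise embedding kernel

    sim_e(p, q) = sigmoid(<p_vec, q_vec>)

aggregated with best-match-average (BMA, the default) or
best-match-maximum (BMM).  Because only *phenotype* vectors are ever
looked up, the query disease itself need not have been embedded: any
novel disease described by known phenotype terms can be ranked.  Two
transductive scorers are provided for comparison -- the direct entity
similarity sim_e(g, d) and the model's own triple score f(g, r, d) --
both of which fail with :class:`UnknownEntityError` on diseases absent
from the embedding vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .graph import build_variant
from .kge import EmbeddingSet, KnowledgeGraphEmbedding, UnknownEntityError, score_triples
from .ontology import ASSOCIATED_WITH, AssociationTable, Ontology
from .semsim import AGGREGATIONS, SemanticSimilarity, bma_bmm


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def entity_similarity(emb: EmbeddingSet, a: str, b: str) -> float:
    """sigmoid(dot product) of two entity embeddings; symmetric, in (0, 1)."""
    va, vb = emb.vector(a), emb.vector(b)
    return float(_sigmoid(va @ vb))


def profile_similarity(
    emb: EmbeddingSet,
    pg: Iterable[str],
    pd: Iterable[str],
    aggregation: str = "bma",
    normalize: bool = False,
) -> float:
    """BMA/BMM aggregation of the pairwise sigmoid-dot-product matrix
    between two phenotype profiles.

    ``normalize=True`` L2-normalizes the vectors first (cosine kernel);
    the default uses the raw dot product.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}, got {aggregation!r}")
    pg, pd = sorted(set(pg)), sorted(set(pd))
    if not pg or not pd:
        raise ValueError("profiles must be non-empty")
    vg, vd = emb.vectors(pg), emb.vectors(pd)
    if normalize:
        vg = vg / np.linalg.norm(vg, axis=1, keepdims=True)
        vd = vd / np.linalg.norm(vd, axis=1, keepdims=True)
    matrix = _sigmoid(vg @ vd.T)
    bma, bmm = bma_bmm(matrix)
    return float(bma if aggregation == "bma" else bmm)


# ---------------------------------------------------------------------------
# scorers (all expose score_pair(gene, gene_profile, query, query_profile))
# ---------------------------------------------------------------------------

class EmbeddingProfileScorer:
    """Inductive scorer: sim^e aggregated over phenotype profiles."""

    kind = "bma_e"

    def __init__(self, emb: EmbeddingSet, aggregation: str = "bma", normalize: bool = False):
        if aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        self.emb = emb
        self.aggregation = aggregation
        self.normalize = normalize
        self.kind = f"{aggregation}_e"

    def score_pair(self, gene, gene_profile, query, query_profile) -> float:
        return profile_similarity(
            self.emb, gene_profile, query_profile,
            aggregation=self.aggregation, normalize=self.normalize,
        )


class EntitySimilarityScorer:
    """Transductive scorer sim_e(g, d): requires both entities embedded."""

    kind = "entity_sim"

    def __init__(self, emb: EmbeddingSet):
        self.emb = emb

    def score_pair(self, gene, gene_profile, query, query_profile) -> float:
        return entity_similarity(self.emb, gene, query)


class TripleScorer:
    """Transductive scorer f(g, r, d) under the trained model, by default
    over the gene-disease association relation."""

    kind = "triple_score"

    def __init__(self, emb: EmbeddingSet, relation: str = ASSOCIATED_WITH):
        self.emb = emb
        self.relation = relation

    def score_pair(self, gene, gene_profile, query, query_profile) -> float:
        return float(score_triples(self.emb, [(gene, self.relation, query)])[0])


@dataclass(frozen=True)
class RankedList:
    """Full candidate ranking for one query disease: scores
    non-increasing, ties broken lexicographically by gene id."""

    disease: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        scores = [s for _, s in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("entries must be sorted by non-increasing score")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene in ranked list")

    def position(self, gene: str) -> int:
        for i, (g, _) in enumerate(self.entries, start=1):
            if g == gene:
                return i
        raise KeyError(gene)


def rank_genes(
    scorer,
    gene_profiles: Mapping[str, Iterable[str]],
    query_profile: Iterable[str],
    query_id: str = "QUERY",
) -> RankedList:
    """Score every candidate gene against the query profile and sort.

    The candidate universe is every gene with a non-empty profile.  The
    output order is deterministic: descending score, then gene id.
    Tie-aware (fractional) ranks are the evaluation module's concern.
    """
    if isinstance(gene_profiles, AssociationTable):
        gene_profiles = gene_profiles.profiles
    query_profile = sorted(set(query_profile))
    if not query_profile:
        raise ValueError("query profile is empty")
    scored = [
        (gene, float(scorer.score_pair(gene, sorted(gene_profiles[gene]), query_id, query_profile)))
        for gene in sorted(gene_profiles)
        if gene_profiles[gene]
    ]
    scored.sort(key=lambda gs: (-gs[1], gs[0]))
    return RankedList(disease=query_id, entries=tuple(scored))


class InductivePhenotypeRanker(BaseEstimator):
    """End-to-end estimator: project the annotated ontology to a graph
    variant, train a knowledge-graph embedding on it, and rank candidate
    genes for arbitrary phenotype-set queries.

    Parameters
    ----------
    embedding : KnowledgeGraphEmbedding
        Unfitted embedding estimator (cloned per fit).
    variant : {"G1", "G2", "G3", "G4", "G3T", "G4T"}
        Graph variant to train on; G4 adds the supervised GDA signal.
    aggregation : {"bma", "bmm"}
        Profile aggregation; BMA is the method's default.

    After :meth:`fit`, :meth:`rank` accepts any phenotype profile drawn
    from the ontology vocabulary -- including profiles of diseases never
    seen during training (the inductive contract).
    """

    def __init__(
        self,
        embedding: KnowledgeGraphEmbedding | None = None,
        variant: str = "G4",
        aggregation: str = "bma",
        normalize: bool = False,
    ):
        self.embedding = embedding
        self.variant = variant
        self.aggregation = aggregation
        self.normalize = normalize

    def fit(
        self,
        ontology: Ontology,
        gene_assoc: AssociationTable,
        disease_assoc: AssociationTable | None = None,
        gda_assoc: AssociationTable | None = None,
        test_diseases: Iterable[str] = (),
    ) -> "InductivePhenotypeRanker":
        graph = build_variant(
            ontology, gene_assoc, disease_assoc, gda_assoc,
            self.variant, frozenset(test_diseases),
        )
        base = self.embedding if self.embedding is not None else KnowledgeGraphEmbedding(model="transd")
        # fresh estimator with identical params; init_from (a fitted
        # warm-start source) is deliberately carried over by reference
        self.embedding_ = KnowledgeGraphEmbedding(**base.get_params(deep=False))
        self.embedding_.fit(graph)
        filtered, _ = gene_assoc.filter_terms(ontology.classes)
        self.gene_profiles_ = dict(filtered.profiles)
        self.graph_ = graph
        self.scorer_ = EmbeddingProfileScorer(
            self.embedding_.embedding_, aggregation=self.aggregation, normalize=self.normalize
        )
        return self

    def rank(self, query_profile: Iterable[str], query_id: str = "QUERY") -> RankedList:
        if not hasattr(self, "scorer_"):
            raise RuntimeError("ranker is not fitted")
        return rank_genes(self.scorer_, self.gene_profiles_, query_profile, query_id)

    def predict(self, query_profiles: Mapping[str, Iterable[str]]) -> list[RankedList]:
        """Rank genes for each of several query diseases."""
        return [self.rank(profile, qid) for qid, profile in sorted(query_profiles.items())]
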