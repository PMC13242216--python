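"""Information-content-based semantic similarity baselines.

The term frequency P(p) of a phenotype term is its propagated annotation
frequency in a corpus of entity profiles (an entity annotated to a term
counts once for the term and each of its ancestors), and

    IC(p) = -ln P(p)                      (nats)

Pairwise measures over two terms p1, p2 with most informative common
ancestor MICA:

    sim_Resnik(p1, p2) = IC(MICA(p1, p2))
    sim_Lin(p1, p2)    = 2 IC(MICA) / (IC(p1) + IC(p2))

Groupwise measures over two profiles Pg, Pd: the best-match-average
(BMA) and best-match-maximum (BMM) aggregate the pairwise matrix by the
mean resp. max of the two directional best-match means, while SimGIC is
the IC-weighted Jaccard index of the reflexive ancestor closures:

    SimGIC(Pg, Pd) = sum_{c in CT+(Pg) & CT+(Pd)} IC(c)
                   / sum_{c in CT+(Pg) | CT+(Pd)} IC(c)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .ontology import AssociationTable, Ontology, ancestor_closure

PAIRWISE_MEASURES = ("resnik", "lin")
AGGREGATIONS = ("bma", "bmm")


@dataclass(frozen=True)
class ICTable:
    """Per-term information content (nats) over a fixed annotation corpus."""

    ic: Mapping[str, float]
    corpus_size: int

    def __post_init__(self):
        if self.corpus_size <= 0:
            raise ValueError("corpus_size must be positive")

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def get(self, term: str, default: float | None = None) -> float | None:
        return self.ic.get(term, default)


def compute_ic(ontology: Ontology, corpus: AssociationTable) -> ICTable:
    """Information content of every ontology class from a profile corpus.

    Annotation counts are propagated through the (reflexive) subsumption
    closure before frequencies are taken, so an ancestor's count is at
    least each descendant's.  Terms with zero propagated count receive
    the maximal attainable IC, ln(corpus size), keeping downstream
    Lin/SimGIC values finite on sparse corpora.
    """
    if not corpus.profiles:
        raise ValueError("corpus must be non-empty")
    closure = ancestor_closure(ontology)
    counts: dict[str, int] = {}
    for entity, terms in corpus.profiles.items():
        covered: set[str] = set()
        for t in terms:
            anc = closure.get(t)
            if anc is None:
                raise KeyError(f"corpus term {t!r} not an ontology class")
            covered |= anc
        for c in covered:
            counts[c] = counts.get(c, 0) + 1
    n = len(corpus.profiles)
    max_ic = math.log(n)
    ic = {
        term: (-math.log(counts[term] / n) if term in counts else max_ic)
        for term in ontology.classes
    }
    return ICTable(ic=ic, corpus_size=n)


def mica(ontology: Ontology, ic_table: ICTable, p1: str, p2: str) -> tuple[str, float]:
    """Most informative common ancestor of two terms (reflexive closure).

    Ties are broken lexicographically so the returned term is
    deterministic; the IC value of any maximizer is unique.
    """
    closure = ancestor_closure(ontology)
    common = closure[p1] & closure[p2]
    if not common:
        roots = ontology.roots()
        if len(roots) == 1:
            (root,) = roots
            return root, 0.0
        raise ValueError(f"{p1} and {p2} share no ancestor and the ontology is multi-rooted")
    best = min(common, key=lambda c: (-ic_table[c], c))
    return best, ic_table[best]


def pairwise_sim(
    measure: str, ic_table: ICTable, ontology: Ontology, p1: str, p2: str
) -> float:
    if measure not in PAIRWISE_MEASURES:
        raise ValueError(f"measure must be one of {PAIRWISE_MEASURES}, got {measure!r}")
    _, ic_mica = mica(ontology, ic_table, p1, p2)
    if measure == "resnik":
        return ic_mica
    denom = ic_table[p1] + ic_table[p2]
    return 0.0 if denom == 0 else 2.0 * ic_mica / denom


def bma_bmm(matrix: np.ndarray) -> tuple[float, float]:
    """Directional best-match means of a pairwise similarity matrix and
    their mean (BMA) and max (BMM)."""
    if matrix.size == 0:
        raise ValueError("empty similarity matrix")
    row_best = matrix.max(axis=1).mean()
    col_best = matrix.max(axis=0).mean()
    return 0.5 * (row_best + col_best), max(row_best, col_best)


def _pairwise_matrix(
    kernel: Callable[[str, str], float], pg: Sequence[str], pd: Sequence[str]
) -> np.ndarray:
    return np.array([[kernel(a, b) for b in pd] for a in pg], dtype=float)


def simgic(ontology: Ontology, ic_table: ICTable, pg: Iterable[str], pd: Iterable[str]) -> float:
    closure = ancestor_closure(ontology)
    ct_g: set[str] = set().union(*(closure[t] for t in pg))
    ct_d: set[str] = set().union(*(closure[t] for t in pd))
    denom = sum(ic_table[c] for c in ct_g | ct_d)
    if denom == 0:
        return 0.0
    return sum(ic_table[c] for c in ct_g & ct_d) / denom


def groupwise_sim(
    measure: str,
    aggregation: str | None,
    pg: Iterable[str],
    pd: Iterable[str],
    ontology: Ontology,
    ic_table: ICTable,
) -> float:
    """Groupwise similarity of two term profiles.

    ``measure`` is ``resnik``/``lin`` (combined with ``aggregation`` in
    ``bma``/``bmm``) or ``simgic`` (direct; aggregation ignored).
    """
    pg, pd = sorted(set(pg)), sorted(set(pd))
    if not pg or not pd:
        raise ValueError("profiles must be non-empty")
    if measure == "simgic":
        return simgic(ontology, ic_table, pg, pd)
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}, got {aggregation!r}")
    kernel = lambda a, b: pairwise_sim(measure, ic_table, ontology, a, b)
    matrix = _pairwise_matrix(kernel, pg, pd)
    bma, bmm = bma_bmm(matrix)
    return bma if aggregation == "bma" else bmm


class SemanticSimilarity(BaseEstimator):
    """IC-based profile similarity, fit on an ontology and a corpus.

    Parameters
    ----------
    measure : {"resnik", "lin", "simgic"}
        Pairwise kernel, or the direct groupwise SimGIC measure.
    aggregation : {"bma", "bmm"}
        How the pairwise matrix is aggregated (ignored for simgic).

    Attributes
    ----------
    ic_ : ICTable
        Per-term information content computed during :meth:`fit`.
    """

    def __init__(self, measure: str = "resnik", aggregation: str = "bma"):
        self.measure = measure
        self.aggregation = aggregation

    def fit(self, ontology: Ontology, corpus: AssociationTable) -> "SemanticSimilarity":
        if self.measure not in PAIRWISE_MEASURES + ("simgic",):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        self.ontology_ = ontology
        self.ic_ = compute_ic(ontology, corpus)
        self._mica_cache: dict[tuple[str, str], float] = {}
        return self

    def _check_fitted(self):
        if not hasattr(self, "ic_"):
            raise RuntimeError("SemanticSimilarity must be fit before use")

    def pairwise(self, p1: str, p2: str) -> float:
        """Pairwise term similarity (resnik/lin kernel), with MICA caching."""
        self._check_fitted()
        measure = "resnik" if self.measure == "simgic" else self.measure
        key = (p1, p2) if p1 <= p2 else (p2, p1)
        ic_mica = self._mica_cache.get(key)
        if ic_mica is None:
            _, ic_mica = mica(self.ontology_, self.ic_, p1, p2)
            self._mica_cache[key] = ic_mica
        if measure == "resnik":
            return ic_mica
        denom = self.ic_[p1] + self.ic_[p2]
        return 0.0 if denom == 0 else 2.0 * ic_mica / denom

    def profile_similarity(self, pg: Iterable[str], pd: Iterable[str]) -> float:
        self._check_fitted()
        pg, pd = sorted(set(pg)), sorted(set(pd))
        if not pg or not pd:
            raise ValueError("profiles must be non-empty")
        if self.measure == "simgic":
            return simgic(self.ontology_, self.ic_, pg, pd)
        matrix = _pairwise_matrix(self.pairwise, pg, pd)
        bma, bmm = bma_bmm(matrix)
        return bma if self.aggregation == "bma" else bmm

    # scorer protocol used by ranking.rank_genes
    def score_pair(self, gene: str, gene_profile, query: str, query_profile) -> float:
        return self.profile_similarity(gene_profile, query_profile)
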