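"""Disease-split cross-validation and ranked-retrieval metrics.

Evaluation follows the inductive protocol: diseases (not associations)
are partitioned into k folds; each fold's test diseases are excluded
from the training graph, their gene associations never enter any
training input, and test diseases whose phenotype profile *and* gene
set both duplicate a training disease are dropped.  For every surviving
test disease, all candidate genes are scored and the tie-averaged rank
of each true causative gene is recorded.  Metrics:

* MR      mean rank (lower better)
* MRR     mean reciprocal rank
* Hits@k  fraction of true genes ranked in the top k
* AUC     mean of (N - rank) / (N - 1) over records, i.e. the
          probability that a true association outranks a random
          non-association under tie-averaging
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._seeds import derive_seed
from .graph import GRAPH_VARIANTS, build_variant
from .kge import KnowledgeGraphEmbedding
from .ontology import AssociationTable, Ontology
from .ranking import EmbeddingProfileScorer, EntitySimilarityScorer, TripleScorer
from .semsim import SemanticSimilarity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSpec:
    index: int
    train_diseases: frozenset[str]
    test_diseases: frozenset[str]

    def __post_init__(self):
        if self.train_diseases & self.test_diseases:
            raise ValueError(f"fold {self.index}: train/test overlap")


def disease_folds(diseases: Iterable[str], k: int, seed: int = 0) -> list[FoldSpec]:
    """Uniform random partition of the disease set into k folds."""
    if k <= 1:
        raise ValueError("k must be at least 2")
    diseases = sorted(set(diseases))
    if len(diseases) < k:
        raise ValueError(f"need at least {k} diseases for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(diseases))
    folds = []
    chunks = np.array_split(order, k)
    for i, chunk in enumerate(chunks):
        test = frozenset(diseases[j] for j in chunk)
        folds.append(FoldSpec(i, frozenset(diseases) - test, test))
    return folds


def filter_duplicate_test_diseases(
    test: Iterable[str],
    train: Iterable[str],
    disease_profiles: Mapping[str, frozenset[str]],
    gda: AssociationTable,
) -> frozenset[str]:
    """Drop test diseases whose phenotype profile AND gene set both
    exactly match some training disease's."""
    train_keys = {
        (disease_profiles.get(d, frozenset()), gda.profiles.get(d, frozenset()))
        for d in train
    }
    kept, removed = set(), []
    for d in sorted(set(test)):
        key = (disease_profiles.get(d, frozenset()), gda.profiles.get(d, frozenset()))
        if key in train_keys:
            removed.append(d)
        else:
            kept.add(d)
    if removed:
        logger.info("removed %d duplicate test disease(s): %s", len(removed), removed)
    return frozenset(kept)


# ---------------------------------------------------------------------------
# rank records and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankRecord:
    disease: str
    gene: str
    rank: float            # tie-averaged, 1-based
    n_candidates: int

    def __post_init__(self):
        if not (1 <= self.rank <= self.n_candidates):
            raise ValueError(f"rank {self.rank} outside [1, {self.n_candidates}]")


@dataclass(frozen=True)
class MetricsReport:
    mr: float
    mrr: float
    hits: Mapping[int, float]
    auc: float
    n_records: int
    per_fold: tuple["MetricsReport", ...] | None = None
    std: Mapping[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "mr": self.mr, "mrr": self.mrr,
            "hits": {str(k): v for k, v in sorted(self.hits.items())},
            "auc": self.auc, "n_records": self.n_records,
        }
        if self.std is not None:
            out["std"] = dict(self.std)
        if self.per_fold is not None:
            out["per_fold"] = [f.to_dict() for f in self.per_fold]
        return out


def tie_averaged_rank(
    scores: Mapping[str, float], true_gene: str, exclude: Iterable[str] = ()
) -> tuple[float, int]:
    """1-based fractional rank of ``true_gene`` among candidate scores
    (descending).  ``exclude`` removes other genes (e.g. the disease's
    other true genes, in filtered evaluation) from the candidate list."""
    exclude = set(exclude) - {true_gene}
    s = scores[true_gene]
    better = tied = 0
    n = 0
    for gene, sc in scores.items():
        if gene in exclude:
            continue
        n += 1
        if sc > s:
            better += 1
        elif sc == s:
            tied += 1
    return better + (tied + 1) / 2.0, n


def ranking_metrics(records: Sequence[RankRecord], ks: Iterable[int] = (1, 10, 100)) -> MetricsReport:
    if not records:
        raise ValueError("no rank records to aggregate")
    ranks = np.array([r.rank for r in records], dtype=float)
    ncand = np.array([r.n_candidates for r in records], dtype=float)
    with np.errstate(invalid="ignore"):
        auc_terms = np.where(ncand > 1, (ncand - ranks) / (ncand - 1), 1.0)
    return MetricsReport(
        mr=float(ranks.mean()),
        mrr=float((1.0 / ranks).mean()),
        hits={int(k): float((ranks <= k).mean()) for k in ks},
        auc=float(auc_terms.mean()),
        n_records=len(records),
    )


def compare_methods(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired rank values.

    Pairs must be aligned on the same (disease, gene) keys; pairs with
    zero difference are dropped (Wilcoxon's original treatment).
    """
    a, b = np.asarray(ranks_a, float), np.asarray(ranks_b, float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equally long paired sequences of length >= 5")
    if np.all(a == b):
        raise ValueError("all paired differences are zero; the test is degenerate")
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

@dataclass
class MethodSpec:
    """One (model, scorer) combination to evaluate.

    type 'semantic': measure in {resnik, lin, simgic} + aggregation.
    type 'kge': model in MODELS + scorer in {bma_e, bmm_e, entity_sim,
    triple_score} + estimator keyword overrides.
    """

    name: str
    type: str                      # "semantic" | "kge"
    measure: str = "resnik"        # semantic only
    aggregation: str = "bma"
    model: str = "transd"          # kge only
    scorer: str = "bma_e"
    kge_params: dict = field(default_factory=dict)


@dataclass
class ExperimentConfig:
    ontology: Ontology
    gene_assoc: AssociationTable
    disease_assoc: AssociationTable
    gda_assoc: AssociationTable
    variants: tuple[str, ...] = ("G4",)
    methods: tuple[MethodSpec, ...] = (MethodSpec(name="transd-bma", type="kge"),)
    n_folds: int = 10
    ks: tuple[int, ...] = (1, 10, 100)
    seed: int = 0
    filtered: bool = False

    def __post_init__(self):
        for v in self.variants:
            if v not in GRAPH_VARIANTS:
                raise ValueError(f"unknown variant {v!r}")


def _fit_kge(spec: MethodSpec, graph, seed: int) -> KnowledgeGraphEmbedding:
    params = dict(spec.kge_params)
    if spec.model in ("convkb", "convkb_d"):
        base_model = "transd" if spec.model == "convkb_d" else "transe"
        base = KnowledgeGraphEmbedding(
            model=base_model, random_state=derive_seed(seed, "warmstart"),
            **{k: v for k, v in params.items() if k not in ("n_filters", "l2_reg")},
        )
        base.fit(graph)
        est = KnowledgeGraphEmbedding(
            model=spec.model, init_from=base, random_state=seed, **params
        )
    else:
        est = KnowledgeGraphEmbedding(model=spec.model, random_state=seed, **params)
    return est.fit(graph)


def _make_scorer(spec: MethodSpec, graph, ontology, gene_assoc, seed: int):
    if spec.type == "semantic":
        est = SemanticSimilarity(measure=spec.measure, aggregation=spec.aggregation)
        est.fit(ontology, gene_assoc)
        return est
    est = _fit_kge(spec, graph, seed)
    emb = est.embedding_
    if spec.scorer in ("bma_e", "bmm_e"):
        return EmbeddingProfileScorer(emb, aggregation=spec.scorer[:3])
    if spec.scorer == "entity_sim":
        return EntitySimilarityScorer(emb)
    if spec.scorer == "triple_score":
        return TripleScorer(emb)
    raise ValueError(f"unknown scorer {spec.scorer!r}")


def evaluate_fold(
    scorer,
    gene_profiles: Mapping[str, frozenset[str]],
    disease_profiles: Mapping[str, frozenset[str]],
    gda: AssociationTable,
    test_diseases: Iterable[str],
    filtered: bool = False,
) -> list[RankRecord]:
    """Rank all candidate genes for each test disease; one record per
    true (disease, gene) association."""
    records = []
    genes = sorted(g for g in gene_profiles if gene_profiles[g])
    for disease in sorted(test_diseases):
        profile = disease_profiles.get(disease)
        true_genes = sorted(gda.profiles.get(disease, ()))
        if not profile or not true_genes:
            continue
        query = sorted(profile)
        scores = {
            g: float(scorer.score_pair(g, sorted(gene_profiles[g]), disease, query))
            for g in genes
        }
        for gene in true_genes:
            if gene not in scores:
                continue
            exclude = set(true_genes) if filtered else ()
            rank, n = tie_averaged_rank(scores, gene, exclude=exclude)
            records.append(RankRecord(disease, gene, rank, n))
    return records


def aggregate_folds(fold_reports: Sequence[MetricsReport]) -> MetricsReport:
    """Mean +/- sample s.d. across folds for each metric."""
    if not fold_reports:
        raise ValueError("no fold reports")
    def sd(xs):
        return float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0
    mrs = [f.mr for f in fold_reports]
    mrrs = [f.mrr for f in fold_reports]
    aucs = [f.auc for f in fold_reports]
    ks = sorted(fold_reports[0].hits)
    hits = {k: float(np.mean([f.hits[k] for f in fold_reports])) for k in ks}
    std = {"mr": sd(mrs), "mrr": sd(mrrs), "auc": sd(aucs)}
    std.update({f"hits@{k}": sd([f.hits[k] for f in fold_reports]) for k in ks})
    return MetricsReport(
        mr=float(np.mean(mrs)), mrr=float(np.mean(mrrs)), hits=hits,
        auc=float(np.mean(aucs)),
        n_records=int(sum(f.n_records for f in fold_reports)),
        per_fold=tuple(fold_reports), std=std,
    )


def run_experiment(config: ExperimentConfig) -> dict[tuple[str, str], MetricsReport]:
    """Full cross-validated comparison.

    Returns a report per (graph variant, method name).  All randomness
    descends from ``config.seed`` through labeled sub-seeds, so a rerun
    with the same config is bit-identical in single-threaded mode.
    """
    onto = config.ontology
    gene_assoc, _ = config.gene_assoc.filter_terms(onto.classes)
    disease_assoc, _ = config.disease_assoc.filter_terms(onto.classes)
    gene_profiles = dict(gene_assoc.profiles)
    disease_profiles = dict(disease_assoc.profiles)
    gda = config.gda_assoc

    folds = disease_folds(disease_profiles, config.n_folds, derive_seed(config.seed, "folds"))
    results: dict[tuple[str, str], MetricsReport] = {}
    for variant in config.variants:
        for spec in config.methods:
            fold_reports = []
            for fold in folds:
                test = filter_duplicate_test_diseases(
                    fold.test_diseases, fold.train_diseases, disease_profiles, gda
                )
                train_gda = gda.restrict_to(fold.train_diseases)
                graph = build_variant(
                    onto, gene_assoc, disease_assoc, train_gda, variant, fold.test_diseases
                )
                scorer = _make_scorer(
                    spec, graph, onto, gene_assoc,
                    derive_seed(config.seed, variant, spec.name, fold.index),
                )
                records = evaluate_fold(
                    scorer, gene_profiles, disease_profiles, gda, test,
                    filtered=config.filtered,
                )
                if records:
                    fold_reports.append(ranking_metrics(records, config.ks))
            results[(variant, spec.name)] = aggregate_folds(fold_reports)
    return results
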