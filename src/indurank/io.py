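"""Readers and writers for the package's flat-file dialects.

All formats are plain TSV/JSON:

* axiom TSV            ``subject  kind  relation  object`` ('-' = none)
* association TSVs     gene (``gene_id``, ``phenotype_id``, extra
  columns ignored), disease (``database_id``, ``phenotype_id``, '#'
  comments skipped), GDA (``gene_id``, ``disease_id``)
* graph edge list      ``head  relation  tail``
* IC table             ``term  ic``
* embeddings           one TSV per table plus a JSON manifest
* rankings / records   self-describing TSVs
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import LabeledGraph
from .kge import EmbeddingSet
from .ontology import (
    ASSOCIATED_WITH,
    HAS_PHENOTYPE,
    HAS_SYMPTOM,
    AssociationTable,
    Ontology,
    parse_axiom_tsv,
    parse_obo,
    write_axiom_tsv,
)
from .ranking import RankedList

logger = logging.getLogger(__name__)

SCORE_DIGITS = 10  # rankings are printed with 10 significant digits


def read_ontology(path: str | Path) -> Ontology:
    """Read an ontology from an axiom TSV or an OBO-subset file, sniffed
    by extension (.obo) falling back to content inspection."""
    path = Path(path)
    if path.suffix == ".obo" or path.read_text(encoding="utf-8").lstrip().startswith("format-version"):
        return parse_obo(str(path))
    return parse_axiom_tsv(path.read_text(encoding="utf-8"))


def write_ontology(ontology: Ontology, path: str | Path) -> None:
    Path(path).write_text(write_axiom_tsv(ontology), encoding="utf-8")


def _read_pair_table(path: str | Path, required: tuple[str, str], relation: str) -> AssociationTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty association file", path)
        return AssociationTable(relation, {})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.info("%s: ignoring extra column(s) %s", path, extra)
    df = df[list(required)].dropna()
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        logger.info("%s: dropped %d duplicate row(s)", path, n_before - len(df))
    return AssociationTable.from_pairs(relation, list(df.itertuples(index=False, name=None)))


def read_gene_phenotype_table(path: str | Path) -> AssociationTable:
    return _read_pair_table(path, ("gene_id", "phenotype_id"), HAS_PHENOTYPE)


def read_disease_phenotype_table(path: str | Path) -> AssociationTable:
    return _read_pair_table(path, ("database_id", "phenotype_id"), HAS_SYMPTOM)


def read_gda_table(path: str | Path) -> AssociationTable:
    table = _read_pair_table(path, ("gene_id", "disease_id"), ASSOCIATED_WITH)
    # the GDA dialect is gene -> disease per row; profiles are keyed by disease
    pairs = [(d, g) for g, terms in table.profiles.items() for d in terms]
    return AssociationTable.from_pairs(ASSOCIATED_WITH, pairs)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    header = {
        HAS_PHENOTYPE: ("gene_id", "phenotype_id"),
        HAS_SYMPTOM: ("database_id", "phenotype_id"),
        ASSOCIATED_WITH: ("gene_id", "disease_id"),
    }[table.relation]
    rows = ["\t".join(header)]
    if table.relation == ASSOCIATED_WITH:
        rows += [f"{g}\t{d}" for d, genes in sorted(table.profiles.items()) for g in sorted(genes)]
    else:
        rows += [f"{e}\t{t}" for e, t in table.pairs()]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def write_graph(graph: LabeledGraph, path: str | Path) -> None:
    rows = ["head\trelation\ttail"]
    rows += [f"{h}\t{r}\t{t}" for h, r, t in graph.sorted_edges()]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_graph(path: str | Path) -> LabeledGraph:
    edges = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "head\trelation\ttail":
            raise ValueError(f"{path}: expected edge-list header, got {header.strip()!r}")
        for line in fh:
            if line.strip():
                h, r, t = line.rstrip("\n").split("\t")
                edges.add((h, r, t))
    nodes = {h for h, _, _ in edges} | {t for _, _, t in edges}
    return LabeledGraph(frozenset(nodes), frozenset(edges))


def write_ic_table(ic, path: str | Path) -> None:
    rows = ["term\tic"] + [f"{t}\t{v:.{SCORE_DIGITS}g}" for t, v in sorted(ic.ic.items())]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def _write_matrix(ids: Sequence[str], matrix: np.ndarray, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, row in zip(ids, matrix):
            fh.write(name + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def _read_matrix(path: Path) -> tuple[list[str], np.ndarray]:
    ids, rows = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ids, np.array(rows)


def write_embeddings(emb: EmbeddingSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entities = sorted(emb.entity_index, key=emb.entity_index.get)
    relations = sorted(emb.relation_index, key=emb.relation_index.get)
    _write_matrix(entities, emb.entity_vectors, outdir / "entities.tsv")
    _write_matrix(relations, emb.relation_vectors, outdir / "relations.tsv")
    manifest = dict(emb.meta)
    manifest["model"] = emb.model
    if emb.relation_normals is not None:
        _write_matrix(relations, emb.relation_normals, outdir / "relation_normals.tsv")
    if emb.entity_projections is not None:
        _write_matrix(entities, emb.entity_projections, outdir / "entity_projections.tsv")
    if emb.conv_filters is not None:
        _write_matrix([f"filter_{i}" for i in range(len(emb.conv_filters))],
                      emb.conv_filters, outdir / "conv_filters.tsv")
        _write_matrix(["conv_weight"], emb.conv_weight[None, :], outdir / "conv_weight.tsv")
        manifest["conv_bias"] = emb.conv_bias
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_embeddings(indir: str | Path) -> EmbeddingSet:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    entities, evec = _read_matrix(indir / "entities.tsv")
    relations, rvec = _read_matrix(indir / "relations.tsv")
    kwargs = {}
    if (indir / "relation_normals.tsv").exists():
        _, kwargs["relation_normals"] = _read_matrix(indir / "relation_normals.tsv")
    if (indir / "entity_projections.tsv").exists():
        _, kwargs["entity_projections"] = _read_matrix(indir / "entity_projections.tsv")
    if (indir / "conv_filters.tsv").exists():
        _, kwargs["conv_filters"] = _read_matrix(indir / "conv_filters.tsv")
        _, w = _read_matrix(indir / "conv_weight.tsv")
        kwargs["conv_weight"] = w[0]
        kwargs["conv_bias"] = manifest["conv_bias"]
    return EmbeddingSet(
        model=manifest["model"],
        entity_index={e: i for i, e in enumerate(entities)},
        relation_index={r: i for i, r in enumerate(relations)},
        entity_vectors=evec,
        relation_vectors=rvec,
        meta=manifest,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# rankings and metric reports
# ---------------------------------------------------------------------------

def write_rankings(ranked: Iterable[RankedList], path: str | Path) -> None:
    rows = ["disease\tgene\tscore\tposition"]
    for rl in ranked:
        for pos, (gene, score) in enumerate(rl.entries, start=1):
            rows.append(f"{rl.disease}\t{gene}\t{score:.{SCORE_DIGITS}g}\t{pos}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_rankings(path: str | Path) -> list[RankedList]:
    df = pd.read_csv(path, sep="\t", dtype={"disease": str, "gene": str})
    out = []
    if df.empty:
        return out
    for disease, group in df.groupby("disease", sort=True):
        group = group.sort_values("position")
        out.append(RankedList(disease, tuple(zip(group["gene"], group["score"].astype(float)))))
    return out


def write_records(records, path: str | Path) -> None:
    rows = ["disease\tgene\trank\tn_candidates"]
    rows += [f"{r.disease}\t{r.gene}\t{r.rank:.6g}\t{r.n_candidates}" for r in records]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_records(path: str | Path):
    from .evaluation import RankRecord

    df = pd.read_csv(path, sep="\t", dtype={"disease": str, "gene": str})
    return [
        RankRecord(r.disease, r.gene, float(r.rank), int(r.n_candidates))
        for r in df.itertuples(index=False)
    ]
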