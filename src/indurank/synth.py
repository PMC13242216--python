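"""Synthetic two-species phenome generation.

The generator emulates, at desk scale, the data shapes this package
consumes: two species-specific phenotype taxonomies (mouse-like ``MPX:``
and human-like ``HPX:`` terms) under a shared root, bridged by
cross-species equivalence axioms between aligned leaves; genes annotated
with mouse-side leaf terms, diseases with human-side leaf terms; and
planted gene-disease associations.

The generative story is module-structured: leaves are grouped into
aligned cross-species modules, each gene and disease draws most of its
annotations from one module (a fraction ``annotation_noise`` comes from
other modules), and a disease's causative genes are drawn from its own
module.  This is the minimal structure under which both IC-based and
embedding-based similarity should recover the planted associations; no
claim of biological realism is made.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ontology import ASSOCIATED_WITH, HAS_PHENOTYPE, HAS_SYMPTOM, AssociationTable, Axiom, Ontology

SHARED_ROOT = "PHEN:0000000"


@dataclass(frozen=True)
class SynthConfig:
    """Shape and difficulty of the synthetic phenome.

    The default is the desk-scale preset: ~80 phenotype terms per
    species in 6 aligned modules, 60 genes, 30 diseases, 4-8 annotations
    per entity, full cross-species bridging, 10% off-module annotation
    noise and one planted causative gene per disease.
    """

    n_modules: int = 6
    depth: int = 3
    branching: int = 3
    n_genes: int = 60
    n_diseases: int = 30
    annotations_min: int = 4
    annotations_max: int = 8
    cross_species_bridge_rate: float = 1.0
    annotation_noise: float = 0.1
    gda_per_disease: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_modules", "depth", "branching", "n_genes", "n_diseases",
                     "annotations_min", "annotations_max", "gda_per_disease"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cross_species_bridge_rate", "annotation_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.annotations_min > self.annotations_max:
            raise ValueError("annotations_min > annotations_max")


def default_preset() -> SynthConfig:
    return SynthConfig()


def _species_tree(prefix: str, config: SynthConfig):
    """Build one species taxonomy: root -> module roots -> full
    ``branching``-ary tree of height depth-1 under each module root.

    Returns (axioms, root id, per-module leaf lists).  Node numbering is
    deterministic so aligned species trees are isomorphic by index.
    """
    axioms: list[Axiom] = []
    counter = 0

    def new_term():
        nonlocal counter
        term = f"{prefix}:{counter:07d}"
        counter += 1
        return term

    root = new_term()
    module_leaves: list[list[str]] = []
    for _m in range(config.n_modules):
        mroot = new_term()
        axioms.append(Axiom(mroot, "SubClassOf", root))
        frontier = [mroot]
        for _level in range(config.depth - 1):
            nxt = []
            for parent in frontier:
                for _ in range(config.branching):
                    child = new_term()
                    axioms.append(Axiom(child, "SubClassOf", parent))
                    nxt.append(child)
            frontier = nxt
        module_leaves.append(frontier)
    return axioms, root, module_leaves


def _draw_profile(rng, module: int, per_module_leaves, config: SynthConfig) -> frozenset[str]:
    own = per_module_leaves[module]
    n = int(rng.integers(config.annotations_min, config.annotations_max + 1))
    if n > len(own):
        raise ValueError(
            f"module of {len(own)} leaves cannot supply {n} annotations; "
            "increase depth/branching or lower annotations_max"
        )
    terms = list(rng.choice(own, size=n, replace=False))
    other = [
        leaf for m, leaves in enumerate(per_module_leaves) if m != module for leaf in leaves
    ]
    for i in range(n):
        if rng.random() < config.annotation_noise:
            terms[i] = other[int(rng.integers(0, len(other)))]
    return frozenset(terms)


def generate_phenome(
    config: SynthConfig,
) -> tuple[Ontology, AssociationTable, AssociationTable, AssociationTable]:
    """Generate (ontology, gene, disease, GDA association tables).

    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mp_axioms, mp_root, mp_leaves = _species_tree("MPX", config)
    hp_axioms, hp_root, hp_leaves = _species_tree("HPX", config)
    axioms = mp_axioms + hp_axioms
    axioms.append(Axiom(mp_root, "SubClassOf", SHARED_ROOT))
    axioms.append(Axiom(hp_root, "SubClassOf", SHARED_ROOT))

    # cross-species bridges between aligned leaves
    for m in range(config.n_modules):
        for mp_leaf, hp_leaf in zip(mp_leaves[m], hp_leaves[m]):
            if rng.random() < config.cross_species_bridge_rate:
                axioms.append(Axiom(mp_leaf, "EquivalentTo", hp_leaf))
    ontology = Ontology.from_axioms(axioms)

    genes = [f"GENE:{i:05d}" for i in range(config.n_genes)]
    diseases = [f"DIS:{i:05d}" for i in range(config.n_diseases)]
    gene_module = {g: i % config.n_modules for i, g in enumerate(genes)}
    disease_module = {d: i % config.n_modules for i, d in enumerate(diseases)}

    gene_profiles = {
        g: _draw_profile(rng, gene_module[g], mp_leaves, config) for g in genes
    }
    disease_profiles = {
        d: _draw_profile(rng, disease_module[d], hp_leaves, config) for d in diseases
    }
    gda_profiles = {}
    for d in diseases:
        pool = [g for g in genes if gene_module[g] == disease_module[d]]
        n = min(config.gda_per_disease, len(pool))
        gda_profiles[d] = frozenset(rng.choice(pool, size=n, replace=False))

    return (
        ontology,
        AssociationTable(HAS_PHENOTYPE, gene_profiles),
        AssociationTable(HAS_SYMPTOM, disease_profiles),
        AssociationTable(ASSOCIATED_WITH, gda_profiles),
    )


def random_dag(n_terms: int, seed: int = 0) -> Ontology:
    """Single-rooted random subsumption DAG (oracle-test substrate).

    Term ``T:0`` is the root; every later term gets one or two parents
    among earlier terms, so acyclicity and root reachability hold by
    construction.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    terms = [f"T:{i:04d}" for i in range(n_terms)]
    axioms = []
    for i in range(1, n_terms):
        n_parents = 1 if i == 1 else int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            axioms.append(Axiom(terms[i], "SubClassOf", terms[int(p)]))
    return Ontology.from_axioms(axioms)
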