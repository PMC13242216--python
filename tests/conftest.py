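import math

import numpy as np
import pytest

import indurank as ir

LN2 = math.log(2.0)
LN4 = math.log(4.0)


@pytest.fixture(scope="session")
def toy_ontology():
    """Five-class DAG: P_A1, P_A2 under P_A; P_B1 under P_B; both under ROOT."""
    axioms = [
        ir.Axiom("P_A1", "SubClassOf", "P_A"),
        ir.Axiom("P_A2", "SubClassOf", "P_A"),
        ir.Axiom("P_B1", "SubClassOf", "P_B"),
        ir.Axiom("P_A", "SubClassOf", "ROOT"),
        ir.Axiom("P_B", "SubClassOf", "ROOT"),
    ]
    return ir.Ontology.from_axioms(axioms)


@pytest.fixture(scope="session")
def toy_corpus():
    return ir.AssociationTable(
        ir.HAS_PHENOTYPE,
        {
            "g1": frozenset({"P_A1"}),
            "g2": frozenset({"P_A2"}),
            "g3": frozenset({"P_B1"}),
            "g4": frozenset({"P_B1"}),
        },
    )


@pytest.fixture(scope="session")
def toy_ic(toy_ontology, toy_corpus):
    return ir.compute_ic(toy_ontology, toy_corpus)


@pytest.fixture(scope="session")
def preset_data():
    """Synthetic phenome at the default desk-scale preset."""
    return ir.generate_phenome(ir.default_preset())


@pytest.fixture(scope="session")
def trained_transd(preset_data):
    """TransD embeddings of G4 with a 20% disease holdout (seed 0)."""
    onto, genes, diseases, gdas = preset_data
    disease_ids = sorted(diseases.profiles)
    rng = np.random.default_rng(0)
    test = frozenset(rng.choice(disease_ids, size=6, replace=False))
    train_gda = gdas.restrict_to(set(disease_ids) - test)
    graph = ir.build_variant(onto, genes, diseases, train_gda, "G4", test)
    est = ir.KnowledgeGraphEmbedding(
        model="transd", dim=32, epochs=150, learning_rate=0.01, random_state=0
    ).fit(graph)
    return est.embedding_, test
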