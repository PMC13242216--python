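"""Brute-force reference implementations used only by the tests.

Everything here is deliberately naive -- explicit set enumeration and
pair counting -- and independent of the library's own code paths, so a
disagreement points at a real defect rather than a shared bug.
"""

from __future__ import annotations

import math


def brute_ancestors(axioms, term):
    """Reflexive ancestor set by fixpoint iteration over SubClassOf and
    (symmetric) EquivalentTo axioms."""
    anc = {term}
    changed = True
    while changed:
        changed = False
        for ax in axioms:
            if ax.kind == "SubClassOf" and ax.subject in anc and ax.object not in anc:
                anc.add(ax.object)
                changed = True
            elif ax.kind == "EquivalentTo":
                if ax.subject in anc and ax.object not in anc:
                    anc.add(ax.object)
                    changed = True
                if ax.object in anc and ax.subject not in anc:
                    anc.add(ax.subject)
                    changed = True
    return anc


def brute_ic(ontology, corpus):
    """Propagated-count IC per class; zero-count terms get ln(corpus size)."""
    n = len(corpus.profiles)
    counts = {}
    for _entity, terms in corpus.profiles.items():
        covered = set()
        for t in terms:
            covered |= brute_ancestors(ontology.axioms, t)
        for c in covered:
            counts[c] = counts.get(c, 0) + 1
    return {
        c: (-math.log(counts[c] / n) if c in counts else math.log(n))
        for c in ontology.classes
    }


def brute_resnik(ontology, ic, p1, p2):
    common = brute_ancestors(ontology.axioms, p1) & brute_ancestors(ontology.axioms, p2)
    return max(ic[c] for c in common) if common else 0.0


def brute_lin(ontology, ic, p1, p2):
    denom = ic[p1] + ic[p2]
    if denom == 0:
        return 0.0
    return 2.0 * brute_resnik(ontology, ic, p1, p2) / denom


def brute_bma_bmm(pairwise, pg, pd):
    pg, pd = sorted(pg), sorted(pd)
    row = sum(max(pairwise(a, b) for b in pd) for a in pg) / len(pg)
    col = sum(max(pairwise(a, b) for a in pg) for b in pd) / len(pd)
    return (row + col) / 2.0, max(row, col)


def brute_simgic(ontology, ic, pg, pd):
    ct_g = set()
    for t in pg:
        ct_g |= brute_ancestors(ontology.axioms, t)
    ct_d = set()
    for t in pd:
        ct_d |= brute_ancestors(ontology.axioms, t)
    denom = sum(ic[c] for c in ct_g | ct_d)
    if denom == 0:
        return 0.0
    return sum(ic[c] for c in ct_g & ct_d) / denom


def brute_auc_from_scores(scores, true_gene):
    """AUC of one positive among candidates by explicit pair counting
    (ties count one half)."""
    s = scores[true_gene]
    others = [v for g, v in scores.items() if g != true_gene]
    if not others:
        return 1.0
    wins = sum(1.0 if s > v else 0.5 if s == v else 0.0 for v in others)
    return wins / len(others)


def brute_metrics(ranks_and_sizes, ks):
    """MR/MRR/Hits@k from a list of (tie-averaged rank, n_candidates)."""
    n = len(ranks_and_sizes)
    mr = sum(r for r, _ in ranks_and_sizes) / n
    mrr = sum(1.0 / r for r, _ in ranks_and_sizes) / n
    hits = {k: sum(1 for r, _ in ranks_and_sizes if r <= k) / n for k in ks}
    return mr, mrr, hits
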