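# Methods

This note documents the models implemented in `indurank`, the choices
made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Ontology dialect and graph projection

An ontology is a signature (classes, roles, individuals) with axioms of
three kinds: named-class subsumption `C ⊑ D`, existential restriction
`C ⊑ ∃R.D`, and equivalence `C ≡ D`. This is deliberately far short of
OWL 2 — no nested class expressions, cardinality, or annotation axioms —
but covers exactly what a phenotype taxonomy with cross-species bridges
and association axioms needs. Unsupported constructs are rejected at
parse time. Supported inputs are a flat axiom TSV and an OBO subset
(`is_a`, `relationship`, `equivalent_to`), the latter read via `obonet`.

Projection is purely structural: `C ⊑ D` → edge `(C, subClassOf, D)`;
`C ⊑ ∃R.D` → edge `(C, R, D)`; `C ≡ D` → two reciprocal `subClassOf`
edges. The equivalence rule makes equivalent terms mutual ancestors,
which is how cross-species phenotype bridges become navigable both for
the embedding models and for the IC measures. Inverse edges for
existential relations are off by default (`include_inverse=True`
materializes them); no lexical/literal channel exists. The `SubClassOf`
fragment must be acyclic; equivalence-induced two-cycles are exempt by
construction.

Associations become existential axioms (`gene ⊑ ∃has_phenotype.P`,
`disease ⊑ ∃has_symptom.P`, `disease ⊑ ∃associated_with.gene`).
Association pairs whose phenotype term is missing from the ontology are
dropped with a logged count, mirroring how association files routinely
cite terms absent from the ontology release in use.

Six graph variants: G1 (ontology only), G2 (+gene–phenotype), G3
(+training-disease phenotypes), G4 (+training GDAs), and transductive
G3T/G4T which add test-disease phenotype edges (never test GDAs). A
leakage guard makes any test-disease GDA in a builder input a hard
error, and the inductive variants additionally verify that no
test-disease node survives into the graph.

## Information-content baselines

IC is computed over the **gene** annotation corpus: annotation counts
are propagated through the reflexive subsumption closure before
frequencies are taken (an entity annotated to a term counts once for
the term and each ancestor), and `IC(p) = −ln P(p)` in nats. Terms with
zero propagated count receive the maximal attainable IC,
`ln(corpus size)`, rather than infinity; this keeps Lin and SimGIC
finite on sparse corpora while preserving "rarest possible" semantics.
MICA search runs over the same closure (subsumption plus equivalence;
existential-restriction edges are not subsumptions), with ties broken
lexicographically — the IC value of any maximizer is unique.

Pairwise Resnik is `IC(MICA)`; Lin is `2·IC(MICA)/(IC(p1)+IC(p2))`
(0 when the denominator is 0). Groupwise BMA/BMM are the mean/max of
the two directional best-match means of the pairwise matrix; SimGIC is
the IC-weighted Jaccard of the reflexive ancestor closures of the two
term sets (1 for identical sets, 0 when the union has zero total IC).

## Knowledge-graph embedding models

Four scoring functions, higher = more plausible:

| model  | score f(h, r, t) |
|--------|------------------|
| TransE | −‖h + r − t‖_p, p ∈ {1, 2} (default 2) |
| TransH | −‖(h − w_rᵀh·w_r) + r − (t − w_rᵀt·w_r)‖₂², ‖w_r‖ = 1 |
| TransD | −‖(w_r w_hᵀ + I)h + r − (w_r w_tᵀ + I)t‖₂² |
| ConvKB | [v₁;…;v_τ]·w with v_i = ReLU(ω_i ∗ [h, r, t] + b), filter width 3 |

TransH uses the canonical hyperplane projection with `w_r` in both
occurrences. TransD entities carry an embedding and a projection
vector; `I` is the rectangular identity when the relation-space
dimension k differs from d (default k = d). ConvKB's filters span the
three columns of the stacked d×3 matrix and slide down its rows.

Training is mini-batch gradient descent on a margin ranking loss
`max(0, γ − f(pos) + f(neg))` for the translational models and a
soft-margin logistic loss (with L2 regularization of the output weight)
for ConvKB — each model's original formulation, since no single loss is
canonical across them. Negatives corrupt the head or tail (probability
½ each) with a uniformly drawn entity, unfiltered. Gradients are
derived analytically and validated in the test suite against central
finite differences; optimization is a hand-rolled Adam (plain SGD
available). Entity norms are clipped to ≤ 1 after every step for the
translational models, and TransH normals are renormalized to unit
length. Initialization is Xavier-uniform; TransD projection vectors
start at zero, so TransD begins as squared-distance TransE and learns
its projections from there. ConvKB must be warm-started from pretrained
TransE embeddings, and "ConvKB-D" from TransD embeddings; an override
flag permits random initialization for experimentation.

Everything is plain numpy: at the graph sizes this package targets
(hundreds of nodes, ~10³ edges) a vectorized numpy loop trains any of
these models in seconds on one CPU, and runs are bit-reproducible under
a fixed seed in single-threaded mode. Multi-threaded BLAS can introduce
run-to-run nondeterminism and is not assumed.

Desk-scale defaults are d = 64, 200 epochs, batch 256, lr 0.01, margin
1, 2 negatives per positive; tests and the acceptance script use d = 32
and 150 epochs, which is where the planted-signal benchmark saturates.
The full-scale hyperparameter grid (d ∈ {100…400}, batch ∈ {1024…8192},
lr ∈ {1e-4…1e-2}, τ ∈ {100, 200}) is exposed as `DEFAULT_GRID` but not
run at desk scale.

## Inductive ranking

`sim_e(p, q) = σ(⟨p, q⟩)` over phenotype vectors, aggregated with BMA
(default — it consistently matches or beats BMM, and the evaluation
asserts this) or BMM. Embeddings enter the dot product unnormalized; an
optional flag L2-normalizes them for cosine-kernel behavior. The
candidate universe is every gene with at least one surviving phenotype
annotation. Output rankings are sorted by descending score with
lexicographic tie-breaks for reproducible files; evaluation recomputes
tie-averaged fractional ranks from the raw scores.

Numerical caveats, documented rather than hidden:

* σ saturates to exactly 1.0 in float64 once the dot product exceeds
  ~37. Under the entity-norm constraint (‖e‖ ≤ 1) dot products are
  bounded by 1 and the sigmoid is a strict monotone map, so orderings
  under `sim_e` and under the raw dot product coincide; with
  unconstrained vectors of large norm, saturation can tie scores.
* Multiplying all embeddings by c > 0 transforms every pairwise
  similarity monotonically and therefore preserves pairwise orderings,
  but BMA-aggregated orderings are *not* scale-invariant in general:
  the sigmoid is nonlinear, so directional best-match means can
  reorder. Scores are only comparable within one embedding set.

Transductive scorers (`sim_e(g, d)` on entity vectors, and the model's
own `f(g, associated_with, d)`) are provided for comparison; both raise
a named `UnknownEntityError` on any entity absent from the embedding
vocabulary, which is exactly the failure mode that motivates the
inductive scorer. The inductive contract requires only that the query's
phenotype *terms* are known — novel diseases are fine, novel terms are
not.

## Evaluation protocol

Diseases are randomly partitioned into k folds (default 10). Per fold,
the training graph is built with the fold's test diseases excluded
(leakage-guarded), and test diseases whose phenotype profile **and**
gene set both exactly duplicate a training disease are dropped. Every
true association of each surviving test disease yields one rank record:
the tie-averaged rank of the true gene among all candidate genes.
Default evaluation is unfiltered (a disease's other true genes stay in
the candidate list); a filtered mode excludes them and can only improve
ranks. Metrics: MR, MRR, Hits@k, and AUC computed per record as
`(N − rank)/(N − 1)` (1 when N = 1), which equals the probability that
the true association outranks a random non-association under
tie-averaging; fold aggregates are mean ± sample s.d. Method comparison
uses the two-sided Wilcoxon signed-rank test on paired ranks, dropping
zero differences and refusing the degenerate all-zero case.

All randomness fans out from one master seed through a splitmix64-style
labeled derivation (`indurank._seeds.derive_seed`), so a full
`run_experiment` is byte-identical across reruns with the same config.

## Synthetic phenome

The generator emulates the *shapes* of the real inputs: two isomorphic
species taxonomies (`MPX:`/`HPX:`) under a shared root — per species a
root, `n_modules` module roots, and a full `branching`-ary tree of
height `depth − 1` beneath each (defaults 6/3/3 → 79 terms per
species) — with equivalence bridges between aligned leaves at rate
`cross_species_bridge_rate`. Genes (60) are annotated with 4–8 mouse
leaves and diseases (30) with 4–8 human leaves, drawn from one module
with a fraction `annotation_noise` replaced by off-module leaves; each
disease's planted causative gene comes from its own module.

Defaults where a choice had to be made once: full bridging (the
cross-species ontology's whole point is comparability, and most
phenotype classes in such ontologies are bridged) and 10% annotation
noise (so profiles are informative but not trivially identical;
module-pure annotations make the task near-degenerate). Module-
structured annotation is the minimal generative story under which both
IC-based and embedding-based similarity should recover planted
associations. What this deliberately does **not** model: realistic
HPO/MP topology statistics, annotation-frequency imbalance between
species, granularity bias, or patient-level phenotyping. Passing the
planted-signal benchmark therefore shows the pipeline is correct and
the signal path works end to end — not that real-data performance
numbers transfer.

On this benchmark (five generator replicates, 20% disease holdout,
TransD d = 32), the inductive BMA scorer on G4 and the IC baselines all
reach AUC ≈ 0.9 while a label-permuted control stays near 0.5 — at desk
scale the planted signal is recoverable by taxonomy alone, so the
embedding method's advantage over IC baselines on real data is *not*
reproduced here, only parity and correctness.

## Known limitations

* No OWL 2 parsing or DL reasoning; real ontology releases can be
  ingested only through the OBO subset.
* The KGE stack is CPU-bound numpy; it is not intended for
  million-edge graphs.
* `filter_duplicate_test_diseases` requires exact profile equality;
  near-duplicates are kept.
* The aggregation function is fixed (BMA/BMM); it is not learned
  jointly with the embeddings.
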