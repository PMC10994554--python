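# Methods

## Step-enabling entities

A pathway is modeled as steps enabled by molecular entities. Raw participants
form trees of three node kinds: `protein` (leaf), `complex` (AND over
children), `set` (OR over children). Flattening reduces every tree to
*step-enabling entities* — solo genes or gene sets:

- a protein becomes one solo entity;
- a complex concatenates its flattened children: if a complex is required,
  every subunit is treated as required, accepting that this permits partial
  contribution to enrichment where biology may be all-or-nothing;
- a set whose descendants are all proteins becomes a single set entity over
  the union of its leaf genes (nested pure-protein sets dissolve; a singleton
  collapses to a solo entity);
- a set containing at least one complex takes the intersection of its
  children's leaf-gene sets as shared subunits (one solo entity each) and
  pools every remaining leaf gene into one remainder set. This faithfully
  represents families of complexes differing in one subunit (prolyl
  4-hydroxylase: `P4HB1 AND (P4HA1 OR P4HA2 OR P4HA3)`) and is knowingly
  lossy for heterogeneous groups: with `C3 = P1 & Pc & Pd` alongside
  `P1 & Pa` and `P1 & Pb`, the simplification `P1 & {Pa|Pb|Pc|Pd}` lets the
  input `[P1, Pc]` count the whole group.

Entities are identified by `kind:sorted-members`; flattening output is sorted
by this id, so child order never matters. Within a pathway entities are
deduplicated by id; distinct entities sharing genes are kept (a gene that
solely enables one step and sits in a set at another can legitimately count
twice). The background is the union of entity ids across all pathways
(`M_entities`) and of all annotated genes (`M_genes`); a solo and a set
sharing a gene remain distinct background entities.

## The tests

Input genes are normalized (trim + uppercase), intersected with the annotated
gene universe, and mapped once to background entities: every set with ≥ 1
member present plus every matching solo. Per pathway:

- **gene** method: `k = |input ∩ gene list|`, `n = |gene list|`,
  `N = |annotated input|`, `M = M_genes`;
- **step** method: the same quantities over entities, `M = M_entities`;
- p-value: one-tailed hypergeometric `P(K ≥ k)` (scipy's log-space survival
  function; verified against exhaustive subset enumeration for all tuples
  with `M ≤ 12` at 1e-12).

Each input list is tested against every pathway in the database and adjusted
together by Benjamini–Hochberg (statsmodels `fdr_bh`; checked against the
step-up definition on random vectors). Results are ordered by raw p, ties by
pathway id. The default significance threshold is FDR = 0.10 (0.05
available); up- and down-regulated lists should be run separately, and the
method is intended for data from a single cell type or state, where one
regulatory strategy per set is plausible.

## The weighted test

The step null gives every entity equal sampling probability, but an entity of
`w` genes offers `w` chances for a uniformly drawn gene to activate it. The
weighted test assigns each entity weight = member count and models the class
composition of the drawn entities with the multivariate Fisher's noncentral
hypergeometric distribution: independent draws with odds proportional to
weights, conditioned on the total `N`. Fisher's conditioned-independence
model (not Wallenius's sequential-draw model) is used because a
differential-expression experiment fixes `N` only after the fact and draw
order has no biological meaning.

Urn construction per tested pathway:

- pathway entities are grouped ("compressed") into classes of identical
  weight — exact by the Vandermonde identity, and it shrinks the outcome
  space; weights are integers for pathway entities;
- the background is the `M_entities − n` entities outside the pathway,
  approximated by a single class at their mean weight rounded to exactly two
  decimal places. This preserves the pathway-vs-background odds; a two-group
  background split at the median weight is deliberately not implemented — it
  multiplies runtime by orders of magnitude for a negligible p-value change.

For composition `x` over the classes (`Σx = N`, `x_i ≤ m_i`):

    P(x) = Π_i C(m_i, x_i) w_i^{x_i} / Z.

`Z` and the tail masses are read off per-class generating polynomials
`Σ_x C(m,x) w^x t^x`, convolved in log space (log-sum-exp): the coefficient
of degree `j` in the pathway-classes product, times the background term
`C(bg, N−j) w_bg^{N−j}`, is the unnormalized mass of all outcomes with
pathway total `j`. `weighted_tail_p(k)` sums degrees `j ≥ k` and divides by
`Z`; outcomes with `N − j > bg_count` are infeasible (probability 0). This is
exactly the sum of `mfnchg_pmf` over `enumerate_outcomes(j)` (asserted in
tests) without enumeration, and stays stable for backgrounds up to ~10^4
entities and thousands of draws. Final probabilities are clipped to [0, 1];
tail sums run over ascending `j`; enumeration order, where used, is
lexicographic.

`simulate_urn` provides an independent Monte-Carlo oracle: exact sequential
conditional sampling (class `i` count given `r` remaining draws is
categorical with mass `poly_i[v] · suffixpoly_{i+1}[r−v]`), seeded
explicitly. The gene-first simulation null (uniform gene draws scored with
the entity statistic) is not a production method; the sampler covers its
validation role.

Global weight scaling cancels in `P(x)`, so unit weights (databases with no
sets) reduce the weighted test to the unweighted step test — verified to
1e-9 over 100 random databases. Increasing a pathway weight cannot decrease
the tail p at fixed k: set-heavy pathways are penalized relative to the
unweighted step test, but the weighted background (mean weight > 1) offsets
the sensitivity the unweighted method loses from its smaller probability
mass.

## GO-CAM ingestion

Models are parsed from RDF Turtle with rdflib. The model id is the
`owl:Ontology` node; state comes from the `lego:modelstate` annotation and
taxa from RO:0002162. Activity nodes are individuals typed with a
GO-namespace class; causal edges are triples between activity nodes over the
RO causal-relation family; enablers come from `enabled by` (RO:0002333),
recording the enabler individual's class IRI. Filtering keeps models with at
least 3 activities linked by 2 causal edges (configurable) in production
state; Reactome-derived conversions (`R-HSA-`/`R-MMU-` ids), which circulate
before official release, bypass the state check. Steps without an enabler
contribute nothing but do not disqualify a model.

Entity class IRIs resolve through the complex/set ontology: subunits via
`has part` (BFO:0000051) restrictions, set members via `has member`
(RO:0002351), proteins as `identifiers.org/uniprot` IRIs (isoform suffixes
stripped), CHEBI classes (ions, small molecules) dropped; a node left
childless after drops is itself dropped, an IRI absent from the ontology is
an error. Non-human models require a local two-column TSV ortholog table;
unmapped genes are dropped with a counted warning. Ingestion is
deterministic: the native JSON output is byte-identical across reruns.

Limitation: treating every GO-typed individual as an activity can overcount
steps in full release models that embed biological-process or component
context individuals; the filter thresholds are configuration if that matters
for a given corpus.

## Synthetic scenarios

`ScenarioSpec` defines a generator whose defaults emulate a curated pathway
database: 15 pathways of 4–12 entities drawn from a 400-gene pool, 60% solo
proteins, 15% complexes (2–4 subunits), 20% flat sets (2–6 members), 5%
sets-of-complexes sharing a common subunit — sets in the minority but common
enough to matter, mirroring databases where most step enablers are single
gene products. Entities within a pathway use disjoint genes; pathways
overlap through the shared pool. Perturbation lists select a fraction of a
target pathway's entities and emit one member per set by default (the premise
being that a cell need not perturb every interchangeable member to regulate a
step), plus optional noise genes from outside all perturbed pathways. All
randomness flows from the spec's single seed (the input-list stream is the
child seed `[seed, 7919]`); truth labels accompany every list.

What the generator does not emulate: expression magnitudes or count noise
(membership lists only), correlated pathway overlap structure, shared genes
across entities within one pathway, or annotation error — so passing recovery
tests demonstrate statistical correctness of the machinery, not performance
on real transcriptomes.

`brute_force_tail` is the independent oracle: full enumeration of the
outcome space over all classes with exact `fractions.Fraction` arithmetic,
refusing spaces above 10^6 outcomes.

## Numerical and design choices

- Binomial coefficients via `gammaln`; all products/sums of weight masses in
  log space; p-values clipped to [0, 1].
- Weight classes merge only on exact equality (integers for pathway
  entities, one 2-dp decimal for the background), so compression is exact.
- Degenerate inputs: empty input lists yield `k = 0`, `p = 1` everywhere;
  `N = 0` urns put all mass on the empty draw; a background smaller than the
  requested draw count is a domain error.
- Problem sizes in the validation suite (hundreds of brute-forced urns with
  ≤ 5 classes and `m_i ≤ 4`, universes `M ≤ 12` for subset enumeration, 100
  scenario seeds, 10^5 Monte-Carlo replicates) are chosen so the exact
  oracles remain exhaustive while the whole suite runs in seconds.
- Deduplication within and across pathways is by canonical entity id only;
  no attempt is made to merge near-identical pathways arising from different
  curation sources.

## Known limitations

- Overlapping sets violate the independence assumption of the weighted
  distribution (a gene inside several entities correlates their draws); the
  effect is weak between sets and strongest between a solo gene and a set
  containing it.
- Sets counting once toward `k` is lenient when many members of a set change
  together meaningfully; weighting by set size is itself questionable when a
  set encodes tissue-specific expression, since a given cell type cannot
  sample members it never expresses.
- Reaction stoichiometry, kinetics, and interactions among set members are
  out of scope, as is any fold-change-ranked (GSEA-style) statistic or
  depletion test.
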