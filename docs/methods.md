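# Methods

## Data model

A clinical web is a labelled directed graph `D(V, E)`. Each node is one
entity — roughly one tuple of the source relational EHR (patient,
hospitalization, employee, medication, diagnosis, diagnostics, cardiac
record, events plan, lab record) — with a unique string id, a role label
`λ(v)`, and an ordered list of attribute name/value pairs; the
concatenated attribute values are the entity's bag of words. Each edge
carries a role label `λ(e)` (e.g. `prescribed_by`). Role names are never
interpreted by the algorithms except as keys for per-role
authority-transfer rates. A schema graph lists the allowed labels and the
allowed (source label, target label, role) triples; validation reports
violations as data rather than raising, since real dumps can predate
their schema. Self-loops are representable but flagged.

Two ingestion paths exist: tab-delimited node/edge tables (one dialect;
attributes serialized as `name=value` pairs joined by a reserved
control character, so free text with spaces, commas and `=` survives),
and simple XML with ID/IDREF cross-references in the style of HL7 CDA
documents. XML containment edges point parent→child so that authority
flows from the document root toward content; each IDREF adds an edge
from the referring element to its referent. Node-table row order is
significant: it fixes the node indexing of the transfer matrix.

## Content ranking

Tokenization lowercases and splits on any character that is not a
letter, digit or hyphen (hyphenated dates such as `2004-11-03` stay
whole). No stemming and no stop-word removal: rare/common terms are
handled by idf alone. All logarithms are base 10 — the choice is fixed
by the documented worked example (`idf(pericardial) = log(100/10) = 1.0`)
and ranking order is invariant to it.

* tf·idf: `Σᵢ tf(qᵢ)·log₁₀(N/n(qᵢ))`, terms absent from the collection
  contribute zero.
* Okapi BM25: `Σᵢ idf(qᵢ)·tf(qᵢ)(k₁+1)/(tf(qᵢ)+k₁(1−b+b·dl/avdl))` with
  `idf(q) = log₁₀((N−n(q)+0.5)/(n(q)+0.5))`. Defaults `k₁ = 2.0`,
  `b = 0.75` (the conventional choices); negative idf for terms in more
  than half the collection is clamped at zero by default (toggleable).

`CollectionStats` normally derives `N`, `n(q)`, `dl` and `avdl` from the
graph, but every field can be supplied manually to score a node against
the statistics of a larger collection of which the graph is a displayed
subset — that is how the worked example's `N = 100` is reproduced.

## The base set

An entity belongs to the base set S when it contains **all** query terms
(conjunctive). The design space here is genuinely open — a disjunctive
"any term" reading also exists and is provided behind a flag — but the
conjunctive default is what reproduces the documented example
(S = {v1, v4, v5} for "pericardial effusion", exactly the phrase-bearing
entities) and matches phrase-like clinical queries. `phrase_mode`
additionally requires the terms to be contiguous in token order. An
empty base set raises a distinct error; ranking layers translate it into
an empty result list with a logged warning, never a silent zero vector.

## Authority flow

The transfer matrix is column-oriented:
`A[i,j] = rate(role(vⱼ→vᵢ))/OutDeg(vⱼ)`, all rates defaulting to 1.
Dangling entities give zero columns and leak mass — no teleport
renormalization — so `Σr ≤ 1` with equality only on dangling-free
graphs. Reverse edges (authority flowing against the arrow, normalized
by in-degree) are supported but off by default, matching the asymmetric
worked-example matrix.

The fixed point of `r = d·A·r + (1−d)/|S|·s` is found by power iteration
from `r₀ = s/|S|`, stopping when the L1 change drops below
`epsilon = 1e-10` or after `max_iters = 200` iterations (geometric
convergence at rate ≤ d makes both generous; typical clinical webs
converge in well under 30 iterations, layered ones in a handful). The
initialization is not uniquely determined by the problem; `s/|S|` makes
the start consistent with the teleport term, and the fixed point is
initialization-independent anyway. Ties in all rankings break by
ascending node id for determinism.

A note on the documented example: the score vector printed there,
`[0.05, 0, 0, 0.05, 0.05, 0.063, 0.117]`, is described as the state
after one iteration, but it is in fact the *converged* fixed point of
the printed matrix (one true step from `r₀ = s/|S|` gives 0.425 on the
last two components). The package asserts both facts separately: the
initialization-independent 0.05 on no-in-edge base-set entities after
one step, and the full converged vector.

Variants: CO085 (`d = 0.85`), CO030 (`d = 0.30`; smaller d keeps
authority close to the keyword-bearing entities, favouring focused
results), CO085BM25 (per-entity product of the CO085 authority and the
BM25 score, so entities without any query term are excluded). Global
PageRank is the degenerate case S = V and shares the solver.

## Explaining subgraphs

For BM25 results the explanation is the result plus its direct
neighbors (either edge direction) that contain at least one query term.
For CO results it is the union of all directed simple paths of length
≤ `max_path_len` (default 3) from base-set entities to the result;
on-path entities bearing no query term are categorized `intermediate`.
No pruning by authority contribution is performed — every short
keyword-to-result path is shown. Export is Graphviz DOT with the
category as fill colour and the entity's attributes as a tooltip.

## Evaluation protocol

Rankers are compared per query on a pooled universe: the union of every
algorithm's top-k (k = 5 by default, mirroring a top-5 user study).
Results are first restricted to hospitalization entities — a
post-scoring filter, not part of any ranker — because hospitalizations
are the result type of interest and the other entity types serve to rank
them. Against a judged-relevant subset of the pool, each algorithm's
top-k yields TP/FP/FN/TN partitioning the pool, hence sensitivity and
specificity; zero denominators leave a metric undefined and excluded
from the unweighted macro averages. The pool is used as the negative
universe because it is the only universe the raters ever saw; raters are
combined by union of relevant marks (intersection available). Raters may
mark anywhere from 0 to k results relevant.

## Synthetic clinical webs

The generator emulates the shape of a six-month pediatric-cardiology EHR
extract. The shipped study-scale configuration fixes 15,092 entities —
850 hospitalizations, the remaining 14,242 allocated across the other
eight labels as a plausible split (the per-label breakdown of the
original extract is not public) — and 31,492 edges divided among the 11
schema rules. Edge wiring draws both endpoints uniformly within each
rule; no degree distribution is imposed because none is reported for
real extracts. Background text is i.i.d. clinical-flavoured filler,
uniform 20–60 tokens per node, deliberately disjoint from the default
query phrases ("respiratory distress", "pericardial effusion",
"tetralogy of fallot", "edema" — the phrases named in the motivating
study; its full 11-query list is unpublished) so that injected phrases
are the only matches. Injections place a phrase verbatim into a chosen
number of nodes of a chosen label and record every site in a manifest.
Generation is fully deterministic given seed and configuration.

Synthetic judgments mark hospitalizations relevant either when they
contain the phrase themselves (`phrase_in_result`) or when an adjacent
entity does (`phrase_in_neighbors`). The second scenario is the
qualitative heart of the comparison: a content ranker scores such
hospitalizations exactly zero, while authority flow can retrieve them,
so CO sensitivity ≥ BM25 sensitivity holds by construction of the
method, and the test suite verifies it across 20 generated corpora
(~450 entities each; small corpora keep the 20-seed sweep quick while
preserving the full 9-label schema). What these synthetic corpora do
*not* model: realistic clinical language, correlated text between linked
entities, skewed degree distributions, or human judgment noise — so
green tests here demonstrate the algorithmic contrast, not clinical
retrieval quality. The original study's headline percentages
(sensitivity 65% vs 38%) depend on two physicians' unpublished judgments
over a private dataset and are deliberately not targets of this package.

## Numerical and degenerate-input choices

* Convergence in L1; contraction factor ≤ d guaranteed by column sums ≤ 1.
* Dense linear solve of `(I − dA)r = (1−d)/|S|·s` is used in tests as the
  independent oracle for the iterative solver (graphs ≤ 50 nodes).
* Empty graph: transfer matrix construction refuses; empty collection:
  `avdl` is flagged undefined rather than silently zero.
* Duplicate edges accumulate their matrix entries (multigraph semantics).
* Scores are written with 10 significant digits; reruns are
  byte-identical.

## Known limitations

* Authority-transfer rates per role default to 1 everywhere; the
  machinery to weight association types exists, but no calibrated rates
  ship with the package (learning them from feedback is out of scope).
* The ID/IDREF XML path handles the generic mechanism, not full HL7 CDA
  conformance (no namespace-aware template validation).
* No ontology-based query expansion, stemming or fuzzy matching.
* The inverted index is an in-memory dict with a plain-text dump —
  built for corpora of tens of thousands of entities, not millions.
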