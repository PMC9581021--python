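# Methods

## Pipeline overview

`ppistack` predicts binary protein–protein interactions by combining four
evidence channels in a modified stacked scheme: instead of training base
classifiers, the base level consists of deterministic detection-method
scores (sequence, GO semantic similarity per branch, domain, pathway)
that form a six-column feature matrix, and the only trained component is
the meta-level boosted classifier. This keeps feature generation cheap,
reusable and exactly reproducible, and concentrates all statistical
learning in one place.

## Knowledge base

Annotation records are canonicalized (fixed field order, lexicographically
sorted set members, UTF-8) and hashed with SHA-256. The hash is the
identity of a record's content: ingest of an identical record is a no-op,
and staleness against an upstream copy is decided by digest inequality
alone. Absent proteins are a distinct state from proteins with empty
annotation sets — scorers receive an explicit absent marker and degrade
to zero scores with all missing flags set, so "no evidence" is never
silently conflated with "evidence of no interaction".

## Evidence scores

All Jaccard-style scores define 0/0 = 0 (no shared vocabulary means no
evidence, not undefined evidence).

**Domain.** LDP is the per-pair unordered cross product of the two
proteins' domain sets, canonicalized; self-pairs (d, d) arise when both
proteins carry d. The default denominator is |LDC ∪ LDP| — the printed
formula — which makes absolute scores small when the known list LDC is
large. Because the downstream scaling is variance-based, the classifier
is insensitive to this overall magnitude; a `domain_denominator =
"ldp_only"` switch normalizes by |LDP| instead for users who want
interpretable per-pair fractions.

**Ontology similarity.** The Pekar measure needs a lowest common
subsumer. On multi-parent DAGs "deepest common ancestor" (depth = minimal
edge distance from the branch root) is not well behaved: a strict
ancestor of t can be *deeper* than t itself, which would make
sim(t, t) < 1. The LCS is therefore selected as the classical lowest
common ancestor — minimal combined distance to the two terms, ties broken
by maximal depth and then lexicographic term id for determinism. On trees
this coincides with the deepest common ancestor; it preserves
sim(t, t) = 1 for every non-root term, and the root–root degenerate case
returns 0 (no shared information). Distances are shortest paths along
child→parent edges. Term sets are aggregated by the symmetric best-match
average (mean over A of the best match in B, averaged with the B-side
quantity); an empty side scores 0 by the missing-annotation convention.
Ancestor maps and pair similarities are memoized per DAG.

**Sequence.** An external sequence predictor is treated as a pluggable
pair→score table. The self-contained fallback is the Jaccard index of
3-mer sets — a deliberately simple measure whose only role is to make the
pipeline runnable without external tooling; sequences shorter than k
score 0 and non-amino-acid characters are rejected with their position.

## Classification

Scaling divides each feature column by its sample standard deviation
(n−1 denominator), without centering; zero-variance columns pass through
with a warning. The statistics are stored in the model and reused at test
time, never refit. The meta-classifier is AdaBoost over depth-1 decision
trees, 100 rounds — the canonical stump configuration. Training reports
stratified 10-fold cross-validation; the headline metrics pool the
out-of-fold predictions (so the confusion matrix sums to n) and per-fold
metrics are retained. The final model is refit on all rows. The decision
threshold for a positive call is probability ≥ 0.5; the ROC is built by
sweeping the probability threshold and the AUC is the trapezoid-rule
area, which equals the normalized Mann–Whitney statistic. Every report
asserts its own confusion-matrix identities. All randomness flows from a
single experiment seed; training twice with the same inputs and seed
yields bit-identical reports.

## Co-localization filtering

Each known validated interaction contributes one transaction: the union
of the two proteins' cellular-component terms (the adopted reading of
compartment co-occurrence; pairs with absent proteins or empty unions are
dropped and counted). Apriori is run over a strictly descending support
schedule (default 0.5, 0.3, 0.2, 0.1, 0.05; min confidence 0.6), stopping
at the first level whose rules mention every configured "main" component;
components absent from all transactions cannot be covered and are warned
about and excluded from the stop criterion — if none remain, the full
schedule runs. The filter itself is symmetric (one protein's terms must
intersect a rule's antecedent and the other's its consequent, in either
orientation) because physical interaction is symmetric even though rules
are directional. CC terms are matched literally, without ancestor
expansion — a known fidelity limitation when annotations are given at
different granularities.

## Literature evidence mining

Documents are cleaned of markup (reference, acknowledgment and figure
sections discarded), split into sentences, tokenized, lowercased,
POS-tagged, stop-word-filtered and Porter-stemmed. The NLP layer is
self-contained: a classic Porter stemmer, a compact stop-word list, and a
heuristic tagger (closed-class word lists plus suffix rules) whose only
job is separating verbs and nouns — the token classes the evidence rules
consume — from everything else. All lexicons are stemmed with the same
stemmer at load time so matching happens in stem space.

A sentence is interaction evidence iff (i) at least one synonym of each
pair member occurs, (ii) no context-exclusion entry fires (a single term,
or a term-set all of whose members occur), and (iii) at least one
interaction term survives among the verb/noun tokens. Co-occurrence is
same-sentence; no syntactic linking is attempted. The shipped lexicons
are deliberately small starter lists and are plain editable text files.
Experimental-method mentions are recorded on each hit. The per-pair
report asserts the invariant that interaction context implies
co-mention.

## Workflow

Experiments are YAML-configured (mode, datasets, store, resources, model,
jobs, seed) and validated field-by-field before any computation. Each
dataset is an isolated job; jobs run in parallel up to the configured
count with the shared annotation store read concurrently. Every
per-dataset seed is derived as SHA-256(global seed, dataset name) mod
2³¹, so results are independent of scheduling order and parallel output
is byte-identical to sequential output. A failing dataset aborts only
itself; the run manifest records per-dataset status and the number of new
ingests (zero on a repeat run over the same proteins — the knowledge-base
reuse contract).

## Synthetic data

The generators produce every input the pipeline consumes as pure
functions of (spec, seed): per-branch rooted DAGs (each non-root term
gets 1–2 parents among earlier terms, acyclic by construction), an
annotated proteome, balanced labeled pair datasets, known-interaction
lists, and labeled corpora. Planted signal is per-channel: for each
sampled pair an independent Bernoulli draw (probability p_pos for
interacting pairs, p_neg otherwise) rewires the two proteins to share a
GO term per branch, a pathway, or a 20-residue sequence stretch, or
injects the pair's domain combination into the known domain-interaction
list — mirroring how each scorer consumes evidence. Every planted event
is recorded in a manifest sufficient to compute downstream expectations.

Default sizes are chosen to be realistic at desk scale: 100 ontology
terms per branch, 300 domain identifiers, 100 pathways, sequences of
50–200 residues over the 20 canonical amino acids. Small vocabularies
would produce heavy identifier collisions between unrelated proteins —
spurious sharing no real annotation corpus exhibits. Cellular-component
terms are drawn with Zipf weights (weight ∝ 1/rank) because real CC
annotation is dominated by a few major compartments; this concentration
is precisely what makes co-occurrence rules minable. Corpus sentences are
built strictly from the lexicons in three classes — hit (both mentions +
interaction term), excluded (both mentions + exclusion term, emulating
the expression/regulation false-positive mode) and irrelevant — so hit
precision and recall on generator-labeled corpora are exactly measurable.

What the fixtures do **not** emulate: real GO topology and term depth
distributions, UniProt field richness, homology structure between
sequences, or published prose. Passing tests therefore demonstrate the
correctness of the mechanics (scores, mining, rules, contracts) and the
recoverability of planted signal, not field performance on real
proteomes.

## Problem sizes and numerical choices

The standard study conditions used by the test suite and the acceptance
script are 2,000 balanced pairs over 1,000 proteins with p_pos = 0.9 and
p_neg = 0.1 — large enough for stable cross-validation estimates while
keeping a full run in seconds. Oracle-equivalence checks use 1,000 random
inputs per scorer, 100 random DAGs (≤ 50 nodes per branch, tolerance
1e-12; set-arithmetic scores are compared exactly), and exhaustive
itemset enumeration up to 10 items × 30 transactions. The permutation
null accepts accuracy within 0.5 ± 0.05 at n = 2,000.

## Known limitations

* The sequence fallback is a toy; real deployments should plug an actual
  sequence predictor's score table.
* CC rule matching has no ontology-ancestor expansion.
* The heuristic POS tagger is adequate for lexicon-built text and common
  biomedical phrasing, not for general prose.
* Self-pairs (A, A) are allowed and scored, since homodimers exist; pair
  deduplication treats (A, B) and (B, A) as one pair.
* Stale knowledge-base records are kept and flagged, never auto-deleted.
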