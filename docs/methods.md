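# Methods

cldkit analyzes the *structure* of causal loop diagrams (CLDs): signed
directed graphs in which nodes are system variables, each assigned to one
of four biopsychosocial domains (biological, psychological, behavioral,
social), and edges are hypothesized causal connections with polarity
`positive`, `negative` or `ambiguous`. It does not simulate dynamics;
everything here is combinatorial and reproducible from the diagram alone.

## Diagram model and invariants

A diagram is valid when every connection's endpoints resolve to declared
variables, at most one connection exists per ordered pair, and (by
default) no variable connects to itself. Conflicting evidence about one
ordered pair is encoded as a single `ambiguous` connection rather than as
parallel edges. Self-loops can be enabled (`allow_self_loops`), in which
case they are length-1 cycles and fall outside every analysis that uses
the default minimum loop length of 2. Variable ids are slugified labels
(lowercase, hyphenated) so file formats have stable keys while labels keep
their original spelling. Each variable carries exactly one domain even
when it is conceptually integrative (e.g. well-being); multi-domain
membership is out of scope. The exogenous set — variables with in-degree
zero, which influence the system but are not influenced by it and
therefore cannot lie on any feedback loop — is always derived, never
stored.

Native JSON and GraphML round-trip every field (GraphML stores the
citation list as a JSON-encoded string attribute because the format has
no list type). The CSV edge list carries only `source,target,polarity`;
importing it assigns a configurable `default_domain` because the format
cannot express domains. DOT output is for rendering only: solid edges for
positive, dashed for negative, bold for ambiguous polarity.

## Feedback loops

A feedback loop is a directed simple cycle. Classification follows the
standard parity rule: a loop with an odd number of negative-polarity
connections is **balancing** (self-correcting); an even number makes it
**reinforcing** (amplifying). Any ambiguous connection on the cycle makes
the parity, and hence the class, **undetermined**. A loop is
**within-scale** when all its variables share one domain and
**cross-scale** otherwise.

Enumeration is a bounded-depth variant of Johnson's elementary-circuit
search: a depth-first search rooted at each vertex in lexicographic order,
restricted to vertices that sort after the root, with a depth cap. Every
cycle is found exactly once and emitted in its canonical rotation
(lexicographically smallest id first); `enumerate_loops` sorts the result
by (length, sequence), while `iter_loops` streams loops to counters and
participation accumulators in a deterministic single pass, so long length
caps on dense diagrams never materialize the full loop set. Loops through
ambiguous edges are counted in totals and classified undetermined; a
config flag excludes them. (In the diagram that motivated this package
the two ambiguous connections leave exogenous variables and provably lie
on no cycle, so the totals are unaffected either way; explicit handling
future-proofs other diagrams.)

The independent correctness reference is `brute_force_loop_oracle`, which
tests every vertex sequence (one permutation per rotation class, anchored
at the subset's smallest id) and is guarded to diagrams of at most 10
variables. The test suite and the acceptance script check exact agreement
with the fast enumerator over 200 seeded random diagrams for every
(min, max) length window.

**Participation.** For each endogenous variable, the share of all loops
with length in `[min_length, max_length]` (pooled across lengths,
defaults 2–14) that contain it. Percentages are kept as exact rationals
internally and rounded half-up to one decimal only for reporting; rows
are sorted by descending percentage with lexicographic tie-break.
Percentages deliberately do not sum to 100 (each loop has several
members). Since participation is a heuristic whose ranking can shift as
the length cap grows, `ranking_stabilization` finds the smallest cap L at
which the ordered top-k ranking is identical under caps L−1 and L, and
reports the table at L+1 — one cap past the first stable pair. If the
window contains no loops at small caps, all-zero rankings compare equal
(lexicographic order); stability is then declared at the first comparable
pair, which is the intended semantics for single-cycle diagrams.

**Focal queries.** `loops_containing` filters loops by a required
variable set (empty set = plain enumeration); `third_parties` returns the
distinct third variables of length-3 loops through a focal pair; and
`bidirectional_partners` returns those third variables v for which both
cyclic orientations through {a, b, v} exist — the variables that couple
the focal pair in both directions.

**Balancing-loop overlay.** Recovery mechanisms elicited on top of a
problem-focused (all-reinforcing) diagram may pass through auxiliary
variables outside the core CLD, so overlay loops are validated standalone
from their own polarity sequence: the loop must be simple, must have an
odd number of negative polarities (a genuine balancing loop — ambiguous
polarities are not allowed here), and must carry one of four categories:
`homeostatic_resource`, `behavioral`, `clinical`, `interpersonal`. The
categories themselves are expert annotations; the package validates, it
does not assign them.

## Harmonizing expert variable proposals

Free-text proposals from multiple experts are merged in five steps:

1. **Normalization** — lowercase, strip punctuation, drop stopwords,
   preserve token order. The built-in stopword list is deliberately
   small (articles, copulas, common prepositions/conjunctions),
   configurable, and recorded verbatim in the merge manifest so a run is
   reproducible without any external wordlist.
2. **Embedding** — each label is the arithmetic mean of its
   in-vocabulary word vectors; a sentence-level vector can be served by
   the same provider contract. Out-of-vocabulary tokens are skipped in
   the mean; a label with no embeddable token is reported `unembeddable`
   and kept as a singleton routed to manual review, never dropped.
   Real pre-trained backends (GloVe-style word vectors,
   sentence-transformer models) plug in through `EmbeddingProvider`;
   the package ships a deterministic hashing provider (distinct tokens
   get near-orthogonal unit vectors — exact-duplicate detection without
   semantics) and a table-driven fixture provider for tests.
3. **Pair flagging** — unordered pairs with cosine similarity strictly
   above `pair_flag_threshold` (default 0.8) are listed for reviewer
   attention, sorted by descending similarity.
4. **Clustering** — agglomerative clustering on cosine distance
   1 − s with average linkage (damps outliers, yields a monotone,
   inversion-free dendrogram, so lowering the threshold only coarsens
   the partition). The similarity threshold (default 0.58) is applied
   as a distance cut 1 − s on the dendrogram. The threshold can be
   selected from a cutoff-versus-flagged-pair-count curve by the kneedle
   rule: normalize both axes to [0, 1] and return the cutoff maximizing
   the deviation from the chord between the endpoints, or nothing when
   that maximum does not exceed a sensitivity (default 0.01 — a linear
   curve has no knee). Equal-distance merges follow scipy's
   deterministic lowest-index order.
5. **Rating aggregation** — each cluster's importance ratings
   (1–3 per proposal, 3 = high importance) are summed; the cluster
   enters the key-variable list when the sum reaches the cutoff
   (default 3): one high-importance vote suffices, as do three
   low-importance ones. Cluster scores conserve the total rating mass
   under any partition. The suggested representative label is the
   member with the highest summed within-cluster similarity; final
   naming remains an expert decision.

## Mediation audit of direct connections

Empirical support for a causal link does not establish that it is
*direct*: its mechanism may already be represented by other diagram
variables. Given candidate intermediary mechanisms for an edge, the
three-way rule is: **retain** the direct connection if at least one
mechanism is not a diagram variable; **replace with an indirect path**
through the matched variables if mechanisms were named and all of them
match; **remove** if no plausible mechanism was identified. Matching
reuses the harmonization machinery — same provider, same 0.8 pair
threshold — so one notion of "is already a CLD variable" exists in the
package; an exact id/label match (case- and punctuation-insensitive)
short-circuits with similarity 1.0, and an unembeddable mechanism counts
as unmatched (conservatively retaining the edge for manual review).
Multiple matched mechanisms are ordered in the suggested path by
descending similarity — a reporting convention, flagged as such;
polarities along a rerouted path are left to expert judgment. Generation
of the candidate mechanisms themselves (e.g. by a language model) is
out of scope; they arrive as input text.

## Synthetic data

`random_cld` generates diagrams meeting a requested composition
*exactly*: variables per domain, connection count, negative/ambiguous
quotas, and exogenous count. Defaults mirror the published young adult
sleep diagram's shape — 29 variables split 5/7/9/8 across
biological/psychological/behavioral/social, 175 connections with 58
negative and 2 ambiguous, 3 exogenous variables. Construction first gives
every endogenous variable one incoming edge (so the exogenous set is
exactly as requested), then fills the remaining quota uniformly at random
over the still-free ordered pairs, and assigns polarities by exact quota
shuffling rather than independent coin flips. The same seed reproduces
the same diagram byte-for-byte in the native format. Only the summary
shape of the real diagram is emulated, not its topology: loop counts and
participation rankings on synthetic diagrams are properties of the random
ensemble, not estimates of the published diagram's values, which is why
the test suite pins them only through the brute-force oracle and fixture
diagrams. The two fixture sub-diagrams transcribed from the source
figures (the fully bidirectional sleep/depressive-symptoms/smoking triad;
the six-variable cross-scale well-being loop with four negative edges)
are shipped as package data with their polarity rationale recorded per
edge.

`synth_elicitation` plants synonym clusters: each concept receives an
orthonormal anchor direction (QR of a seeded Gaussian matrix) and each
synonym the anchor plus a small perturbation (sigma 0.05), giving a
within-group/between-group similarity gap by construction; the `noise`
parameter in [0, 1] adds perturbation (sigma 0.8 at noise 1) that erodes
the gap, so planted-partition recovery is perfect at zero noise and
degrades monotonically — the generator emulates near-duplicate label
structure and importance ratings, not the semantics of real expert
phrasing, so passing tests demonstrate the pipeline's mechanics, not that
any particular embedding model merges real proposals correctly. Labels
are single pseudo-word tokens so the word and sentence embedding stages
coincide exactly in tests. Ratings are drawn from a configurable
distribution over {1, 2, 3} (default 0.25/0.5/0.25).

## Problem sizes and numerical choices

The default verification workloads are desk-scale: oracle-equivalence
studies use 200 random diagrams of 3–8 variables (seconds in total);
synthetic published-diagram-shaped diagrams are analyzed at length caps 4–5 in
examples and the acceptance script, while the default cap of 14 is
intended for one-off analyses of real diagrams, where the streaming
enumerator's memory stays flat and runtime grows with the loop count.
Cosine similarities are clipped to [−1, 1] against floating-point drift;
zero-norm vectors are rejected rather than silently normalized.
Reproducing the published diagram's own loop counts requires the deposited
interactive diagram, which is distributed separately online; no loader
for that deposit is bundled, and the package's printed-figure fixtures
cover the sub-diagrams reproducible from text alone.

## Known limitations

- No quantitative system-dynamics simulation, loop-dominance analysis or
  trajectory modeling; the package analyzes structure only.
- Participation percentages are a structural heuristic; they say nothing
  about loop strength or timescales.
- The hashing embedding provider carries no semantics; real synonym
  merging needs a pre-trained backend plugged into the provider contract.
- Balancing-loop categories and rerouted-path polarities are expert
  inputs, validated but never inferred.
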