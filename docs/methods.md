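# Methods

## Edge model

A labeled multidigraph over protein identifiers consolidates every
relation between an unordered pair into a single 8-bit code per ordered
direction. Bits 1–2 carry the undirected labels (interacts-with,
in-complex-with); bits 3–5 the forward-directed labels
(catalysis-precedes, controls-expression-of, controls-state-change-of);
bits 6–8 the same labels oriented backwards, rendered as
catalysis-succeeds, expression-controlled-by and state-changed-by. The
code is rendered as an 8-character 0/1 string with bit 1 leftmost. The two
endpoint encodings of one edge are related by swapping the two directed
blocks (`symmetric_code`, an involution); both are stored, so each
adjacency list is self-contained. The reverse labels are synthesized
during encoding only — input files carrying them are rejected rather than
guessed at.

Two of the seven input relation types, controls-phosphorylation-of and
controls-transport-of, are parsed but excluded from the integrated
network: pairs carrying them are in practice annotated with the broader
state-change relation as well, so keeping them would double-count the
same biochemical fact at low abundance. No remapping option is offered.
Rows whose endpoints look like chemical-compound identifiers (prefix list,
default `CHEBI:`) are skipped; only protein–protein relations enter the
graph.

## Canonical graphlet keys

A 2-node graphlet is identified by its edge code; its canonical key is the
lexicographic minimum of the code and its symmetric re-encoding. A 3-node
graphlet on (a, b, c) is the 24-character concatenation
`e(a,b)‖e(b,c)‖e(c,a)`, with eight zeros standing for an absent closing
edge; its canonical key is the lexicographic minimum over the six node
orderings, re-orienting pairwise codes as needed. Lexicographic
minimality is our tie-break — any stable representative would do — and it
is part of the on-disk format contract: keys in TSV outputs are these
minimal strings, bit 1 leftmost. Over the full alphabet there are 143
distinct 2-node classes ((256 + 32)/2 − 1 by the orbit-counting
arithmetic); the number of classes *observed* in any given network is
data-dependent and always reported per network, never assumed.

## Counting

Enumeration walks every ordered path (a, b, c) centered at b through the
adjacency lists, so the work grows as Σ_b deg(b)², linear in nodes for
bounded degree. Each path contributes its canonical 24-bit key to a hash
tally; an instance is enumerated 6 times if it is a triangle and 2 times
if it is an open path, and tallies are divided by exactly this
multiplicity to give instance counts (the division is asserted exact). A
`raw_tallies` mode preserves the undivided tallies; z-scores are
unaffected by the choice because real and randomized networks are
normalized identically, but instance counts are the interpretable
default. Only the most specific multi-label occurrence is counted: a
pair's full consolidated code enters the key, so label subsets never
contribute to more generic graphlets. A per-network report threshold
(default: a graphlet must occur at least 10 times) is applied at report
time; all null-model counting runs unthresholded.

## Null model and z-scores

Randomized networks preserve the multi-label degree structure: two edges
with the *identical* code, a→b and c→d, are rewired to a→d and c→b,
keeping the code, only when the four proteins are distinct and neither new
pair is already connected. The first condition prevents self-edges; the
second is required for exact conservation — merging labels onto an
existing pair would change two codes and break the per-node typed degree
vectors. Under these rules the node set, the code multiset, and every
node's per-code adjacency profile are invariant (asserted by audit in the
tests). The swap budget defaults to 10 × (connected pairs) successful
swaps with an attempt cap of 100 × the budget; falling short produces a
warning with the achieved count, never a silent partial result.

z_g = (c_g − μ_g)/σ_g per canonical key, where μ_g and σ_g are the mean
and sample (n−1) standard deviation of the key's count over the ensemble,
counting absence as zero. When σ_g = 0 the score degenerates: +∞ if the
real count exceeds μ_g (the graphlet never appears in the ensemble), −∞
below, 0 at equality. Sentinel keys are excluded from signature matrices
and surfaced separately in differential reports. Two ensemble designs are
provided: the default builds N = 20 independent shuffles per network; a
pooled mode takes one shuffle of each network and pools their counts into
a single null shared by all networks. Per-network nulls are statistically
cleaner (each network is compared against its own degree structure); the
pooled mode reproduces the alternative design exactly and is a flag away.
A per-key Shapiro–Wilk normality check of the ensemble counts is available
as a diagnostic; it never gates the z-score computation.

A consequence worth knowing when interpreting z-scores: because swaps
preserve each node's per-code degrees, every ordered 2-path tally
Σ_b deg_x(b)·deg_y(b) is *invariant* under the null. Open-path graphlet
counts therefore fluctuate only through triangle closure, and the
significant signal in this null model comes almost entirely from closure
patterns — which triangles exist and with which closing codes. The
planted-motif benchmark in the test suite is built on exactly this
observation: it plants triangles (two interacts-with edges closed by a
catalysis edge) into a background where that closure also arises by
chance, so the planted key has a finite, strongly outlying z-score rather
than an uninformative ∞ sentinel.

## Condition-specific networks

A gene is active in a condition when its aggregated expression over the
condition's replicate samples is strictly greater than the noise threshold
r (default 10.0, the scale of RMA-normalized microarray values).
Aggregation is the mean by default, configurable to median or min; the
choice only matters for genes whose replicates straddle r. The
condition-specific network is the induced subgraph on the active genes:
node kept iff active, edge kept iff both endpoints kept, codes unchanged.
Requested genes absent from the network are counted and logged, not
errors. Expression input is gene-level (gene × sample TSV plus a
two-column sample → condition map); probe-level array handling and
probe-to-gene mapping are deliberately out of scope.

## Synthetic data

`SynthSpec` drives three seeded generators. The network generator assigns
each unordered pair at most one code, drawn from per-code probabilities
(or expected counts divided by the number of pairs); the default
composition skews heavily toward undirected physical interaction with a
handful of directed and mixed codes at intermediate rates and one rare
reciprocal-catalysis code, mimicking the label-frequency skew of curated
integrated networks. Directed codes are stored in a random orientation.
The planting generator places instances of a canonical 3-node key on
node-disjoint triples that are unconnected in the background, so planted
counts are exact up to background collisions (rejected with an error when
too few fresh triples exist — overlapping plants would make expected
counts combinatorial). The expression generator draws active genes in
(r + margin, r + margin + spread) and inactive genes in (low, r − margin)
per replicate, margin 0.5 by default, so the activity truth table is
unambiguous under the strict threshold and recovered exactly.

What the generators do *not* emulate: the heavy-tailed degree
distribution, modular/community structure and label correlations of real
interaction networks, or the continuous unimodal expression distributions
of real arrays. Passing tests therefore demonstrate correctness of the
algorithms and their contracts, not biological performance on real data.

## Numerical and design choices

- Strict inequality for activity ("above r"); ties at r are inactive.
- Sample (n−1) standard deviation in ensemble statistics.
- Signature-matrix columns: finite z everywhere, instance count ≥ the
  report threshold in ≥ 1 network; keys missing from a network's vector
  are filled with 0 and logged; rows and columns sorted lexicographically.
- PCA explained variance via singular values of the centered matrix;
  a zero-variance matrix is defined as fraction 1 with a warning.
- Clustering: 1 − Pearson correlation distance between signature rows,
  average linkage; rows are sorted by label first so the dendrogram is
  independent of input order; zero-variance rows are rejected by name.
- Differential ranking: |z1 − z2| descending with the key as tie-break;
  the z-ratio is reported only when both scores are positive (a ratio
  across zero is misleading); count fold is c1/c2 with ∞ when c2 = 0.
  Keys without a finite score in both networks go to per-network
  exclusive sections.
- All randomness flows from one top-level seed; CLI stages derive their
  generators from (seed, stage index), so stage-by-stage runs and
  `run-all` produce byte-identical outputs.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale: oracle-equivalence checks use 200 random graphs of up to 30
nodes against brute-force all-pairs/all-triples enumeration; canonical-key
soundness uses 10,000 random key triples against a permutation oracle;
null-model conservation uses 150–200-node graphs at the full 10 × pairs
swap budget; planted-motif recovery uses 300-node backgrounds with
20-shuffle ensembles over 5 seeds. These sizes exercise every code path
while keeping the whole suite in the tens of seconds.

## Known limitations

- Graphlets of size ≥ 4, orbit decomposition within graphlets, and
  sampling-based approximate counting are out of scope.
- The 8-bit label layout is fixed; arbitrary label alphabets are not
  supported.
- Functional-enrichment analysis of inducing-protein sets is not
  performed; the differential stage emits plain gene lists suitable as
  input to external enrichment tools.
- The edge-shuffling null preserves typed degree vectors but not
  higher-order structure; as noted above, open-path counts are nearly
  deterministic under it, so significance statements concern closure
  structure.
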