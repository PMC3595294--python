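# Methods

This note documents the models and procedures implemented in `meshsom`, the
parameters that matter, the synthetic data the tests run on, and the
numerical and design choices made where more than one reasonable option
existed.

## Corpus representation

Documents are sets of controlled-vocabulary terms with binary occurrence;
each is stored as a sorted array of vocabulary indices. The vocabulary
order is canonical everywhere: descending document frequency, ties broken
lexicographically. This has two consequences used throughout: keeping the
N most frequent terms is a prefix cut, and every dominance tie-break
("prefer the more common term, then alphabetical") is simply the ascending
vocabulary index, so a stable sort suffices. Documents emptied by a
vocabulary cut are dropped and counted. Tokenization is out of scope —
terms are taken verbatim as strings, as produced by an indexer.

An optional minimum-document-frequency pre-filter (default off) emulates
upstream rare-term removal; it composes with the top-N cut by filtering the
prefix it would otherwise keep.

## Batch SOM trainer

**Lattice.** Odd-r horizontal-offset hexagonal lattice, pointy-top cells,
unit spacing, 0-based row-major linear indexing. One convention is fixed
and shared by the training kernel, the clustering adjacency, and the
rendering geometry, so the three subsystems cannot disagree. Grid distance
is the Euclidean distance between hex centers (the SOM-PAK convention),
not a hex-step count; all six neighbors of a neuron are exactly distance 1.

**Initialization.** Every weight is drawn 0 or 1 with probability ½
(seeded). With realistic vocabulary sizes an all-zero row has vanishing
probability, but the degenerate case is handled downstream anyway.

**BMU search.** Cosine similarity between a binary document and each
reference vector, computed through the sparse identity
sim(i) = (Σ_{k∈doc} w_ik)/(√|doc|·‖w_i‖). Zero-norm neurons score 0. Ties
break to the lowest linear index — deterministic and independent of the
partitioning.

**Kernel table.** h(d) = exp(−d²/2σ²) is tabulated once per batch over
distances quantized at 0.01 lattice units, with values below 1e−9 treated
as exactly zero. The quantization step bounds the table (a 275-wide map
needs ~43k entries) and the floor truncates the effective kernel radius,
making accumulation cost proportional to the neighborhood size at small σ.
The table is sized with headroom so that any rounded distance up to the
lattice diameter stays in range.

**Sigma schedule.** σ decays linearly *across batches* from `sigma_start`
(default max(rows, cols), i.e. roughly the size of the map) to `sigma_end`
(default 1.0, in grid-distance units). An alternative reading — restarting
the decay inside every batch — is implemented behind
`sigma_within_batch=True` for comparison; under it each batch's partitions
step σ down from start to end. The across-batch decay is the default
because a neighborhood that never stays small can never sharpen the map:
the per-batch restart repeatedly re-smooths fine structure.

**Batch update.** Neurons with positive denominator are set to the
kernel-weighted mean of their accumulated documents; the ratio is clipped
to [0, 1] to remove floating-point summation-order epsilon (the exact value
is a convex combination of binary inputs, so the clip can only touch the
last ulp). Neurons never reached by any kernel (possible only at very small
σ) keep their previous weights — the only choice that preserves the [0, 1]
invariant and avoids NaNs.

**Data partitioning.** Each batch presents a rotating contiguous window of
`steps_per_batch` documents, wrapping around the corpus so the full corpus
is cycled every ⌈n_docs/steps⌉ batches. The window is split into P
contiguous chunks, one per partition; partition accumulators are summed in
partition index order before the update. Because accumulation is additive,
the P-way result equals the serial result up to floating-point summation
order (observed ~1e−15 relative; the contract is 1e−7). No distributed
runtime is included — the artifact guarantees the merge contract, not a
scheduler. Internally, accumulation is vectorized by grouping a partition's
documents by BMU and spreading the per-BMU binary sums through the kernel
with one matrix product; this is algebraically identical to per-document
accumulation.

**Diagnostics.** The per-batch log records σ, steps, mean BMU similarity,
and quantization error (mean 1 − cosine(doc, BMU)). On the synthetic
corpora the quantization error falls steeply early and flattens; the test
suite asserts non-increase over the last quartile of batches with 0.01
slack (the sequence is stochastic at the batch level).

## Term dominance and ranking

Dominance is the row-normalized weight, d_ik = w_ik / Σ_k w_ik; each
neuron's ranking is the stable descending sort of its dominance row, so
ties resolve toward the more frequent (then lexicographically earlier)
term. Rankings are materialized to rank 10 by default — deep enough for
drill-down tables and transects. All-zero neurons are flagged degenerate,
ranked as −1, and excluded from clustering.

## Patch clustering

Patches at rank r are the connected components of the graph joining
lattice-adjacent neurons that share the same rank-r term, computed with
sparse connected components over the same adjacency the trainer uses.
Patch ids order by lowest member neuron index. Levels are clustered
independently; lower-rank solutions are *not* refinements of higher ones.
Patch geometry is the shapely union of member hexagon cells; cell vertices
are snapped to 1e−9 so shared edges have exactly identical coordinates and
the union is numerically clean (patch area is member count × cell area to
~1e−9 relative). Holes appear where foreign neurons are enclosed.

## Label placement

The placement engine is a deliberately simple greedy algorithm with a
documented anchor-fallback scheme; its fidelity target is the accounting
structure (placed/unplaced per level) and the strict top-down hierarchy,
not the output of any particular commercial placement engine. Levels are
processed in rank order, and within a level patches in descending neuron
count. A label anchors at its patch's pole of inaccessibility; if the text
box fails any constraint — fully inside the frame, intersecting its own
patch, disjoint from every already-placed box — eight fallback anchors on a
compass ring (radius ¼ of the patch bounding-box extent) are tried before
the label is marked unplaced. Placed boxes accumulate as exclusion masks,
so a level's solution is invariant to everything below it.

Text metrics use a fixed-width glyph model (advance 0.6 × font size per
character), making collision geometry font-independent and reproducible;
curved, shape-following baselines are a rendering flag only, with
collisions always on the straight box. Font size grows with the log of the
patch's neuron count, saturating at 1,000 neurons, within per-level bands
(level 1: 0.5–2.0 lattice units; level 2: 0.4–1.4; level 3: 0.3–1.0;
deeper: 0.25–0.8). The bands are sized so a saturated level-1 label of ~10
characters spans about 12 hex cells — comparable to the extent of patches
that reach such sizes, and well inside any map large enough to contain
them. Percentages in the accounting table round half-up to one decimal.

## Synthetic corpus generator

The generator provides corpora with known latent structure, emulating the
statistical features the pipeline depends on:

* **Document length**: shifted negative binomial, L = min + NB(n, p), with
  (n, p) moment-matched to the target mean (default 7.06) and SD (default
  3.67). The family is chosen because the emulated corpus statistics show
  mean > median, a large SD, a hard floor of one term, and a heavy mass of
  one- and two-term documents; moment matching requires variance > mean
  above the floor, and infeasible parameterizations raise. The realized
  mean tracks the target to sampling error (SE ≈ 0.012 at n = 100,000);
  the realized median sits at 6–7.
* **Topics**: one hard topic per document, drawn uniformly; each topic owns
  a contiguous block of topic-exclusive terms drawn uniformly within the
  block, with `topic_vocab_overlap` leakage into the two neighboring
  blocks. Hard membership keeps topology-preservation tests unambiguous.
* **Methodological stratum**: a small set of cross-topic terms (default 4%
  of the vocabulary) drawn with Zipf(1.0) weights at per-slot probability
  `methodological_fraction` (default 0.05). At the defaults the busiest
  procedural term lands in ~10% of documents — a few times the rate of the
  busiest topic term, mirroring the frequency profile of real procedural
  headings — so procedural terms top the frequency table and dominate
  boundary and mixed neurons without swamping topical regions. At slot
  probabilities ≥ 0.2 the stratum overwhelms the corpus: every
  methodological term becomes more frequent than any topic-exclusive term
  (property-tested).

What the generator does **not** model: indexer behavior, hierarchical
vocabulary structure, topic admixture within a document, term burstiness,
or corpus growth over time. Passing tests therefore demonstrate that the
pipeline recovers planted co-occurrence topology from sparse binary data at
realistic sparsity — not that it resolves any particular real literature.

## Map-reading analytics

Transect paths are BFS shortest paths on the hex adjacency graph through
the requested waypoints (neighbors explored in ascending index, so paths
are deterministic); any adjacent-step path is admissible for the analysis,
which reads per-rank dominance profiles and per-term ordinal rank series
directly from the dominance matrix. Document overlays reuse the training
BMU rule unchanged (same cosine, same tie-break), so base-map placement is
consistent with training assignment.

## Problem sizes and determinism

The test suite trains small maps chosen to exercise every code path at
interactive speed: a shared 15×15 map over 1,500 three-topic documents
(30 batches), a 30×30 / 3,000-document / 30-batch benchmark for partition
invariance and topology preservation, a 20×20 ten-topic run for the
patch-discontiguity phenomenon, and ten 12×12 runs for placement
accounting. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give identical corpora,
models, and output files, and SVG output is byte-for-byte reproducible.

## Known limitations

* The trainer is single-process; the data-partitioned structure matches a
  distributed deployment but none is provided.
* Greedy placement is order-dependent by design and can leave labels
  unplaced that a global optimizer would fit.
* Patch polygons are exact unions of hex cells; no boundary smoothing or
  generalization is applied.
* The generator's topic blocks are disjoint except for explicit leakage;
  real vocabularies have overlapping, hierarchical term usage.
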