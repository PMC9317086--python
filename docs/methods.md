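# Methods

This note records the model, the conventions the implementation commits
to, the defaults and why, and what the synthetic benchmark does and does
not demonstrate.

## Model and assumptions

The method assumes (i) protein complexes are dense subgraphs of the PPI
network, (ii) complex members tend to share specific GO terms, and
(iii) known complexes are informative about unknown ones — both through
explicit subgraph features (stage 1) and through the geometry of a
random-walk node embedding (stage 2). All graphs are undirected and
simple; self-loops and duplicate interactions are removed at read time.

### Edge confidence

Each existing edge (no link prediction) is scored
`weight = sqrt(sim + HOCN)`:

* `HOCN = (JCS + CNS + |CN|)/(|CN| + 1)` with
  `CNS = Σ_w JCS(v,w)·JCS(w,u)` over common neighbors `w`. HOCN is
  bounded by 2 and is 0 for an isolated edge.
* `sim = |C| · log(min_i |S_i| / Smax)²` over the shared-term set `C`.
  The log base is a pure scale factor on `sim`; **base 10** is the
  default (configurable). An empty shared set short-circuits to 0
  rather than evaluating the log. Only direct annotations are counted;
  no propagation up the ontology graph is applied.
* Edges with weight ≤ `min_weight` are removed. The default
  `min_weight = 0` removes exactly the zero-confidence edges (no shared
  neighborhood and no shared terms); on sparse noisy networks this
  already deletes most background edges while never touching an edge
  inside a coherent module.

### The 16 subgraph features

5 unweighted (density, max/mean/median degree, variance of the
unweighted clustering coefficient), 9 weighted (density, max/mean/median
weighted degree, edge-weight mean and variance, modularity, mean and max
weighted clustering coefficient) and 2 degree-related (mean and variance
of per-node average neighbor degree). Conventions, chosen once and
frozen:

* weighted density sums ordered pairs, so a unit-weight clique scores
  exactly 1; modularity's internal sum counts each edge once (otherwise
  internal weight double-counts against the boundary);
* the weighted clustering sum ranges over *adjacent* neighbor pairs
  (triangle-closing pairs), each unordered pair once;
* variances are population variances; medians are midpoint-of-two for
  even counts; all degenerate cases (singletons, zero degree, no
  internal edges) map to 0, never NaN;
* every statistic is computed on the induced subgraph except
  modularity, which by definition sees boundary edges of the host
  weighted network;
* average neighbor degree uses unweighted degrees by default
  (`weighted_annd` switches to weighted).

### Stage 1 (SVCC)

The subgraph scorer is an SVC with C = 3, polynomial kernel of degree 4,
`gamma='scale'`, `coef0 = 0`, `tol = 1e-3` and Platt probability
calibration, behind a feature standardiser. The standardiser is a
deliberate addition: the degree-4 homogeneous polynomial kernel on raw
features is dominated by vector magnitude, so a perfect triangle (small
norm) would land near the origin and inherit the majority bias;
z-scoring the 16 features restores the geometry the kernel is meant to
see without touching any hyperparameter.

Negative training examples are uniform random node sets, one per
positive and size-matched, redrawn if identical to any positive.

Candidate detection: maximal cliques (Bron–Kerbosch via networkx) with
≥ 3 nodes on the confidence-filtered network, then

* **selection** — ranked scan by descending probability; a seed sharing
  strictly more than α = 2 proteins with a kept seed is dropped
  ("exceeds" is strict: sharing exactly 2 survives);
* **expansion** — external neighbors adjacent to ≥ 1 member are tried
  one at a time; the largest *strict* probability increase is taken,
  ties broken lexicographically by node id; stops at the first
  non-improving round;
* **filtration** — ranked scan with β = 0.8 on the overlap ratio
  |∩|/|∪|: overlap ≥ β merges (union, rescored, pushed back into the
  ranked pool — merging therefore cascades through the re-ranked scan,
  one pair at a time), 0 < overlap < β removes the lower-ranked
  candidate, and disjoint candidates are untouched. Applying the
  removal rule to zero-overlap pairs would annihilate every disjoint
  candidate, so the rule is deliberately restricted to overlapping
  pairs.

Probability ties anywhere are broken by (larger size, lexicographic
member tuple), making every scan a total order and the stage
deterministic.

### Stage 2 (embedding + random forest)

Second-order biased walks: transition weight 1/p back to the previous
node, 1 to common neighbors of the previous and current node, 1/q
otherwise (p = 8, q = 1, 10 walks of length 80 per node). Walks run on
the **confidence-filtered network's topology**. The raw graph was tried
first and rejected: walks leak through noise edges, the embedding mixes
modules, and the stage-2 classifier's held-out probabilities sit near
chance. On the filtered graph walks stay inside functional modules and
held-out complexes separate cleanly. `use_weights` optionally biases
sampling by edge weight (off by default).

The skip-gram model (64 dimensions, window 10, 5 epochs, 5 negative
samples, unigram^0.75 negative table, linearly decaying learning rate
0.025 → 1e-4) is implemented in-package with a numba-compiled update
loop and is bit-reproducible under a fixed seed (single stream,
xorshift64* negative draws).

A complex's vector is the coordinate-wise mean of member vectors. The
classifier is a 1000-tree random forest; candidates with positive-class
probability > 0.5 (configurable) survive. The embedding is trained once
per network and shared across CV folds — it uses no complex labels, so
sharing it is leak-free and saves a factor of `folds` in compute.

### Evaluation and cross-validation

Matching is neighborhood affinity NA > 0.25 (strict). Precision =
N_cp/|P|, recall = N_cb/|B|, F = harmonic mean. Enrichment p-values are
exact hypergeometric upper tails computed with integer binomials
(mathematically 1 − CDF(k−1), but immune to the floating-point
cancellation of that form); k = 0 returns 1 by convention; the universe
defaults to the network's node count; p-values are reported raw per
complex (optional Bonferroni flag, off by default).

Five-fold protocol: seeded uniform shuffle into folds; per fold, both
stages are trained on the other four folds (+ fresh seeded negatives),
prediction runs on the whole network, and predictions overlapping any
*training* complex at ratio ≥ 0.9 are discarded as rediscoveries (the
≥ here, versus the strict > 0.6 of the final deduplication, follows the
protocol's wording). The five survivor sets are pooled and deduplicated
by a ranked scan keeping the higher stage-2 probability. The final set
is scored against the full reference catalog.

## Synthetic benchmark

`SynthConfig` defaults: 300 nodes, background edge probability 0.01, 20
disjoint planted complexes of 3–8 members wired at p_in = 0.9, 50 GO
terms, 90 % of complexes receive a dedicated coherent term, 5 %
per-protein annotation noise, aspects cycled P/F/C. These sizes keep a
full five-fold pipeline run around 15 s on one core while leaving the
detection problem non-trivial (background triangles exist, size-3
planted complexes are frequently missing an edge).

What the generator emulates: sparse interactome, dense complexes,
term-coherent annotation, annotation noise. What it does **not**
emulate: scale-free degree structure, overlapping complexes, false
*negative* interactions within complexes beyond 1 − p_in, aspect- and
depth-structured GO vocabularies, or evidence-code heterogeneity.
Passing the planted-recovery tests therefore shows the machinery is
correct and self-consistent, not that real-interactome F-scores carry
over.

## Numerical and degenerate-input choices

* All randomness fans out from one global seed through SHA-256-salted
  stage names (`fanout_seed`), so stages are independently reproducible
  and reordering one stage never perturbs another.
* SVC Platt calibration and the forest receive explicit seeds;
  single-worker training is the default for determinism.
* Empty networks, empty candidate sets, singleton subgraphs,
  unannotated proteins and missing GAF files all degrade to defined
  values (empty outputs, zero features, sim = 0) rather than errors;
  genuinely contradictory inputs (negative weights, single-class
  training sets, empty reference sets) raise validation errors.
* Walk dead ends truncate the walk (only isolated nodes, in an
  undirected graph); isolated nodes keep their random initial vectors.

## Known limitations

* Clique seeding misses planted complexes that lost enough internal
  edges to have no 3-clique; these bound recall on sparse complexes.
* The stage-2 forest can only confirm or veto stage-1 candidates; it
  never proposes new complexes, so two-stage recall is at most SVCC
  recall.
* GAF parsing accepts any evidence code by default and reads direct
  annotations only; ontology-aware propagation would change `sim` and
  the enrichment universe.
* With very small training catalogs the Platt-calibrated probabilities
  are coarse; rankings are more trustworthy than absolute values.
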