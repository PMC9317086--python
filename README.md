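# complexwise

Supervised prediction of protein complexes from protein–protein
interaction (PPI) networks.

Protein complexes — groups of proteins that assemble and act together —
appear in interaction networks as dense subgraphs, but raw
high-throughput PPI data is noisy enough that purely topological
clustering struggles. `complexwise` implements a two-stage supervised
method that exploits both Gene Ontology (GO) knowledge and known complex
catalogs:

1. **Edge weighting.** Every interaction `(v, u)` gets a confidence
   weight combining a high-order common-neighbor similarity

   `HOCN(v,u) = (JCS(v,u) + CNS(v,u) + |CN(v,u)|) / (|CN(v,u)| + 1)`

   (a Jaccard coefficient `JCS` augmented with the connectivity `CNS` of
   the shared neighborhood `CN`) with a GO-annotation similarity

   `sim(v,u) = |C(v,u)| · log₁₀(min|Sᵢ(v,u)| / Smax)²`

   where `C(v,u)` are the terms annotating both proteins, `Sᵢ` each
   shared term's annotated-protein set and `Smax` the largest such set.
   The edge weight is `√(sim + HOCN)`; zero-confidence edges are dropped.
2. **Stage 1 (SVCC).** A probability-calibrated SVM (polynomial kernel)
   is trained on 16 topological features of known complexes versus
   size-matched random node sets, then maximal cliques (≥ 3 nodes) are
   selected (overlap count > α = 2 pruned), greedily expanded by the
   neighbor giving the largest probability increase, and
   overlap-filtered (overlap ratio ≥ β = 0.8 merged, smaller nonzero
   overlaps removed).
3. **Stage 2.** Node vectors are learned by biased random walks
   (return bias p = 8, in-out q = 1) plus skip-gram with negative
   sampling; a complex's vector is the mean of its member vectors, and a
   1000-tree random forest classifies the stage-1 candidates. Candidates
   with positive probability > 0.5 are the final predictions.

Evaluation matches predicted against reference complexes by
neighborhood affinity `NA(b,p) = |V_b ∩ V_p|² / (|V_b|·|V_p|) > 0.25`,
reports precision = N_cp/|P|, recall = N_cb/|B| and their harmonic mean
(F-score), scores biological coherence with an exact hypergeometric GO
enrichment test, and runs the whole protocol under five-fold
cross-validation with overlap pruning (0.9 against the training folds,
0.6 for final deduplication).

A synthetic benchmark generator (sparse Erdős–Rényi background with
planted dense complexes and term-coherent GO annotations) lets the whole
pipeline run and be validated without downloading any database.

## Worked example

Generate a benchmark, weight the network, and run the cross-validated
pipeline:

```sh
complexwise simulate --seed 7 --out fixtures/
complexwise weight --network fixtures/edges.tsv --gaf fixtures/ann.gaf -o weighted.tsv
# -> 300 nodes, 321 weighted edges
head -3 weighted.tsv   # u <TAB> v <TAB> sqrt(sim + HOCN)
# P0000  P0041  1.064654
# P0000  P0063  1.058113
# P0000  P0066  1.044980
complexwise cv --network fixtures/edges.tsv --gaf fixtures/ann.gaf \
    --reference fixtures/truth.txt --seed 7 -o final.txt
# n_predicted  n_reference  ncp  ncb  precision  recall  fscore
# 21           20           18   17   0.8571     0.8500  0.8536
head -2 final.txt      # members <TAB> stage-2 probability
# P0034 P0054 P0079 P0183 P0246         0.9450
# P0001 P0125 P0139 P0172 P0194 P0224   0.9020
```

Of the 20 planted complexes, 17 are recovered at NA > 0.25 (recall
0.85); 18 of the 21 predictions match a true complex (precision 0.857),
giving F = 0.854. The same workflow is available as library calls
(`complexwise.weighting.weight_network`,
`complexwise.evaluation.cross_validate`, …) with identical results, and
`complexwise pipeline` runs everything end to end with a manifest.

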