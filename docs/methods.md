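# Methods

## Model

The predictor treats miRNA–disease association as link ranking on a
bi-level network: a miRNA similarity layer and a disease similarity
layer, coupled by the bipartite graph of known links `A ∈ {0,1}^{n_m×n_d}`.
Its core assumption is the guilt-by-association premise of the field:
functionally similar miRNAs tend to associate with semantically similar
diseases. The score of a pair is built from two directional components,
each combining

1. an *information property* `S ∈ [0,1]` — the ratio of
   threshold-filtered to unfiltered similarity mass connecting the
   source entity to the target's known partners,
   `S(g,h) = Σ_k H(g,k)A(k,h) / Σ_k F(g,k)A(k,h)` with
   `H = F·1[F ≥ T]`, and
2. an *association-type weight* `W ∈ {0} ∪ (1,e]` — `e` for known
   links, `exp(F(g,s))` when the source's most similar neighbour `s` is
   linked to the target, `0` otherwise.

The directional affinity is the elementwise product `S∘W`; the final
score averages the two directions, so `Sf ∈ [0,e]` and `Sf = 0` exactly
when neither direction finds supporting evidence. The score is a
relative ranking quantity, not a calibrated probability — known pairs
always carry the maximal weight `e`.

## Similarity inputs

**miRNA functional similarity** is taken as given (precomputed scores
such as the published MISIM matrix); the package validates it
(symmetry to 1e-8, range [0,1]) but does not re-derive it.

**Disease semantic similarity** is computed from per-disease ancestor
DAGs. The decay frame assigns the disease's own descriptor contribution
1 and each ancestor `Δ` times the best contribution among its children
inside that disease's DAG (not the global descriptor graph), giving
`Δ^depth` on chains. The information-content frame assigns
`-log(N_l/N)`; the logarithm base cancels between the numerator and
denominator of the similarity, so the choice of natural log only
affects reported contribution values. A denominator of exactly 0 (all
descriptors ubiquitous) yields similarity 0 by convention. The matrix
diagonal is reported as 1 even in that degenerate case. `N` defaults to
the number of DAGs in the corpus but is caller-configurable
(`DagCorpus.corpus_size`) for frequencies drawn from a larger
vocabulary.

**GIP kernel.** `K(x,y) = exp(-β‖IP(x)−IP(y)‖²)` with
`β = β*/(mean ‖IP‖²)`, `β* = 1`. Profiles are rows/columns of the
*current* association matrix, so cross-validation folds get bandwidths
and profiles free of their held-out links. All-zero profiles (isolated
nodes) are allowed; an entirely empty association matrix raises a
degenerate-bandwidth error. Squared distances are computed via the
Gram-matrix identity, clipped at 0, symmetrised, and the diagonal set
to exactly 1.

**Integration** selects, cell-wise, the primary similarity where it is
*available* and the kernel elsewhere. Availability is per-pair; by
default a pair is available iff both entities are present in the
primary matrix and the stored value is strictly positive (public
releases encode "unknown" as 0). Callers may override with an explicit
symmetric 0/1 mask. Per-entity availability is expressible through the
mask.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `T` | weak-similarity threshold in the information property | 0.02 | the value at which cross-validated AUC peaks on the reference corpus; swept by `t_sweep` |
| `Δ` (`delta`) | per-edge semantic contribution decay | 0.5 | standard literature value |
| `β*` (`beta_star_m/d`) | original GIP bandwidth | 1.0 | rescaled by mean squared profile norm |
| `k`, `repeats`, `seed` | cross-validation controls | 5, 1, 0 | repeats is first-class so the 100×-repeated five-fold protocol is one flag |

## Numerical and procedural choices

* 0/0 in the information property (target with no known partners) is
  defined as 0: no evidence contributes no affinity.
* The sums over `k` include `k = g`; the self term only enters for
  already-known pairs, so the ranking of candidate (unknown) pairs is
  unaffected.
* The nearest neighbour excludes self (self-similarity 1 would make the
  potential branch unsatisfiable) and is taken over the *unthresholded*
  integrated similarity; ties break to the smallest index.
* Matrix orientation is miRNA-rows × disease-columns everywhere; the
  disease→miRNA direction works on the explicit transpose and its
  affinity is transposed back before averaging.
* Similarity matrices are dense: at the scale this method targets
  (hundreds × hundreds) sparsity buys nothing and dense keeps the
  formulas literal.
* Identifiers are matched exactly after case-folding and whitespace
  trimming; ids missing from a similarity input are warned about and
  fall back to the kernel.

## Evaluation protocol

Cross-validation masks the held-out known links, *recomputes kernels
and integration on the masked matrix* (semantic/functional inputs are
fixed — they do not derive from `A`), reruns the pipeline, and ranks
held-out scores against the negative pool (all zero cells of the full
matrix) under the same fold's model. AUC is rank-based (ties ½),
identical to trapezoidal ROC integration, and the reported CV AUC is
the mean per-fold AUC; for leave-one-out this is the mean
per-left-out-pair AUC. `CvResult` carries fold assignments and
held-out scores for exact replay. A fast mode
(`refit_similarity=False` / `--fast-loocv`) reuses the full-data
similarities across folds; it leaks held-out links through the kernel
profiles and is provided only as a labelled approximation.

The permutation null (`shuffled_label_auc`) scores the full data once
and ranks random pseudo-positive cell sets; its mean AUC concentrates
at 0.5 for any scorer and is used to calibrate the ranking statistic.

Top-k case-study ranking excludes an entity's known partners and breaks
score ties by identifier.

## Synthetic data

The generator plants aligned miRNA/disease blocks: links are Bernoulli
(0.6 within matched blocks, 0.02 elsewhere), functional similarity is
0.8 within / 0.1 between blocks plus symmetric clipped Gaussian noise
(σ = 0.05, diagonal pinned to 1), 20% of off-diagonal similarity pairs
are withheld to exercise the kernel fallback, and the DAG corpus gives
same-block diseases a depth-3 shared ancestor chain
(root → block → disease) — deep enough for both semantic frames to
separate blocks, shallow enough to hand-verify. Defaults (30 miRNAs,
20 diseases, 3 blocks) keep a full leave-one-out run under a second
while leaving ~120 known links, enough for stable AUC estimates.
Setting `within_sim == between_sim` and `density == background_density`
produces a signal-free null on which leave-one-out AUC is ≈ 0.5.

What the generator does **not** emulate: the heavy-tailed degree
distribution of curated association databases, correlated noise in
similarity estimates, descriptor synonymy, or multi-rooted real MeSH
DAGs. Passing tests therefore demonstrate correctness of the
computation and sane behaviour under planted structure, not
performance on curated human data; reproducing published AUC levels
requires the original association/similarity inputs, which the file
readers accept but the package does not download.

## Known limitations

* Entities with no known links and no primary similarity are scored
  purely through kernel fallback against empty profiles, which carries
  little information.
* Leave-one-out with per-fold similarity refitting is O(#links) full
  pipeline runs; at database scale (thousands of links) use five-fold
  CV or the labelled fast mode.
* Scores are not probabilities; compare them only within one run.
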