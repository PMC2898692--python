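# Methods

## The model

`dlphylo` infers phylogenies from whole genomes or whole gene/protein sets
without aligning anything.  Each taxon is summarized by the counts of all
N = |Σ|^K words of length K (Σ = {A,C,G,T} or the 20 amino acids), and the
part of those counts that is explained by shorter-word composition is
removed before taxa are compared.

For one taxon, with counts pooled over its m sequences,

    p(w) = Σ_j n_j(w) / Σ_j (L_j − K + 1)

is the observed frequency of K-mer w.  The background model treats a K-mer
s₁…s_K as producible in two ways — appending s_K to the (K−1)-mer s₁…s_{K−1},
or prepending s₁ to s₂…s_K — and averages the two estimates:

    q(s₁…s_K) = [ p(s₁…s_{K−1})·p(s_K) + p(s₁)·p(s₂…s_K) ] / 2

The component used for comparison is the relative deviation

    X(w) = p(w)/q(w) − 1,      X(w) := 0 where q(w) = 0.

Two identities hold by construction and are enforced in the tests:
Σp = Σq = 1 over their supports, and Σ_w q(w)·X(w) = 0 — the background
subtraction is mass-conserving.  X ≥ −1 everywhere, with X = −1 exactly for
words that are expected (q > 0) but never observed.

Taxa are compared over the full N-dimensional X vectors:

* **correlation distance** D = (1 − C)/2, C the centered Pearson sample
  correlation of the two vectors (an uncentered-cosine variant is available
  via `correlation_distance(..., centered=False)`);
* **chord distance** ‖x/‖x‖ − y/‖y‖‖ = √(2 − 2 cos θ), a proper metric.

Trees are built from the distance matrix with canonical Saitou–Nei
neighbor joining, and branch robustness is assessed by resampling the
k-mer *columns* of the taxa × k-mer X table (see below).

## Numerical and algorithmic choices

* **Sparse full-space algebra.**  Vectors store only the support of q, but
  all means, variances and inner products are taken over all N components:
  the implicit zeros enter through closed-form corrections (−N·mean_x·mean_y
  etc.).  Tests pin the sparse path to a dense numpy oracle at 1e−12.
* **Integer k-mer coding.**  K-mers are base-|Σ| int64 codes; the code *is*
  the alphabetical component index.  This bounds usable word lengths at
  K ≤ 13 (DNA) and K ≤ 8 (protein), which the pipeline enforces; K ≥ 2 is
  required because the background needs (K−1)-mer frequencies.
* **Ambiguity characters.**  Windows containing any non-canonical character
  (N, X, B, Z, gaps, stop marks) are excluded from both the counts and the
  window denominator, preserving Σp = 1.  Input case is normalized.
* **Short sequences.**  A gene shorter than K contributes zero windows
  rather than raising; a record is rejected only when *no* sequence reaches
  length K.
* **Frequencies at each word length use their own window denominators**
  (L − K + 1, L − K + 2, L), i.e. the definition is applied independently at
  lengths K, K−1 and 1.
* **Neighbor joining.**  Q-criterion; ties broken toward the earliest
  created pair (deterministic); negative branch estimates are clamped to
  zero with the deficit moved to the sister branch so the path length
  through the join is preserved; the final three nodes are solved in closed
  form.  Consistency on additive matrices (exact topology, branch lengths
  to 1e−9) is tested on 100 random trees, and the implementation is
  cross-checked against an independent NJ (R `ape`) during development.
* **Distance matrices** are computed pair-by-pair with the sparse functions;
  the bootstrap uses an algebraically identical vectorized table path,
  tested to agree at 1e−10.

## Modified bootstrap

The resampling unit is a k-mer column of the taxa × k-mer table of X
values, drawn N times with replacement from the *full* column space.  The
draw is collapsed exactly: the number of draws landing in the all-zero
complement (columns no taxon stores) is Binomial(N, 1 − u/N) with u the
union support size, the rest are multinomial over the u observed columns.
Replicate distances weight each column by its multiplicity; all-zero draws
enter only through the fixed total weight N.  Supports are the percentage
of replicate NJ trees containing each internal bipartition of the
reference (unresampled) tree; a majority-rule consensus over the replicate
trees is also available.  Resampling X columns — rather than raw
frequencies — is deliberate: q cannot be coherently recomputed from
resampled K-mer columns because the (K−1)-mer counts are untouched, while
a resampled X table is still a valid vector set in the same space.  A
historical draw-once variant (`distinct=True`) that keeps redrawn columns
singly is provided behind a flag.

## What the simulator emulates — and what it does not

`simulator` draws a uniform random unrooted binary topology (sequential
random edge attachment), i.i.d. exponential branch lengths (default mean
0.05 substitutions/site), and evolves i.i.d.-uniform root genes under a
symmetric s-state substitution model:
p_sub(t) = (s−1)/s·(1 − exp(−s·t/(s−1))).  Defaults (8 taxa, 10 genes of
2000 aa) mirror a small multi-gene proteome study.  It has no indels, rate
heterogeneity, compositional bias or horizontal transfer, so a green
simulation test establishes statistical correctness of the pipeline under
controlled divergence — not performance on real genomes.

## Known limitations

* Both dissimilarities are **not additive in evolutionary time**: the
  correlation distance saturates near 0.5 well before substitutional
  saturation (measured ≈0.45 at 0.5 substitutions/site of patristic
  separation for K=4 proteomes of this size).  Neighbor joining is only
  guaranteed consistent on near-additive input, so very short internal
  edges adjacent to long terminal branches can be misplaced *even with
  unlimited sequence length*.  Under the default simulation world
  (exponential branch lengths, mean 0.05) this occurs in roughly half of
  random 8-taxon trees; with all branches near 0.05 recovery is essentially
  perfect.  This is a property of the method, not of the implementation:
  the same matrices fed to an independent NJ give identical trees.
* The correlation distance is a pseudo-distance (triangle inequality not
  guaranteed); the chord distance is the metric alternative.
* Bootstrap supports quantify stability against k-mer sampling noise, not
  against model misspecification.
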