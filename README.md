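# dlphylo

Alignment-free phylogeny from k-mer composition vectors, for whole genomes
and whole gene/protein sets — the regime (viral genomes, whole proteomes,
deep divergences) where multiple sequence alignment is unreliable or
impossible.

Each taxon is summarized by the frequencies of all N = |Σ|^K words of
length K.  A background model from the theory of dynamical languages
predicts each K-mer's frequency from shorter words,

    q(s₁…s_K) = [ p(s₁…s_{K−1})·p(s_K) + p(s₁)·p(s₂…s_K) ] / 2,

and the comparison vector is the relative deviation **X = p/q − 1**, which
removes the signal already explained by (K−1)-mer composition.  Taxa are
compared by the correlation distance D = (1 − C)/2 (C = Pearson correlation
of the X vectors over all N components) or by the chord distance between
unit-normalized vectors (a proper metric).  Trees are built with
neighbor joining, and branch robustness is assessed with a modified
bootstrap that resamples the k-mer *columns* of the taxa × k-mer table —
the appropriate resampling unit when there is no alignment and too few
genes to resample.

Everything is importable from `dlphylo`; there is no command-line tool.
The `examples/` scripts are the guided tour.

## Worked example

```python
import dlphylo as dl

record = dl.GenomeRecord("demo", ("MAMA",), dl.PROTEIN)
print(dl.count_kmers(record, 2).counts)   # {'AM': 1, 'MA': 2}
print(dl.dl_vector(record, 2).entries)
# {'AA': -1.0, 'AM': 0.333…, 'MA': 1.666…, 'MM': -1.0}
```

`MA` occurs twice in three windows (p = 2/3) but the letter composition
(half M, half A) predicts only q = 1/4, so X = (2/3)/(1/4) − 1 = 5/3: `MA`
is strongly enriched over the background.  `AA` and `MM` are expected but
absent, hence X = −1.  The weighted deviations always cancel:
Σ q·X = 0.

End to end (`python examples/02_distances_and_tree.py`):

```
PHYLIP distance matrix (correlation distance, K=4):
    6
T2  0.000000  0.226900  0.290143  0.395531  0.415374  0.292807
...
neighbor-joining tree: (T2:0.161…,(T6:0.072…,(T1:0.040…,T5:0.071…):0.161…)…
Robinson-Foulds distance to truth: 2  (0 = identical topology)
chord-distance tree differs from correlation tree by RF = 0
```

Six proteomes are simulated on a random tree, compared at K = 4, and the
NJ tree is checked against the truth.  This particular random tree has an
internal edge of 0.004 substitutions/site, which the (non-additive)
composition distance cannot place — RF = 2 means exactly one bipartition
differs; the correlation and chord trees agree with each other.  See
`docs/methods.md` for why very short internal edges are the method's hard
case.

Bootstrap (`python examples/03_bootstrap_support.py`):

```
reference tree with supports: (C:0.090…,D:0.090…,(A:0.089…,B:0.087…)100:0.231…);
  split ['C', 'D'] | rest: 100.0% of 100 replicates
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a seeded simulated dataset —
FASTA on disk → composition vectors → PHYLIP distance matrix → Newick NJ
tree → 100-replicate modified bootstrap, for both distance methods — and
verifies the artifacts roundtrip before writing the results JSON.

## Layout

- `src/dlphylo/` — `composition` (counts, p, q, X), `distance`
  (correlation/chord, PHYLIP I/O), `njtree` (NJ, Newick, Robinson–Foulds),
  `bootstrap` (column resampling, supports, consensus), `simulator`
  (random trees, sequence evolution), `pipeline` (FASTA collections,
  end-to-end runs with manifests).
- `examples/` — one narrative script per capability.
- `scripts/fetch_accessions.py` — optional, network-dependent download of
  real genome accessions for large-scale runs; not part of the test surface.
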