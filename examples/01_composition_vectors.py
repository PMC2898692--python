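"""From a sequence to its background-subtracted k-mer composition vector.

The tiny peptide "MAMA" is small enough to follow every number by hand:
observed 2-mer frequencies p, expected frequencies q from the
dynamical-language background (built from 1-mer and (K-1)-mer frequencies),
and the final vector X = p/q - 1.  Positive X means a k-mer is enriched
over the background; X = -1 means it was expected but never seen.
"""

import numpy as np

import dlphylo as dl

record = dl.GenomeRecord("demo", ("MAMA",), dl.PROTEIN)

counts = dl.count_kmers(record, 2)
print(f"2-mer counts: {counts.counts}  (valid windows: {counts.valid_windows})")

p2 = dl.frequency_profile(counts)
p1 = dl.frequency_profile(dl.count_kmers(record, 1))
q = dl.expected_profile(p1, p1)
print(f"observed p:  {p2.freqs}")
print(f"expected q:  {q.freqs}")

x = dl.composition_vector(p2, q, "demo")
print(f"X = p/q - 1: {x.entries}")
print(f"component space N = 20^2 = {x.n_total}")

# the background subtraction conserves mass: sum_i q_i X_i = 0
print(f"sum q_i X_i = {np.dot(q.values, x.values):+.2e}  (identically zero)")
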