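"""Turn sequences into k-mer frequency vectors.

A sequence of length m decomposes into m-k+1 overlapping k-mers; counting
them over the 4^k vocabulary (16,384 words at k=7) gives each sequence a
fixed-width profile. Rows are relative frequencies, so they sum to 1 and a
21-nt miRNA is comparable to a 500-nt transcript.
"""

import numpy as np

from mirtargraph import KmerConfig, SimConfig, frequency_matrix, simulate, split_kmers

sim = simulate(SimConfig(seed=1))
config = KmerConfig(k=7)

mirna = sim.mirna_records[0]
frags = split_kmers(mirna, config)
print(f"{mirna.id}: length {mirna.length} -> {len(frags)} 7-mers "
      f"(= {mirna.length} - 7 + 1)")
print(f"first three fragments: {frags[:3]}")

fm = frequency_matrix(sim.mirna_records + sim.target_records, config)
sums = np.asarray(fm.values.sum(axis=1)).ravel()
print(f"frequency matrix: {fm.shape[0]} x {fm.shape[1]} "
      f"({fm.values.nnz} nonzeros, {fm.values.nnz / fm.values.shape[0]:.0f} per row)")
print(f"row sums: min {sums.min():.12f}, max {sums.max():.12f}  (all 1 by construction)")
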