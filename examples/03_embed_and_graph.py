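"""Self-supervised embeddings, similarity networks, heterogeneous graph.

The autoencoder compresses each 16,384-dim frequency vector into a dense
embedding; within-role similarity networks (cosine, thresholded at 0.5) plus
the known association block form the symmetric heterogeneous adjacency A_H,
which is then self-looped and degree-normalised for graph convolution.
"""

import numpy as np

from mirtargraph import (
    KmerConfig,
    SDNNConfig,
    SimConfig,
    assemble_graph,
    embed,
    frequency_matrix,
    normalize,
    similarity_network,
    simulate,
    train_sdnn,
)

sim = simulate(SimConfig(seed=1))
fm = frequency_matrix(sim.mirna_records + sim.target_records, KmerConfig(k=7))

encoder, trace = train_sdnn(fm, SDNNConfig(embedding_dim=16, hidden_dim=256, epochs=200, seed=1))
print(f"autoencoder reconstruction loss: {trace[0]:.3g} -> {trace[-1]:.3g}")

emb = embed(encoder, fm)
print(f"embedding matrix: {emb.values.shape[0]} x {emb.values.shape[1]}")

nm = emb.n_mirna
S_m = similarity_network(emb.values[:nm], metric="cosine", threshold=0.5)
S_t = similarity_network(emb.values[nm:], metric="cosine", threshold=0.5)
print(f"miRNA similarity edges:  {np.count_nonzero(np.triu(S_m.values, 1))}")
print(f"target similarity edges: {np.count_nonzero(np.triu(S_t.values, 1))}")

graph = assemble_graph(S_m, S_t, sim.truth, emb)
P = normalize(graph).P
ev = np.linalg.eigvalsh(P)
print(f"A_H: {graph.A_H.shape[0]} x {graph.A_H.shape[1]}, "
      f"association edges: {int(graph.association_block.sum())}")
print(f"normalised operator spectrum in [{ev.min():.3f}, {ev.max():.3f}] (within [-1, 1])")
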