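"""Train on all known pairs and rank candidate targets for one miRNA.

After a single fit on every known association (plus an equal number of
sampled negatives), all unknown pairs of a chosen miRNA are scored and the
top five are printed, the way a biologist would shortlist candidates for
validation.
"""

import numpy as np

from mirtargraph import AssociationList, SimConfig, TrainConfig, simulate
from mirtargraph.graph import assemble_graph
from mirtargraph.study import desk_sdnn_config
from mirtargraph.training import FoldSplit, build_inputs, train_fold

sim = simulate(SimConfig(seed=1))
freqs, emb, S_m, S_t, _ = build_inputs(
    sim.mirna_records, sim.target_records,
    sdnn_config=desk_sdnn_config(1), similarity_source="embedding",
)
graph = assemble_graph(S_m, S_t, sim.truth, emb)

rng = np.random.default_rng(1)
unknown = [
    (m.id, t.id)
    for m in sim.mirna_records
    for t in sim.target_records
    if (m.id, t.id) not in sim.truth
]
neg = [unknown[i] for i in rng.choice(len(unknown), size=len(sim.truth), replace=False)]
fold = FoldSplit(fold_id=0, train_pos=list(sim.truth), train_neg=neg, test_pos=[], test_neg=[])
model, trace = train_fold(graph, fold, TrainConfig(seed=1, epochs=300))
print(f"trained on {len(sim.truth)} pairs, final loss {trace[-1]['total']:.4f}")

mirna = "miR-f1-1"
mi = graph.mirna_ids.index(mirna)
cand = [(t, j) for j, t in enumerate(graph.target_ids) if (mirna, t) not in sim.truth]
probs = model.forward([(mi, j) for _, j in cand])[0]
print(f"top 5 candidate targets for {mirna}:")
for (t, _), p in sorted(zip(cand, probs), key=lambda r: -r[1])[:5]:
    print(f"  {t}\t{p:.4f}")
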