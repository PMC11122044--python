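"""Generate a synthetic plant-like miRNA/transcript dataset.

Two miRNA families (three ~21-nt members each, differing by a few point
mutations from a family core) and 60 transcripts of 500 nt; each transcript
carries one mutated reverse-complement binding site of its assigned miRNA,
the way plant miRNAs pair with near-perfect complementarity. The planted
(miRNA, target) pairs are the ground truth the predictor should recover.
"""

from mirtargraph import SimConfig, export, simulate

sim = simulate(SimConfig(seed=1))
paths = export(sim, "scratch/example-data")

print(f"miRNAs:   {len(sim.mirna_records)} ({sim.mirna_records[0].id} ...)")
print(f"targets:  {len(sim.target_records)} of {sim.target_records[0].length} nt")
print(f"planted associations: {len(sim.truth)}")
print(f"first miRNA sequence: {sim.mirna_records[0].sequence}")
for name, p in paths.items():
    print(f"wrote {name}: {p}")
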