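"""Cross-validated link prediction on planted-signal data.

Runs the imbalanced 5-fold protocol: positives split five ways, training on
four fifths plus an equal number of sampled unknown pairs, testing the
held-out positives against every remaining unknown pair. AUROC/AUPRC are the
threshold-free headline metrics; a shuffled-label control shows what the
numbers look like when the sequence signal is destroyed.
"""

from mirtargraph.study import planted_signal_study

res = planted_signal_study(seed=1)
print(f"seed {res['seed']} (6 miRNAs, 60 targets, one planted site each):")
print(f"  mean 5-CV AUROC, full model:        {res['auroc_full']:.3f}")
print(f"  mean 5-CV AUPRC, full model:        {res['auprc_full']:.3f}")
print(f"  shuffled-label control AUROC:       {res['auroc_shuffled']:.3f}")
print(f"  no-node-features ablation AUROC:    {res['auroc_no_features']:.3f}")
print()
print("At this desk scale every target carries exactly one association, so")
print("held-out targets are isolated in the fold graph and identity")
print("memorisation anti-correlates with the test positives; see")
print("docs/methods.md for why these numbers sit below chance here.")
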