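"""Evaluate a ranked edge list against the known gold standard.

Runs inference on a simulated network and scores the prediction list the
DREAM way: confusion counts at a top-K cutoff, then the full ROC and
precision-recall sweeps.  AUROC is the probability that a random true edge
outranks a random non-edge; AUPR summarizes precision over the whole
recall range (the random-guess baseline equals the edge density).
"""

import tigress
from tigress.stability import StabilityConfig

net = tigress.generate_network(p=30, q=6, mean_out_degree=3, seed=4)
X = tigress.simulate_expression(net, n=80, seed=5)
ranked = tigress.infer_network(X, net.tf_ids, StabilityConfig(R=400, master_seed=1))

K = net.n_edges  # cut at the number of true edges
c = tigress.confusion_at_k(ranked, net.gold, K)
print(f"top {K} predictions: TP={c.TP} FP={c.FP} FN={c.FN} TN={c.TN}")
print(f"precision={c.precision:.3f} recall={c.recall:.3f} fall-out={c.fallout:.3f}")

summary = tigress.curves_and_areas(ranked, net.gold)
density = net.n_edges / len(net.candidates)
print(f"AUROC = {summary.auroc:.3f}   (random ranking: 0.5)")
print(f"AUPR  = {summary.aupr:.3f}   (random ranking: ~{density:.3f}, the edge density)")
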