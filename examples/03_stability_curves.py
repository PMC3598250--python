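"""Inspect the stability-selection frequencies behind the scores.

For one target gene, F(g, t, l) is the fraction of randomized LARS runs in
which TF t entered within the first l steps — a non-decreasing curve in l
for each TF.  The original score reads the curve at l = L; the area score
averages it over l = 1..L, rewarding TFs that enter early.  Per target the
frequencies at step l always sum to l (each run selects exactly l TFs).
"""

import numpy as np

import tigress
from tigress.scoring import score_area, score_original
from tigress.stability import StabilityConfig, run_stability

net = tigress.generate_network(p=12, q=4, mean_out_degree=2, seed=3)
X = tigress.simulate_expression(net, n=50, seed=6)

L = 3
F = run_stability(X, net.regs, StabilityConfig(R=500, L=L, alpha=0.4, master_seed=2))
s_orig, s_area = score_original(F), score_area(F)

g = net.gene_ids.index("G10")
true_regs = {t for (t, tgt) in net.coefficients if tgt == "G10"}
print(f"target G10; true regulators: {sorted(true_regs) or 'none'}")
print(f"{'TF':<6}{'F(l=1)':>8}{'F(l=2)':>8}{'F(l=3)':>8}{'original':>10}{'area':>8}")
for j, tf in enumerate(F.tf_ids):
    if tf == "G10":
        continue
    f1, f2, f3 = F.F[g, j, :]
    print(f"{tf:<6}{f1:>8.3f}{f2:>8.3f}{f3:>8.3f}"
          f"{s_orig.s[g, j]:>10.3f}{s_area.s[g, j]:>8.3f}")
mask = F.candidate_mask()
sums = [float((F.F[g, :, l] * mask[g]).sum()) for l in range(L)]
print(f"per-step frequency sums (must equal l): {np.round(sums, 9)}")
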