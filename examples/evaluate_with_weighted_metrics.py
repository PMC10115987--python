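"""Why weighted metrics: a clustering that misses a rare class entirely.

Uniform-weight purity barely notices losing a 4-cell class inside a
996-cell cluster; the weighted metrics, which give every reference class
equal probability mass, penalize it heavily.  The rare-cluster protocol
then quantifies detection of that class directly.
"""

import progclust as pc

# reference: 996 "big" cells and 4 "rare" cells
ref = {f"c{i}": ("rare" if i < 4 else "big") for i in range(1000)}

# clustering A lumps everything together with the rare cells lost
pred_lost = {c: "cluster1" for c in ref}
# clustering B isolates the rare class
pred_found = {c: ("r" if ref[c] == "rare" else "cluster1") for c in ref}

for name, pred in [("rare class lost", pred_lost),
                   ("rare class found", pred_found)]:
    nmi = pc.weighted_nmi(pred, ref)
    pur = pc.weighted_purity(pred, ref)
    print(f"{name}: weighted NMI = {nmi:.3f}, weighted Purity = {pur:.3f}")

rec, prec, f1, k = pc.rare_cluster_prf(pred_found, ref, "rare", max_size=20)
print(f"rare-cluster protocol on the good clustering: "
      f"recall={rec:.2f} precision={prec:.2f} F1={f1:.2f} "
      f"({k} merged cluster)")
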