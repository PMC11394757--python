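"""The pocket-level evaluation metrics on hand-made predictions.

DCC (center-center distance, success iff <= 4 Å), DVO (Jaccard overlap
of 2 Å voxelizations), and the pocket-level precision/recall/F1 where a
matched prediction within 4 Å is a TP, beyond 4 Å an FP, and an
unpredicted site an FN.
"""

import numpy as np

from pocketgnn.inference import PocketCluster
from pocketgnn.metrics import (compute_dcc, compute_dvo, match_sites,
                               success_curve, summarize)
from pocketgnn.structure_io import LigandSite


def pocket(center, rank):
    c = PocketCluster(np.array([0]), np.array([0.9]),
                      np.asarray(center, float).reshape(1, 3))
    c.rank = rank
    return c


sites = [LigandSite("site_a", np.array([[0.0, 0, 0]])),
         LigandSite("site_b", np.array([[25.0, 0, 0]])),
         LigandSite("site_c", np.array([[0.0, 30.0, 0]]))]
pockets = [pocket((1.0, 2.0, 2.0), 1),    # 3 Å from site_a  -> TP
           pocket((31.0, 0.0, 0.0), 2)]   # 6 Å from site_b  -> FP; site_c FN

records = match_sites(pockets, sites, "demo")
for r in records:
    print(f"{r.site_id}: DCC = "
          f"{'%.2f Å' % r.dcc if r.dcc is not None else 'missing'}")

s = summarize(records)
print(f"TP={s.tp} FP={s.fp} FN={s.fn}  precision={s.precision:.3f} "
      f"recall={s.recall:.3f} F1={s.f1:.3f} success rate={s.success_rate:.3f}")

print("success curve:",
      [f"{t:.0f}Å:{v:.2f}" for t, v in
       zip([2, 4, 6, 8], success_curve(records, [2, 4, 6, 8]))])

rng = np.random.default_rng(0)
patch = rng.uniform(0, 6, (60, 3))
print(f"DVO(identical sets) = {compute_dvo(patch, patch):.2f}, "
      f"DVO(offset by 2 Å) = {compute_dvo(patch, patch + 2.0):.2f}")
print(f"DCC((0,0,0),(1,2,2)) = {compute_dcc((0, 0, 0), (1, 2, 2)):.1f} Å")
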