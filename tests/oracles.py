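"""Brute-force oracle implementations shared by the unit and acceptance
suites.  These stay deliberately naive (explicit loops, hash maps) and
independent of the vectorized code paths they check."""

import numpy as np


def brute_force_voxel(coords, voxel):
    """Hash points into origin-anchored voxels; pick the point nearest the
    voxel centroid (distances rounded to 1e-9 Å, lowest index on ties)."""
    keys = [tuple(np.floor(p / voxel).astype(int)) for p in coords]
    groups = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    chosen = []
    for members in groups.values():
        centroid = coords[members].mean(axis=0)
        d = [round(float(np.linalg.norm(coords[i] - centroid)), 9)
             for i in members]
        chosen.append(members[int(np.argmin(d))])
    return sorted(chosen)


def brute_force_edges(coords, r, max_edges):
    """All-pairs distance test with strict < r and nearest-first
    truncation (distance ties by lower index), sorted by (i, j)."""
    edges = []
    for i in range(len(coords)):
        cand = []
        for j in range(len(coords)):
            if j == i:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d < r:
                cand.append((d, j))
        cand.sort()
        for _, j in sorted(cand[:max_edges], key=lambda t: t[1]):
            edges.append((i, j))
    return edges


def brute_force_aggregate(feats, coords, selected, r0, net):
    """Per-vertex loop over all points within r0 through the aggregation
    MLP, reduced with an explicit elementwise max."""
    W1 = np.vstack([net.W_feat.data, net.W_rel.data])
    out = []
    for s in selected:
        rows = []
        for p in range(len(coords)):
            rel = coords[p] - coords[s]
            if np.linalg.norm(rel) <= r0:
                x = np.concatenate([feats[p], rel]).astype(np.float32)
                h = np.maximum(x @ W1 + net.b1.data, 0)
                rows.append(h @ net.lin2.W.data + net.lin2.b.data)
        out.append(np.max(rows, axis=0))
    return np.array(out)
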