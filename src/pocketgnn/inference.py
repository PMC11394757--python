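"""From per-vertex probabilities to ranked binding pockets.

Vertices with probability strictly above 0.5 are kept, clustered in 3-D
with OPTICS (noise discarded), and each cluster becomes a pocket scored
by the sum of its members' probabilities; pockets are ranked by score
descending.  In evaluation mode only the top-n pockets are kept, n being
the structure's known site count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import OPTICS

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_SAMPLES = 5
DEFAULT_MAX_EPS = 6.0
DEFAULT_XI = 0.05


@dataclass
class PocketCluster:
    """A predicted pocket: member vertices, probability-sum score,
    geometric center and 1-based rank."""

    member_indices: np.ndarray
    member_probs: np.ndarray
    member_coords: np.ndarray
    rank: int = 0
    score: float = field(init=False)
    center: np.ndarray = field(init=False)

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        self.member_probs = np.asarray(self.member_probs, dtype=np.float64)
        self.member_coords = np.asarray(self.member_coords,
                                        dtype=np.float64).reshape(-1, 3)
        self.score = float(self.member_probs.sum())
        self.center = self.member_coords.mean(axis=0)


def threshold_points(probs: np.ndarray,
                     threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Indices with probability strictly greater than ``threshold``."""
    return np.flatnonzero(np.asarray(probs) > threshold)


def cluster_pockets(coords: np.ndarray, probs: np.ndarray,
                    min_samples: int = DEFAULT_MIN_SAMPLES,
                    max_eps: float = DEFAULT_MAX_EPS,
                    xi: float = DEFAULT_XI,
                    cluster_method: str = "dbscan",
                    weighted_center: bool = False):
    """OPTICS-cluster positive vertices into ranked :class:`PocketCluster`s.

    Noise points are discarded; an empty list (everything noise or fewer
    points than ``min_samples``) is a valid outcome.  Extraction defaults
    to the DBSCAN-style reachability cut at ``max_eps``: unlike the xi
    method it is stable under exactly duplicated points (scores must add
    when a blob is duplicated point-for-point); xi extraction remains
    available via ``cluster_method="xi"``.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    probs = np.asarray(probs, dtype=np.float64)
    if len(coords) == 0:
        raise ValueError("no coordinates to cluster")
    if len(coords) < min_samples:
        return []
    optics = OPTICS(min_samples=min_samples, max_eps=max_eps, xi=xi,
                    cluster_method=cluster_method)
    labels = optics.fit(coords).labels_
    clusters = []
    for lbl in np.unique(labels[labels >= 0]):
        idx = np.flatnonzero(labels == lbl)
        c = PocketCluster(idx, probs[idx], coords[idx])
        if weighted_center:
            c.center = np.average(coords[idx], axis=0, weights=probs[idx])
        clusters.append(c)
    clusters.sort(key=lambda c: -c.score)
    for rank, c in enumerate(clusters, start=1):
        c.rank = rank
    return clusters


def select_top_n(clusters, n: int):
    """First ``n`` pockets in rank order plus the shortfall (how many of
    the ``n`` expected sites have no prediction)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    top = clusters[:n]
    return top, max(0, n - len(clusters))


def pockets_to_dataframe(clusters) -> pd.DataFrame:
    return pd.DataFrame([{
        "rank": c.rank, "score": c.score, "n_points": len(c.member_indices),
        "cx": c.center[0], "cy": c.center[1], "cz": c.center[2],
    } for c in clusters])


def write_pocket_pdb(clusters, path):
    """Pocket member points as HETATM pseudo-atoms (residue PCK, one
    residue per pocket) for visualization."""
    lines = []
    serial = 1
    for c in clusters:
        for x, y, z in c.member_coords:
            lines.append(
                f"HETATM{serial:5d}  C   PCK P{c.rank:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
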