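"""Pocket-level evaluation: DCC, success rate, DVO and pocket F1.

DCC is the Euclidean distance between a predicted pocket center and the
true site center; a prediction counts as correct when DCC ≤ 4 Å
(inclusive).  DVO is the Jaccard overlap of the voxelized predicted and
actual site volumes.  At the dataset level, TP are matched predictions
with DCC ≤ 4 Å, FP matched predictions above, FN sites with no
prediction; precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R), success rate = correct sites / total sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DCC_THRESHOLD = 4.0      # Å
DVO_VOXEL = 2.0          # Å, origin-anchored grid


@dataclass
class SiteEvalRecord:
    structure_id: str
    site_id: str
    dcc: float = None         # None means no prediction for this site
    dvo: float = None
    matched_rank: int = None

    @property
    def missing(self) -> bool:
        return self.dcc is None


@dataclass
class EvalSummary:
    n_sites: int
    n_correct: int
    n_missing: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    success_rate: float
    mean_dvo: float


def compute_dcc(pred_center, true_center) -> float:
    pred_center = np.asarray(pred_center, dtype=np.float64)
    true_center = np.asarray(true_center, dtype=np.float64)
    return float(np.linalg.norm(pred_center - true_center))


def match_sites(predictions, sites, structure_id: str = ""):
    """Greedily pair sites with predicted pockets by best available DCC.

    At each step, the unassigned (site, pocket) pair with the smallest
    DCC is matched; sites left without a pocket get a missing record.
    Each prediction is used at most once.
    """
    n_s, n_p = len(sites), len(predictions)
    records = [None] * n_s
    if n_p:
        d = np.array([[compute_dcc(p.center, s.center) for p in predictions]
                      for s in sites])
        free_s = set(range(n_s))
        free_p = set(range(n_p))
        while free_s and free_p:
            best = min(((d[s, p], s, p) for s in free_s for p in free_p))
            _, s, p = best
            records[s] = SiteEvalRecord(
                structure_id, getattr(sites[s], "ligand_id", str(s)),
                dcc=float(d[s, p]), matched_rank=predictions[p].rank)
            free_s.discard(s)
            free_p.discard(p)
    for s in range(n_s):
        if records[s] is None:
            records[s] = SiteEvalRecord(
                structure_id, getattr(sites[s], "ligand_id", str(s)))
    return records


def _voxelize(points, voxel):
    keys = np.floor(np.asarray(points, dtype=np.float64) / voxel).astype(np.int64)
    return set(map(tuple, keys))


def compute_dvo(pred_points, true_points, voxel: float = DVO_VOXEL) -> float:
    """Jaccard overlap of origin-anchored voxel sets (edge ``voxel`` Å)."""
    pred_points = np.asarray(pred_points)
    true_points = np.asarray(true_points)
    if len(pred_points) == 0 or len(true_points) == 0:
        raise ValueError("DVO undefined for empty point sets")
    a = _voxelize(pred_points, voxel)
    b = _voxelize(true_points, voxel)
    return len(a & b) / len(a | b)


def summarize(records, dcc_threshold: float = DCC_THRESHOLD) -> EvalSummary:
    if not records:
        raise ValueError("no records to summarize")
    matched = [r for r in records if not r.missing]
    tp = sum(r.dcc <= dcc_threshold for r in matched)
    fp = len(matched) - tp
    fn = sum(r.missing for r in records)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    dvos = [r.dvo for r in records if r.dvo is not None]
    return EvalSummary(
        n_sites=len(records), n_correct=tp, n_missing=fn,
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1,
        success_rate=tp / len(records),
        mean_dvo=float(np.mean(dvos)) if dvos else float("nan"))


def success_curve(records, thresholds):
    """Success rate at each DCC threshold (non-decreasing by construction)."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    dccs = np.array([r.dcc for r in records if not r.missing])
    n = len(records)
    return [float((dccs <= t).sum() / n) if n else 0.0 for t in thresholds]


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "structure_id": r.structure_id, "site_id": r.site_id,
        "dcc": r.dcc, "dvo": r.dvo, "matched_rank": r.matched_rank,
    } for r in records])
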