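"""Evaluation against crystallographic ground truth.

A module prediction is correct if its centroid lies within 5 Å of a
same-type fragment of the bound ligand.  Assembled sites are judged
under three criteria (all member distances, mean-centroid distance,
centroid RMSD), predictions can be screened at a score threshold for
precision/recall/F-score, and a protein is classified as a nucleotide
binder when its best assembled-site score reaches the trained
threshold (166.33).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import structio
from .assemble import SitePrediction
from .pipeline import ModulePrediction
from .structio import ModuleFragment, Structure

CORRECT_CUTOFF = 5.0          # Å, centroid distance, inclusive
BINDER_THRESHOLD = 166.33     # best-site score separating binders
TOP_KS = (1, 3, 5, 10)


@dataclass
class GroundTruth:
    """Crystallographic module fragments of the bound ligand."""
    fragments: list[ModuleFragment]
    component_id: str = ""

    def by_type(self, module_type: str) -> list[ModuleFragment]:
        return [f for f in self.fragments if f.module_type == module_type]


def ground_truth_from_complex(holo: Structure, defs,
                              component_id: str | None = None) -> GroundTruth:
    """Decompose the (first matching) bound ligand of a holo complex."""
    for ligand in holo.ligands:
        if component_id is not None and ligand.component_id != component_id:
            continue
        try:
            frags = structio.decompose_ligand(ligand, defs)
        except structio.UnknownLigandError:
            continue
        if frags:
            return GroundTruth(fragments=frags,
                               component_id=ligand.component_id)
    raise ValueError("no decomposable ligand found in the complex")


def module_correct(pred: ModulePrediction | ModuleFragment,
                   truth: GroundTruth,
                   cutoff: float = CORRECT_CUTOFF) -> bool:
    """Centroid within ``cutoff`` (inclusive) of any same-type truth fragment."""
    frag = getattr(pred, "fragment", pred)
    same = truth.by_type(frag.module_type)
    if not same:
        return False
    dmin = min(np.linalg.norm(frag.centroid - t.centroid) for t in same)
    return bool(dmin <= cutoff)


def topk_performance(ranked: list[ModulePrediction], truth: GroundTruth,
                     ks=TOP_KS, cutoff: float = CORRECT_CUTOFF) -> dict[int, bool]:
    """Hit at k iff any of the first k ranked predictions is correct."""
    flags = [module_correct(p, truth, cutoff) for p in ranked]
    return {k: any(flags[:k]) for k in ks}


def prf_at_threshold(predictions: list[ModulePrediction], truth: GroundTruth,
                     score_threshold: float,
                     cutoff: float = CORRECT_CUTOFF,
                     recall_mode: str = "per_fragment"):
    """Precision/recall/F over predictions scoring >= threshold.

    Recall's denominator is the number of truth fragments of the
    module type(s) present (``per_fragment``), or 1 if any fragment is
    covered at all (``per_protein``).  Degenerate cases return 0 and a
    flag.
    """
    positives = [p for p in predictions if p.total_score >= score_threshold]
    flags = []
    if not positives:
        return 0.0, 0.0, 0.0, ["no-positives"]
    correct = [p for p in positives if module_correct(p, truth, cutoff)]
    precision = len(correct) / len(positives)

    types = {p.module_type for p in predictions}
    truth_frags = [f for f in truth.fragments if f.module_type in types]
    if not truth_frags:
        return precision, 0.0, 0.0, ["no-truth-fragments"]
    covered = sum(
        1 for f in truth_frags
        if any(np.linalg.norm(p.fragment.centroid - f.centroid) <= cutoff
               for p in correct))
    if recall_mode == "per_protein":
        recall = 1.0 if covered else 0.0
    else:
        recall = covered / len(truth_frags)
    if precision + recall == 0:
        return precision, recall, 0.0, ["zero-f"]
    f = 2 * precision * recall / (precision + recall)
    return precision, recall, f, flags


def best_threshold(train: list[tuple[list[ModulePrediction], GroundTruth]],
                   cutoff: float = CORRECT_CUTOFF) -> float:
    """Grid over observed scores maximising mean F (ties: highest)."""
    if not train:
        raise ValueError("empty training set")
    scores = sorted({p.total_score for preds, _ in train for p in preds})
    if not scores:
        return 0.0
    best_t, best_f = scores[0], -1.0
    for t in scores:
        fs = [prf_at_threshold(preds, truth, t, cutoff)[2]
              for preds, truth in train]
        mean_f = float(np.mean(fs))
        if mean_f >= best_f:        # >= keeps the highest tied threshold
            best_f, best_t = mean_f, t
    return best_t


def _correspondence(site: SitePrediction, truth: GroundTruth):
    """Minimum-total-distance bijection of same-type members to truth."""
    pairs = []
    members = list(site.modules)
    for module_type in structio.MODULE_TYPES:
        mine = [m for m in members if m.module_type == module_type]
        theirs = truth.by_type(module_type)
        if not mine:
            continue
        if len(mine) > len(theirs):
            raise ValueError(
                f"site has more {module_type} members than the ligand")
        cost = np.array([[np.linalg.norm(m.centroid - t.centroid)
                          for t in theirs] for m in mine])
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            pairs.append((mine[r], theirs[c], float(cost[r, c])))
    return pairs


def site_correct(site: SitePrediction, truth: GroundTruth,
                 criterion: str = "rmsd",
                 cutoff: float = CORRECT_CUTOFF) -> bool:
    """Judge an assembled site against the crystallographic modules.

    ``all_modules``: every corresponding centroid pair <= cutoff
    (inclusive).  ``ligand_centroid``: the means of predicted and
    corresponding true centroids lie strictly closer than cutoff.
    ``rmsd``: root mean square of corresponding centroid distances
    <= cutoff (inclusive).
    """
    pairs = _correspondence(site, truth)
    dists = np.array([d for _, _, d in pairs])
    if criterion == "all_modules":
        return bool(np.all(dists <= cutoff))
    if criterion == "ligand_centroid":
        pred_mean = np.mean([m.centroid for m, _, _ in pairs], axis=0)
        true_mean = np.mean([t.centroid for _, t, _ in pairs], axis=0)
        return bool(np.linalg.norm(pred_mean - true_mean) < cutoff)
    if criterion == "rmsd":
        return bool(np.sqrt(np.mean(dists ** 2)) <= cutoff)
    raise ValueError(f"unknown criterion {criterion!r}")


def classify_binder(best_site_score: float | None,
                    threshold: float = BINDER_THRESHOLD) -> bool:
    """True iff the best assembled-site score reaches the threshold."""
    if best_site_score is None:
        return False
    return best_site_score >= threshold


def mcc(tp: int, tn: int, fp: int, fn: int):
    """Matthews correlation coefficient; zero denominator -> (0, flagged)."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0, ["zero-denominator"]
    return (tp * tn - fp * fn) / denom, []


def kfold_splits(items: list, k: int = 10, seed: int = 0):
    """Seeded k-fold index splits (train, test) with ~(k-1):1 ratios."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(items))
    folds = np.array_split(idx, k)
    out = []
    for i in range(k):
        test = sorted(int(j) for j in folds[i])
        train = sorted(int(j) for f in folds[:i] + folds[i + 1:] for j in f)
        out.append((train, test))
    return out


@dataclass
class EvalReport:
    topk: dict[str, dict[int, bool]] = field(default_factory=dict)
    prf: dict[str, tuple] = field(default_factory=dict)
    site: dict[str, bool] = field(default_factory=dict)
    binder: bool | None = None

    def to_dict(self) -> dict:
        return {
            "topk": {t: {str(k): v for k, v in d.items()}
                     for t, d in self.topk.items()},
            "prf": {t: list(v) for t, v in self.prf.items()},
            "site": dict(self.site),
            "binder": self.binder,
        }
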