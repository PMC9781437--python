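"""Segmentation evaluation: confusion counts and the six standard metrics.

ACC, G-mean, Kappa, Dice and FDR are computed from TP/FP/TN/FN tallies;
AUC is the fraction of (positive, negative) score pairs ranked correctly,
ties counting one half — i.e. the Wilcoxon-Mann-Whitney statistic (a
strict-inequality mode is available).  Centerline-level ground truth (deep
vessels) is evaluated within a small pixel tolerance band, since an exact
overlay against a 1-px medial axis is ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from skimage.morphology import dilation, disk


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def pe(self) -> float:
        """Chance agreement of the Kappa statistic."""
        t = self.total
        return ((self.TP + self.FN) * (self.TP + self.FP)
                + (self.TN + self.FP) * (self.TN + self.FN)) / t ** 2


def confusion(pred_bin: np.ndarray, gt: np.ndarray,
              mask: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel tallies over the evaluation mask (default: everywhere)."""
    pred_bin, gt = np.asarray(pred_bin), np.asarray(gt)
    if pred_bin.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred_bin.shape} vs {gt.shape}")
    keep = np.ones(gt.shape, bool) if mask is None else mask.astype(bool)
    p = pred_bin.astype(bool)[keep]
    g = gt.astype(bool)[keep]
    return ConfusionCounts(TP=int(np.sum(p & g)), FP=int(np.sum(p & ~g)),
                           TN=int(np.sum(~p & ~g)), FN=int(np.sum(~p & g)))


def auc(scores_pos, scores_neg, ties: str = "half") -> float:
    """Pairwise ranking AUC: fraction of (pos, neg) pairs with pos > neg.

    ties="half" counts tied pairs 0.5 (rank-statistic convention);
    ties="strict" counts only strict inequalities.
    """
    pos = np.asarray(scores_pos, dtype=np.float64).ravel()
    neg = np.asarray(scores_neg, dtype=np.float64).ravel()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("auc undefined: one class has no scores")
    if ties == "half":
        ranks = rankdata(np.concatenate([pos, neg]))
        p = len(pos)
        return float((ranks[:p].sum() - p * (p + 1) / 2) / (p * len(neg)))
    if ties == "strict":
        sneg = np.sort(neg)
        wins = np.searchsorted(sneg, pos, side="left").sum()
        return float(wins / (len(pos) * len(neg)))
    raise ValueError(f"ties must be 'half' or 'strict', got {ties!r}")


def metric_suite(c: ConfusionCounts) -> dict[str, float]:
    """ACC, G-mean, Kappa, Dice and FDR from one confusion table.

    A metric whose denominator is zero is reported as nan (undefined),
    never silently as 0.
    """
    if c.total <= 0:
        raise ValueError("empty confusion table")
    out = {}
    out["acc"] = (c.TP + c.TN) / c.total
    pos, negc = c.TP + c.FN, c.TN + c.FP
    out["gmean"] = float(np.sqrt(c.TP * c.TN / (pos * negc))) \
        if pos and negc else float("nan")
    pe = c.pe
    out["kappa"] = (out["acc"] - pe) / (1 - pe) if pe < 1 else float("nan")
    denom = c.FP + c.FN + 2 * c.TP
    out["dice"] = 2 * c.TP / denom if denom else float("nan")
    out["fdr"] = c.FP / (c.TP + c.FP) if (c.TP + c.FP) else float("nan")
    return out


def tolerance_band_confusion(pred_bin: np.ndarray, centerline_gt: np.ndarray,
                             tolerance: int = 2) -> ConfusionCounts:
    """Confusion against centerline ground truth within a pixel tolerance.

    A predicted pixel within `tolerance` px of the centerline counts TP;
    outside the dilated band it is FP.  A centerline pixel with no
    prediction within tolerance counts FN.
    """
    pred = np.asarray(pred_bin).astype(bool)
    gt = np.asarray(centerline_gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    band = dilation(gt, disk(tolerance))
    pred_band = dilation(pred, disk(tolerance))
    TP = int(np.sum(pred & band))
    FP = int(np.sum(pred & ~band))
    FN = int(np.sum(gt & ~pred_band))
    TN = int(pred.size - TP - FP - FN)
    return ConfusionCounts(TP=TP, FP=FP, TN=TN, FN=FN)


def dice_score(pred_bin: np.ndarray, gt: np.ndarray,
               centerline: bool = False, tolerance: int = 2) -> float:
    """Dice of a binarised prediction, optionally centerline-tolerant."""
    c = tolerance_band_confusion(pred_bin, gt, tolerance) if centerline \
        else confusion(pred_bin, gt)
    return metric_suite(c)["dice"]


def evaluate_scores(prob: np.ndarray, gt: np.ndarray,
                    threshold: float = 0.5,
                    centerline: bool = False,
                    tolerance: int = 2) -> dict[str, float]:
    """Full metric report for one continuous probability map."""
    pred_bin = (np.asarray(prob) >= threshold).astype(np.uint8)
    gt_b = np.asarray(gt).astype(bool)
    if centerline:
        c = tolerance_band_confusion(pred_bin, gt_b, tolerance)
        band = dilation(gt_b, disk(tolerance))
        pos_scores, neg_scores = prob[band], prob[~band]
    else:
        c = confusion(pred_bin, gt_b)
        pos_scores, neg_scores = prob[gt_b], prob[~gt_b]
    out = metric_suite(c)
    out["auc"] = auc(pos_scores, neg_scores) \
        if len(pos_scores) and len(neg_scores) else float("nan")
    return out
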