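"""Network evaluation against a gold standard.

Only gold-standard pairs are scored: the labeled pairs present in the
network are ranked by edge weight, a confusion table (TP, FP, TN, FN) is
recorded at every distinct weight threshold (ties enter together), and the
threshold sweep yields auPRC, auROC, and precision at a fixed recall by
trapezoidal integration.

Because gold standards of different tissues have different positive/
negative ratios, raw auPRC values are not comparable across standards;
the headline statistic is log2(auPRC/prior), where the prior — the
fraction of positives among labeled pairs — is the auPRC of a random
ranking.  A perfect ranking scores -log2(prior); a random one scores ~0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .goldstd import GoldStandard
from .netbuild import CoexpressionNetwork

__all__ = [
    "ConfusionSweep",
    "EvaluationResult",
    "confusion_sweep",
    "auprc",
    "auroc",
    "precision_at_recall",
    "log2_auprc_over_prior",
    "evaluate",
]


@dataclass
class ConfusionSweep:
    """Confusion counts over descending distinct weight thresholds.

    ``table`` has columns threshold, tp, fp, tn, fn; at every row
    tp + fn = n_pos and fp + tn = n_neg, and tp/fp are non-decreasing.
    """

    table: pd.DataFrame
    n_pos: int
    n_neg: int
    n_dropped: int = 0

    @property
    def prior(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)


def confusion_sweep(net: CoexpressionNetwork, std: GoldStandard) -> ConfusionSweep:
    """Score gold-standard pairs by network weight over all thresholds.

    Pairs with a gene missing from the network are dropped and counted in
    ``n_dropped``.  One row per distinct weight; rows run from the highest
    threshold down to all-pairs-predicted-positive.
    """
    index = {g: i for i, g in enumerate(net.genes)}
    weights, labels = [], []
    n_dropped = 0
    for label, pairs in ((1, std.positives), (0, std.negatives)):
        for a, b in pairs:
            ia, ib = index.get(a), index.get(b)
            if ia is None or ib is None:
                n_dropped += 1
                continue
            weights.append(net.weights[ia, ib])
            labels.append(label)
    if not weights:
        raise ValueError("no gold-standard pair is present in the network")
    w = np.asarray(weights, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-w, kind="stable")
    w, y = w[order], y[order]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    # last position of each distinct weight value
    boundaries = np.flatnonzero(np.diff(w) != 0)
    last = np.concatenate([boundaries, [w.size - 1]])
    cum_tp = np.cumsum(y)
    tp = cum_tp[last]
    fp = (last + 1) - tp
    table = pd.DataFrame(
        {
            "threshold": w[last],
            "tp": tp,
            "fp": fp,
            "tn": n_neg - fp,
            "fn": n_pos - tp,
        }
    )
    return ConfusionSweep(table, n_pos=n_pos, n_neg=n_neg, n_dropped=n_dropped)


def auprc(sweep: ConfusionSweep) -> float:
    """Trapezoidal area under precision vs. recall.

    The curve is anchored at recall 0 with the precision of the
    highest-threshold row (no artificial (0, 1) point).
    """
    if sweep.n_pos == 0:
        raise ValueError("auPRC undefined with zero positives")
    t = sweep.table
    recall = t["tp"].to_numpy() / sweep.n_pos
    precision = t["tp"].to_numpy() / (t["tp"].to_numpy() + t["fp"].to_numpy())
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(p, r))


def auroc(sweep: ConfusionSweep) -> float:
    """Trapezoidal area under TPR vs. FPR, anchored at (0,0); the sweep's
    final row supplies (1,1)."""
    if sweep.n_pos == 0 or sweep.n_neg == 0:
        raise ValueError("auROC needs both positives and negatives")
    t = sweep.table
    tpr = np.concatenate([[0.0], t["tp"].to_numpy() / sweep.n_pos])
    fpr = np.concatenate([[0.0], t["fp"].to_numpy() / sweep.n_neg])
    return float(np.trapezoid(tpr, fpr))


def precision_at_recall(sweep: ConfusionSweep, level: float = 0.20) -> float:
    """Precision at the first sweep row whose recall reaches ``level``
    (step function, no interpolation)."""
    if not 0 < level <= 1:
        raise ValueError("recall level must be in (0, 1]")
    t = sweep.table
    recall = t["tp"].to_numpy() / sweep.n_pos
    idx = int(np.argmax(recall >= level))
    tp, fp = t["tp"].iloc[idx], t["fp"].iloc[idx]
    return float(tp / (tp + fp))


def log2_auprc_over_prior(auprc_value: float, prior: float) -> float:
    if auprc_value <= 0:
        raise ValueError("auPRC must be positive")
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    return float(np.log2(auprc_value / prior))


@dataclass
class EvaluationResult:
    """Bundle of evaluation metrics for one network against one standard."""

    auprc: float
    prior: float
    log2_auprc_over_prior: float
    auroc: float
    precision_at_recall: dict[float, float] = field(default_factory=dict)
    n_sweep_rows: int = 0
    n_dropped_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "auprc": self.auprc,
            "prior": self.prior,
            "log2_auprc_over_prior": self.log2_auprc_over_prior,
            "auroc": self.auroc,
            "precision_at_recall": {str(k): v for k, v in self.precision_at_recall.items()},
            "n_sweep_rows": self.n_sweep_rows,
            "n_dropped_pairs": self.n_dropped_pairs,
        }


def evaluate(
    net: CoexpressionNetwork,
    std: GoldStandard,
    recall_levels: tuple[float, ...] = (0.20,),
) -> EvaluationResult:
    """Full evaluation: sweep, auPRC, prior, log2(auPRC/prior), auROC,
    precision at each requested recall level."""
    sweep = confusion_sweep(net, std)
    area = auprc(sweep)
    return EvaluationResult(
        auprc=area,
        prior=sweep.prior,
        log2_auprc_over_prior=log2_auprc_over_prior(area, sweep.prior),
        auroc=auroc(sweep),
        precision_at_recall={lv: precision_at_recall(sweep, lv) for lv in recall_levels},
        n_sweep_rows=len(sweep.table),
        n_dropped_pairs=sweep.n_dropped,
    )
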