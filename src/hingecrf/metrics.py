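"""Residue-level evaluation: confusion-based metrics, ROC/AUC, bootstrap
standard errors.

The positive class is boundary.  Reported metrics are sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy Ac, Matthews
correlation MCC, the weighted score Sw = Sn + Sp - 1 and the area under
the ROC curve computed by the rank (Mann-Whitney) statistic with ties
counted half.  Metrics with a zero denominator are reported as undefined
(None), never silently as zero.  Standard errors come from bootstrap
resampling of targets: a fraction of the targets (default 80%) is drawn
without replacement, the metric is recomputed on the pooled residues, and
the sample standard deviation across replicates (default 1000) is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .labels import LabelString


@dataclass(frozen=True)
class Confusion:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "Confusion") -> "Confusion":
        return Confusion(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )


@dataclass(frozen=True)
class MetricReport:
    Sn: float | None
    Sp: float | None
    Ac: float | None
    MCC: float | None
    Sw: float | None
    AUC: float | None = None
    SE: dict[str, float] | None = None

    def defined(self) -> dict[str, float]:
        out = {}
        for name in ("Sn", "Sp", "Ac", "MCC", "Sw", "AUC"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


def confusion_counts(pred: LabelString, truth: LabelString) -> Confusion:
    if pred.arity != 2 or truth.arity != 2:
        raise ValueError("confusion counts require two-state labels")
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    p, t = pred.codes.astype(bool), truth.codes.astype(bool)
    return Confusion(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        TN=int(np.sum(~p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def scalar_metrics(c: Confusion) -> MetricReport:
    """Sn, Sp, Ac, MCC and Sw from a confusion table (AUC needs scores)."""
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN
    sn = tp / (tp + fn) if tp + fn > 0 else None
    sp = tn / (tn + fp) if tn + fp > 0 else None
    ac = (tp + tn) / c.total if c.total > 0 else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    sw = sn + sp - 1 if sn is not None and sp is not None else None
    return MetricReport(Sn=sn, Sp=sp, Ac=ac, MCC=mcc, Sw=sw)


def roc_auc(scores: Sequence[float] | np.ndarray, truth: LabelString) -> float | None:
    """Mann-Whitney AUC; tied scores contribute 1/2.  None when the truth
    contains a single class."""
    if truth.arity != 2:
        raise ValueError("AUC requires two-state truth labels")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(truth),):
        raise ValueError("scores and truth lengths differ")
    pos = truth.codes == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_predictions(
    preds: Sequence[LabelString],
    truths: Sequence[LabelString],
    scores: Sequence[np.ndarray] | None = None,
) -> MetricReport:
    """Pool residues across targets and report all metrics."""
    conf = Confusion(0, 0, 0, 0)
    for p, t in zip(preds, truths, strict=True):
        conf = conf + confusion_counts(p, t)
    report = scalar_metrics(conf)
    auc = None
    if scores is not None:
        pooled_scores = np.concatenate([np.asarray(s) for s in scores])
        pooled_truth = LabelString(
            np.concatenate([t.codes for t in truths]), arity=2
        )
        auc = roc_auc(pooled_scores, pooled_truth)
    return MetricReport(
        Sn=report.Sn, Sp=report.Sp, Ac=report.Ac, MCC=report.MCC, Sw=report.Sw, AUC=auc
    )


def bootstrap_se(
    per_target: Sequence,
    metric: Callable[[Sequence], float | None],
    frac: float = 0.8,
    reps: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> float:
    """Standard error of a metric under target-level bootstrap.

    ``metric`` receives a list of per-target prediction records (whatever
    structure the caller uses) and returns a scalar or None when undefined;
    undefined resamples are redrawn, up to ``max_redraws`` extra draws in
    total.
    """
    n = len(per_target)
    if n < 2:
        raise ValueError("bootstrap requires at least 2 targets")
    k = math.ceil(frac * n)
    rng = np.random.default_rng(seed)
    values: list[float] = []
    redraws = 0
    while len(values) < reps:
        idx = rng.choice(n, size=k, replace=False)
        v = metric([per_target[i] for i in idx])
        if v is None:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("metric undefined on too many bootstrap resamples")
            continue
        values.append(float(v))
    return float(np.std(values, ddof=1))


def pooled_metric(name: str) -> Callable[[Sequence], float | None]:
    """Metric functional for :func:`bootstrap_se` over records of the form
    (pred: LabelString, truth: LabelString, scores: ndarray)."""

    def fn(records: Sequence) -> float | None:
        preds = [r[0] for r in records]
        truths = [r[1] for r in records]
        scores = [r[2] for r in records] if name == "AUC" else None
        rep = evaluate_predictions(preds, truths, scores)
        return getattr(rep, name)

    return fn


def with_bootstrap_se(
    records: Sequence,
    metrics: Sequence[str] = ("Sn", "Sp", "Ac", "MCC", "Sw", "AUC"),
    frac: float = 0.8,
    reps: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Full report with bootstrap SEs from per-target (pred, truth, scores)
    records."""
    rep = evaluate_predictions(
        [r[0] for r in records], [r[1] for r in records], [r[2] for r in records]
    )
    se = {}
    for name in metrics:
        if getattr(rep, name) is None:
            continue
        se[name] = bootstrap_se(records, pooled_metric(name), frac=frac, reps=reps, seed=seed)
    return MetricReport(
        Sn=rep.Sn, Sp=rep.Sp, Ac=rep.Ac, MCC=rep.MCC, Sw=rep.Sw, AUC=rep.AUC, SE=se
    )
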