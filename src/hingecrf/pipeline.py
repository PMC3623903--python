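"""End-to-end orchestration: search -> profile -> features -> CRF ->
threshold decoding -> metrics.

The heavy step is the alignment search, so queries are featurized once
(:class:`FeaturizedQuery`) and reused across training, prediction,
threshold sweeps and cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .align import AlignmentHit, ReferenceDB, SearchParams, local_align_search
from .crf import CRFModel, MarginalMatrix, TrainConfig, posterior_marginals, train_crf
from .decode import DecodeConfig, Prediction, argmax_regions, decide_two_state
from .features import FeatureSequence, ShapeString, TemplateConfig, encode_features
from .labels import HingeConfig, LabelString
from .metrics import MetricReport, evaluate_predictions, with_bootstrap_se
from .profile import DHBProfile, compute_dhb_profile
from .synthetic import QueryRecord


@dataclass
class PipelineConfig:
    hinge: HingeConfig = field(default_factory=HingeConfig)
    search: SearchParams = field(default_factory=SearchParams)
    template: TemplateConfig = field(default_factory=TemplateConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)


@dataclass
class FeaturizedQuery:
    id: str
    sequence: str
    x: FeatureSequence
    profile: DHBProfile
    hits: list[AlignmentHit]
    shape: ShapeString
    labels2: LabelString | None = None
    labels3: LabelString | None = None


def featurize_query(
    query_id: str,
    sequence: str,
    shape: ShapeString | None,
    db: ReferenceDB,
    cfg: PipelineConfig,
    labels2: LabelString | None = None,
    labels3: LabelString | None = None,
    hits: list[AlignmentHit] | None = None,
) -> FeaturizedQuery:
    """Run search, profile and feature encoding for one query.

    Precomputed ``hits`` (e.g. imported from an external aligner) bypass
    the built-in search.
    """
    if shape is None:
        shape = ShapeString.unknown(len(sequence))
    if hits is None:
        hits = local_align_search(sequence, db, cfg.search)
    profile = compute_dhb_profile(len(sequence), hits, db)
    x = encode_features(profile, shape, cfg.template)
    return FeaturizedQuery(query_id, sequence, x, profile, hits, shape, labels2, labels3)


def featurize_records(
    records: list[QueryRecord], db: ReferenceDB, cfg: PipelineConfig
) -> list[FeaturizedQuery]:
    return [
        featurize_query(q.id, q.sequence, q.shape, db, cfg, q.labels2, q.labels3)
        for q in records
    ]


def train_on(featurized: list[FeaturizedQuery], cfg: PipelineConfig) -> CRFModel:
    dataset = []
    for fq in featurized:
        if fq.labels3 is None:
            raise ValueError(f"{fq.id}: three-state labels required for training")
        dataset.append((fq.x, fq.labels3))
    return train_crf(dataset, cfg.train)


@dataclass
class QueryPrediction:
    id: str
    marginals: MarginalMatrix
    prediction: Prediction
    truth2: LabelString | None

    def record(self) -> tuple[LabelString, LabelString, np.ndarray]:
        if self.truth2 is None:
            raise ValueError(f"{self.id}: no truth labels")
        return (self.prediction.calls2, self.truth2, self.prediction.scores)


def predict_featurized(
    model: CRFModel, featurized: list[FeaturizedQuery], decode_cfg: DecodeConfig
) -> list[QueryPrediction]:
    out = []
    for fq in featurized:
        marg = posterior_marginals(model, fq.x)
        pred = decide_two_state(marg, argmax_regions(marg), decode_cfg)
        out.append(QueryPrediction(fq.id, marg, pred, fq.labels2))
    return out


def redecode(
    preds: list[QueryPrediction], decode_cfg: DecodeConfig
) -> list[QueryPrediction]:
    """Re-threshold cached marginals without re-running the CRF."""
    return [
        QueryPrediction(
            p.id,
            p.marginals,
            decide_two_state(p.marginals, argmax_regions(p.marginals), decode_cfg),
            p.truth2,
        )
        for p in preds
    ]


def evaluate(
    preds: list[QueryPrediction],
    bootstrap: bool = False,
    reps: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
) -> MetricReport:
    records = [p.record() for p in preds]
    if bootstrap:
        return with_bootstrap_se(records, frac=frac, reps=reps, seed=seed)
    return evaluate_predictions(
        [r[0] for r in records], [r[1] for r in records], [r[2] for r in records]
    )


def threshold_sweep(
    preds: list[QueryPrediction],
    thresholds: np.ndarray | list[float],
    vary: str = "hinge",
    base: DecodeConfig | None = None,
) -> pd.DataFrame:
    """Metrics as a function of the hinge (or domain) decision threshold.

    Varying the hinge threshold uses mode ``hinge_only``; varying the
    domain threshold uses mode ``both`` so the hinge rule stays at its
    default while the domain rule is exercised.
    """
    if vary not in ("hinge", "domain"):
        raise ValueError("vary must be 'hinge' or 'domain'")
    base = base or DecodeConfig()
    rows = []
    for t in thresholds:
        if vary == "hinge":
            cfg = replace(base, t_hinge=float(t), mode="hinge_only")
        else:
            cfg = replace(base, t_domain=float(t), mode="both")
        redecoded = redecode(preds, cfg)
        rep = evaluate(redecoded)
        n_calls = int(sum(p.prediction.calls2.codes.sum() for p in redecoded))
        rows.append(
            {
                "threshold": float(t),
                "Sn": rep.Sn,
                "Sp": rep.Sp,
                "Ac": rep.Ac,
                "MCC": rep.MCC,
                "Sw": rep.Sw,
                "boundary_calls": n_calls,
            }
        )
    return pd.DataFrame(rows)


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random equal split of range(n) into k disjoint folds."""
    if k > n:
        raise ValueError("fold count exceeds number of chains")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(perm[i::k]) for i in range(k)]


def run_kfold(
    featurized: list[FeaturizedQuery],
    cfg: PipelineConfig,
    k: int = 10,
    seed: int = 0,
) -> tuple[MetricReport, list[QueryPrediction]]:
    """The cross-validation protocol: random equal split, train on k-1
    folds, predict the held-out fold, pool all held-out predictions."""
    folds = kfold_indices(len(featurized), k, seed)
    all_preds: list[QueryPrediction] = []
    for fold in folds:
        test_set = set(int(i) for i in fold)
        train_fqs = [fq for i, fq in enumerate(featurized) if i not in test_set]
        test_fqs = [fq for i, fq in enumerate(featurized) if i in test_set]
        model = train_on(train_fqs, cfg)
        all_preds.extend(predict_featurized(model, test_fqs, cfg.decode))
    return evaluate(all_preds), all_preds
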