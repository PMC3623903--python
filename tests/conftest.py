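import numpy as np
import pytest

import hingecrf as hc


def random_annotation(rng: np.random.Generator, max_len: int = 120) -> hc.DomainAnnotation:
    """Random valid annotation: non-overlapping segments grouped into
    domains (some discontinuous)."""
    length = int(rng.integers(1, max_len + 1))
    n_cuts = int(rng.integers(0, min(8, length) + 1))
    cuts = np.sort(rng.choice(np.arange(1, length + 1), size=n_cuts, replace=False))
    segments = []
    pos = 1
    for c in cuts:
        if rng.random() < 0.5 and c >= pos:
            segments.append((pos, int(c)))
        pos = int(c) + 1
    domains: list[list[tuple[int, int]]] = []
    for seg in segments:
        if domains and rng.random() < 0.2:
            domains[-1].append(seg)  # discontinuous domain
        else:
            domains.append([seg])
    return hc.DomainAnnotation("rand", length, tuple(tuple(d) for d in domains))


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world shared by integration-level unit tests."""
    cfg = hc.SynthConfig(seed=7, n_ref=40, n_query=16)
    refs, queries = hc.generate_dataset(cfg)
    db = hc.build_reference_db(refs)
    return cfg, refs, queries, db


@pytest.fixture(scope="session")
def small_pipeline(small_world):
    """Featurized queries + a trained model on the small world."""
    _cfg, _refs, queries, db = small_world
    pcfg = hc.PipelineConfig(train=hc.TrainConfig(max_iter=120))
    fqs = hc.featurize_records(queries, db, pcfg)
    model = hc.train_on(fqs[:10], pcfg)
    preds = hc.predict_featurized(model, fqs[10:], pcfg.decode)
    return pcfg, fqs, model, preds
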