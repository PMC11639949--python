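import numpy as np
import pytest

from femvoice.fem_cluster import FemConfig, fit_fem
from femvoice.synthetic_corpus import CorpusConfig, generate_feature_corpus


@pytest.fixture(scope="session")
def two_blob_data():
    """Two 10-sigma separated Gaussian blobs (last one plays 'normal')."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 1.0, (60, 5))
    b = rng.normal(10.0 / np.sqrt(5), 1.0, (60, 5))  # centers 10 sigma apart
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 60)
    normal_mask = labels == 1
    return X, labels, normal_mask


@pytest.fixture(scope="session")
def small_corpus():
    cfg = CorpusConfig(
        n_types=4, utterances_per_type=5, frames_per_utterance=(15, 25),
        n_phonemes=5, min_separation=8.0, seed=11,
    )
    return generate_feature_corpus(cfg), cfg


@pytest.fixture(scope="session")
def fitted_corpus_model(small_corpus):
    """FEM model fitted on the small synthetic corpus' training frames."""
    (utterances, specs), cfg = small_corpus
    normal_type = next(s.type_id for s in specs if s.is_normal)
    X = np.vstack([u.frames for u in utterances])
    mask = np.concatenate(
        [np.full(u.frames.shape[0], u.type_id == normal_type) for u in utterances]
    )
    res = fit_fem(X, mask, FemConfig(n_clusters=cfg.n_types, seed=5, tol_centers=1e-7,
                                     tol_memberships=1e-7))
    return res, utterances, specs
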